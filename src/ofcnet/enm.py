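"""Gaussian network models: classical GNM and the modified GNM (mGNM).

The classical GNM connects every Cα pair within a cutoff R_c by a
uniform spring; fluctuation covariances are proportional to the
pseudoinverse of the Kirchhoff (graph Laplacian) matrix Γ. The modified
GNM keeps the same topology but reweights edges by physically motivated
factors: an inverse-square distance base, ×10 on bonded (|i−j| = 1)
pairs, a sign-flipping factor on second neighbors (|i−j| = 2, −1 for a
uniform base and −5 for a distance-dependent base), and ×10 on backbone
hydrogen-bonded pairs. Negative second-neighbor springs encode local
frustration; they are acceptable as long as the full matrix stays
nonnegative definite.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .ensemble import MeanStructure, ScalarCovariance
from .exceptions import AnnotationError
from .maxent import NULL_EIG_REL

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContactTopology:
    """Edges of the elastic network: pairs within the cutoff distance."""

    cutoff: float
    edges: tuple[tuple[int, int], ...]
    n: int

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class WeightedNetwork:
    """Spring-weighted network and its Kirchhoff-form matrix.

    Γ_ij = −γ_ij off-diagonal and Γ_ii = Σ_{j≠i} γ_ij, so every row sums
    to zero and rigid translation is a null mode.
    """

    gamma: dict[tuple[int, int], float]
    n: int
    meta: dict = field(default_factory=dict)

    @property
    def kirchhoff(self) -> np.ndarray:
        G = np.zeros((self.n, self.n))
        for (i, j), g in self.gamma.items():
            G[i, j] = G[j, i] = -g
        np.fill_diagonal(G, 0.0)
        np.fill_diagonal(G, -G.sum(axis=1))
        return G

    @property
    def degrees(self) -> np.ndarray:
        """Number of edges at each node."""
        d = np.zeros(self.n, dtype=int)
        for i, j in self.gamma:
            d[i] += 1
            d[j] += 1
        return d


@dataclass(frozen=True)
class MGNMParams:
    """Edge-weighting scheme of a modified GNM variant.

    base: "uniform" (γ = 1) or "inverse-square" (γ = 1/d²).
    Multiplicative factors apply on top of the base weight, composed in
    the fixed order base → contact-order factor → H-bond factor.
    """

    base: str = "inverse-square"
    bonded_factor: float = 10.0
    second_neighbor_factor: float = -5.0
    hbond_factor: float = 10.0

    def __post_init__(self):
        if self.base not in ("uniform", "inverse-square"):
            raise ValueError(f"unknown base scheme {self.base!r}")
        for f in (self.bonded_factor, self.second_neighbor_factor,
                  self.hbond_factor):
            if not np.isfinite(f) or f == 0:
                raise ValueError("factors must be finite and nonzero")


def contact_topology(structure: MeanStructure, cutoff: float
                     ) -> ContactTopology:
    """All residue pairs with Cα distance ≤ cutoff in one structure."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = squareform(pdist(structure.coords))
    n = structure.n_residues
    edges = tuple((i, j) for i in range(n) for j in range(i + 1, n)
                  if d[i, j] <= cutoff)
    return ContactTopology(cutoff=cutoff, edges=edges, n=n)


def classical_gnm(topology: ContactTopology) -> WeightedNetwork:
    """Uniform-spring GNM on a contact topology (every γ_ij = 1)."""
    return WeightedNetwork(gamma={e: 1.0 for e in topology.edges},
                           n=topology.n, meta={"model": "U"})


def gnm_covariance(net: WeightedNetwork,
                   gamma_uniform: float = 1.0) -> ScalarCovariance:
    """Predicted covariance C = Γ⁺ / γ of a network.

    The pseudoinverse discards null (rigid-body) modes by the package
    rule; a disconnected graph contributes extra null modes, which are
    dropped with a warning. Negative eigenvalues (possible for networks
    with negative springs) are likewise excluded and reported in the
    metadata.
    """
    G = net.kirchhoff
    lam, vec = np.linalg.eigh(G)
    lam_max = max(lam[-1], 0.0)
    null = np.abs(lam) <= NULL_EIG_REL * lam_max
    negative = (lam < 0) & ~null
    keep = ~null & ~negative
    n_null = int(null.sum())
    if n_null > 1:
        logger.warning("network has %d null modes (disconnected graph?)",
                       n_null)
    meta = {"null_modes": n_null}
    if negative.any():
        meta["negative_eigenvalues"] = lam[negative].tolist()
        logger.warning("network has %d negative eigenvalue(s); excluded "
                       "from the covariance", int(negative.sum()))
    C = (vec[:, keep] / lam[keep]) @ vec[:, keep].T / gamma_uniform
    return ScalarCovariance(C=C, n_models=0, meta=meta)


def build_mgnm(structure: MeanStructure, topology: ContactTopology,
               annotations=None,
               params: MGNMParams | None = None) -> WeightedNetwork:
    """Weight a contact topology by the modified-GNM scheme.

    Every edge starts from its base weight (1 or 1/d², d from the given
    structure), then bonded, second-neighbor and H-bond factors multiply
    in when the pair qualifies; a pair qualifying for several factors
    receives their product.
    """
    params = params or MGNMParams()
    if params.hbond_factor != 1.0 and annotations is None:
        raise AnnotationError("H-bond factor requires residue annotations")
    coords = structure.coords
    gamma = {}
    for i, j in topology.edges:
        if params.base == "uniform":
            w = 1.0
        else:
            d = float(np.linalg.norm(coords[i] - coords[j]))
            w = 1.0 / d ** 2
        k = abs(i - j)
        if k == 1:
            w *= params.bonded_factor
        elif k == 2:
            w *= params.second_neighbor_factor
        if annotations is not None and j in annotations[i].hbond_partners:
            w *= params.hbond_factor
        gamma[(i, j)] = w
    net = WeightedNetwork(gamma=gamma, n=topology.n,
                          meta={"params": params})
    lam = np.linalg.eigvalsh(net.kirchhoff)
    neg = lam[(lam < 0) & (np.abs(lam) > NULL_EIG_REL * max(lam[-1], 0.0))]
    if neg.size:
        net.meta["negative_eigenvalues"] = neg.tolist()
    return net


#: The ten model variants: base scheme plus optional bonded (γ(1)),
#: second-neighbor (γ(2)) and hydrogen-bond (HB) modifiers. The
#: second-neighbor factor is −1 on a uniform base and −5 on the
#: inverse-square base.
_VARIANTS = {
    "U": ("uniform", 1.0, 1.0, 1.0),
    "D": ("inverse-square", 1.0, 1.0, 1.0),
    "U+g1": ("uniform", 10.0, 1.0, 1.0),
    "D+g1": ("inverse-square", 10.0, 1.0, 1.0),
    "U+g1+g2": ("uniform", 10.0, -1.0, 1.0),
    "D+g1+g2": ("inverse-square", 10.0, -5.0, 1.0),
    "U+g1+HB": ("uniform", 10.0, 1.0, 10.0),
    "D+g1+HB": ("inverse-square", 10.0, 1.0, 10.0),
    "U+g1+g2+HB": ("uniform", 10.0, -1.0, 10.0),
    "D+g1+g2+HB": ("inverse-square", 10.0, -5.0, 10.0),
}

_ALIASES = {"GNM": "U", "mGNM": "D+g1+g2+HB"}


def _canonical_variant(name: str) -> str:
    """Map γ(1)/γ(2) spellings and aliases onto canonical variant keys."""
    if name in _ALIASES:
        return _ALIASES[name]
    s = name.replace("γ", "g").replace(" ", "")
    s = re.sub(r"g\((\d)\)", r"g\1", s)
    s = re.sub(r"g_\((\d)\)", r"g\1", s)
    return s


def model_variant(name: str) -> MGNMParams:
    """Parameter bundle for a named model variant.

    Accepts the canonical symbols ("U", "D+g1+g2+HB", ...), the spelled
    forms with γ(1)/γ(2), and the aliases "GNM" (= U) and "mGNM"
    (= D+g1+g2+HB).
    """
    key = _canonical_variant(name)
    if key not in _VARIANTS:
        raise KeyError(f"unknown model variant {name!r}; "
                       f"choose from {sorted(_VARIANTS)} or GNM/mGNM")
    base, b, s, h = _VARIANTS[key]
    return MGNMParams(base=base, bonded_factor=b, second_neighbor_factor=s,
                      hbond_factor=h)
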