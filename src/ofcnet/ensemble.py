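"""Multi-model structural ensembles and scalar fluctuation covariances.

An NMR-style ensemble of m conformers of an N-residue protein is reduced
to its Cα trace, iteratively superposed onto its own mean structure to
remove rigid-body (external) degrees of freedom, and summarized by the
scalar covariance matrix

    C_ij = (1/3) <ΔR_i · ΔR_j>,

where ΔR_i is the vector displacement of residue i from its mean
position and the average runs over models. The 1/3 prefactor is the
isotropic convention of the Gaussian network model: it makes C_ii the
per-axis mean-square fluctuation, so interaction matrices fitted to C
convert to physical units by the single factor 3·k_B·T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

from . import geometry
from .exceptions import (
    AlignmentError,
    FormatError,
    InsufficientEnsembleError,
    NotSuperposedError,
)

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "C", "O")


@dataclass
class ConformerEnsemble:
    """Aligned Cα coordinates of one protein's structural ensemble.

    Attributes
    ----------
    model_coords : (m, N, 3) float array
        Cα positions in Å, one slab per model.
    residue_ids : list of (chain, resnum, aa) tuples
        Author chain id, author residue number and three-letter code,
        shared by every model.
    backbone_coords : dict or None
        Optional {"N": (m,N,3), "C": ..., "O": ...} backbone positions
        used for hydrogen-bond annotation.
    superposed : bool
        True once rigid-body motion has been removed.
    """

    model_coords: np.ndarray
    residue_ids: list[tuple[str, int, str]]
    backbone_coords: dict[str, np.ndarray] | None = None
    superposed: bool = False

    @property
    def n_models(self) -> int:
        return self.model_coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.model_coords.shape[1]

    def __post_init__(self):
        m, n = self.model_coords.shape[:2]
        if m < 2:
            raise InsufficientEnsembleError(f"need >=2 models, got {m}")
        if n < 2:
            raise AlignmentError(f"need >=2 residues, got {n}")
        if not np.all(np.isfinite(self.model_coords)):
            raise FormatError("non-finite coordinates in ensemble")


@dataclass
class MeanStructure:
    """Arithmetic mean conformation of a superposed ensemble (Å)."""

    coords: np.ndarray
    source: str = ""

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]


@dataclass
class ScalarCovariance:
    """N×N scalar fluctuation covariance matrix in Å²."""

    C: np.ndarray
    n_models: int
    rank_bound: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.C.shape[0]

    @property
    def msf(self) -> np.ndarray:
        """Per-residue (per-axis) mean-square fluctuations, the diagonal."""
        return np.diag(self.C).copy()


def _best_altloc(residue: gemmi.Residue, name: str) -> gemmi.Atom | None:
    """Highest-occupancy atom of the given name (first listed on ties)."""
    best = None
    for atom in residue:
        if atom.name != name:
            continue
        if best is None or atom.occ > best.occ:
            best = atom
    return best


def read_multimodel_structure(path: str) -> ConformerEnsemble:
    """Read a multi-MODEL PDB file into a :class:`ConformerEnsemble`.

    Residues are keyed by (chain, author residue number); only residues
    whose Cα is present in every retained model are kept. Models with no
    Cα atoms at all are dropped with a warning. Backbone N/C/O
    coordinates are attached when present for every kept residue in
    every model.
    """
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(structure) == 0:
        raise FormatError(f"no MODEL records found in {path}")

    per_model: list[dict[tuple[str, int], dict[str, np.ndarray]]] = []
    res_meta: dict[tuple[str, int], str] = {}
    for model in structure:
        atoms: dict[tuple[str, int], dict[str, np.ndarray]] = {}
        for chain in model:
            for residue in chain:
                key = (chain.name, residue.seqid.num)
                entry = {}
                for name in ("CA",) + BACKBONE_ATOMS:
                    atom = _best_altloc(residue, name)
                    if atom is not None:
                        entry[name] = np.array(
                            [atom.pos.x, atom.pos.y, atom.pos.z])
                if "CA" in entry:
                    atoms[key] = entry
                    res_meta.setdefault(key, residue.name)
        if atoms:
            per_model.append(atoms)
        else:
            logger.warning("dropping model with no CA atoms")

    if len(per_model) < 2:
        raise InsufficientEnsembleError(
            f"{path}: {len(per_model)} usable model(s); need >=2")

    common = set(per_model[0])
    for atoms in per_model[1:]:
        common &= set(atoms)
    if len(common) < 2:
        raise AlignmentError(f"{path}: models share no common residue core")
    full = set().union(*per_model)
    dropped = full - common
    if dropped:
        logger.warning("excluding %d residue(s) missing a CA in some model: %s",
                       len(dropped), sorted(dropped))

    keys = sorted(common)
    m, n = len(per_model), len(keys)
    ca = np.empty((m, n, 3))
    for k, atoms in enumerate(per_model):
        for i, key in enumerate(keys):
            ca[k, i] = atoms[key]["CA"]

    backbone = None
    if all(all(name in atoms[key] for name in BACKBONE_ATOMS)
           for atoms in per_model for key in keys):
        backbone = {name: np.empty((m, n, 3)) for name in BACKBONE_ATOMS}
        for k, atoms in enumerate(per_model):
            for i, key in enumerate(keys):
                for name in BACKBONE_ATOMS:
                    backbone[name][k, i] = atoms[key][name]

    residue_ids = [(c, num, res_meta[(c, num)]) for c, num in keys]
    return ConformerEnsemble(model_coords=ca, residue_ids=residue_ids,
                             backbone_coords=backbone)


def superpose_ensemble(ens: ConformerEnsemble, tol: float = 1e-6,
                       max_iter: int = 100
                       ) -> tuple[ConformerEnsemble, MeanStructure]:
    """Iteratively superpose every model onto the evolving mean structure.

    Each round least-squares fits all models onto the current mean and
    recomputes it; iteration stops when the mean shifts by less than
    ``tol`` Å RMS. The converged mean defines the internal reference
    frame in which fluctuations are measured. Backbone atoms, when
    present, ride along with the Cα-derived transform of their model.
    """
    coords = ens.model_coords.copy()
    backbone = (None if ens.backbone_coords is None
                else {k: v.copy() for k, v in ens.backbone_coords.items()})
    mean = coords[0].copy()
    for _ in range(max_iter):
        for k in range(coords.shape[0]):
            centroid = coords[k].mean(axis=0)
            target_centroid = mean.mean(axis=0)
            mc = coords[k] - centroid
            tc = mean - target_centroid
            if np.linalg.matrix_rank(
                    mc, tol=1e-9 * max(1.0, np.abs(mc).max())) < 2:
                from .exceptions import DegenerateGeometryError
                raise DegenerateGeometryError(
                    "collinear or <3-point model: superposition ill-defined")
            rot = geometry.kabsch_rotation(mc, tc)
            coords[k] = mc @ rot.T + target_centroid
            if backbone is not None:
                for name in backbone:
                    backbone[name][k] = (backbone[name][k] - centroid) @ rot.T \
                        + target_centroid
        new_mean = coords.mean(axis=0)
        shift = np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1)))
        mean = new_mean
        if shift < tol:
            break
    out = ConformerEnsemble(model_coords=coords, residue_ids=ens.residue_ids,
                            backbone_coords=backbone, superposed=True)
    return out, MeanStructure(coords=mean)


def representative_model(ens: ConformerEnsemble,
                         mean: MeanStructure | None = None) -> int:
    """Index of the model closest (RMSD) to the mean structure.

    Ties are broken toward the lowest model index. This mirrors the
    convention of picking a representative NMR model for single-structure
    computations (contact topology, DSSP-style annotation).
    """
    if not ens.superposed:
        raise NotSuperposedError("superpose the ensemble before selecting "
                                 "a representative model")
    if mean is None:
        mean = MeanStructure(coords=ens.model_coords.mean(axis=0))
    rmsds = [geometry.rmsd(ens.model_coords[k], mean.coords)
             for k in range(ens.n_models)]
    return int(np.argmin(rmsds))


def scalar_covariance(ens: ConformerEnsemble,
                      ddof: int = 0) -> ScalarCovariance:
    """Scalar fluctuation covariance C_ij = (1/3)<ΔR_i·ΔR_j> of an ensemble.

    The default ``ddof=0`` divides by m (population convention): C is
    the constrained expectation of the entropy-maximization problem, not
    an unbiased estimator. Pass ``ddof=1`` for the sample convention.
    """
    if not ens.superposed:
        raise NotSuperposedError("covariance requires a superposed ensemble")
    m = ens.n_models
    mean = ens.model_coords.mean(axis=0)
    disp = ens.model_coords - mean  # (m, N, 3)
    C = np.einsum("kid,kjd->ij", disp, disp) / (3.0 * (m - ddof))
    C = 0.5 * (C + C.T)
    return ScalarCovariance(C=C, n_models=m,
                            rank_bound=min(C.shape[0], m - 1))


def write_covariance(cov: ScalarCovariance, path: str) -> None:
    """Write a covariance matrix as dense whitespace text with a header."""
    header = f"N={cov.n} m={cov.n_models} units=A^2"
    np.savetxt(path, cov.C, header=header)


def read_covariance(path: str) -> ScalarCovariance:
    """Read a covariance matrix written by :func:`write_covariance`."""
    n_models = 0
    with open(path) as fh:
        first = fh.readline()
    for token in first.lstrip("# ").split():
        if token.startswith("m="):
            n_models = int(token[2:])
    C = np.loadtxt(path)
    C = np.atleast_2d(C)
    return ScalarCovariance(C=C, n_models=n_models)


def ensemble_summary(ens: ConformerEnsemble) -> str:
    """Tab-separated per-residue summary (id, chain, resnum, aa, MSF)."""
    cov = scalar_covariance(ens) if ens.superposed else None
    lines = ["index\tchain\tresnum\taa\tmsf_A2"]
    for i, (chain, num, aa) in enumerate(ens.residue_ids):
        msf = f"{cov.C[i, i]:.4f}" if cov is not None else "NA"
        lines.append(f"{i + 1}\t{chain}\t{num}\t{aa}\t{msf}")
    return "\n".join(lines) + "\n"
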