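"""Normal-mode decomposition and mode-space comparison metrics.

Two networks (or a network and an experimental covariance matrix) are
compared in mode space: per-residue mobilities reconstructed from a
band of modes, and the subspace overlap

    Q_m = (1/m) Σ_{k,p ≤ m} (u^(k) · v^(p))²,

the normalized squared projection of one m-dimensional slow-mode
subspace onto the other. Q_m is 0 for disjoint subspaces, 1 for
identical ones, symmetric in its arguments, and invariant to any
rotation of a basis within its leading-m subspace.

"Slowest" modes of a stiffness-type matrix (interaction matrix K,
Kirchhoff Γ) are those of smallest nonzero eigenvalue; for a covariance
matrix they are the largest-variance eigenmodes — the two orderings
correspond under matrix inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maxent import NULL_EIG_REL, _as_matrix


@dataclass
class ModeSet:
    """Eigenpairs of a symmetric matrix, ordered slowest-first.

    ``eigenvalues``/``eigenvectors`` exclude null modes (|λ| below
    10⁻⁸ of the largest magnitude); ``n_null`` counts the discarded
    ones. ``kind`` is "stiffness" or "covariance" and fixes both the
    slow-mode ordering and the mobility weights.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_null: int
    kind: str = "stiffness"
    source: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size

    @property
    def n(self) -> int:
        return self.eigenvectors.shape[0]


def decompose(matrix, kind: str = "stiffness", source: str = "") -> ModeSet:
    """Full eigendecomposition of a symmetric matrix as a :class:`ModeSet`.

    For ``kind="stiffness"`` modes are ordered by ascending eigenvalue
    (slow = soft); for ``kind="covariance"`` by descending eigenvalue
    (slow = large variance).
    """
    if kind not in ("stiffness", "covariance"):
        raise ValueError("kind must be 'stiffness' or 'covariance'")
    M = _as_matrix(matrix)
    M = 0.5 * (M + M.T)
    lam, vec = np.linalg.eigh(M)
    null = np.abs(lam) <= NULL_EIG_REL * np.abs(lam).max()
    lam, vec = lam[~null], vec[:, ~null]
    order = np.argsort(lam) if kind == "stiffness" else np.argsort(-lam)
    return ModeSet(eigenvalues=lam[order], eigenvectors=vec[:, order],
                   n_null=int(null.sum()), kind=kind, source=source)


def msf_from_modes(modes: ModeSet, m: int) -> np.ndarray:
    """Per-residue mobility from the m slowest modes.

    For a stiffness source, mobility_i = Σ_{k≤m} v_i^(k)² / λ_k (the
    covariance diagonal of those modes); for a covariance source,
    mobility_i = Σ_{k≤m} λ_k v_i^(k)². With all modes included this is
    the diagonal of the (pseudo)inverse or of the matrix itself.
    """
    if not 1 <= m <= modes.n_modes:
        raise ValueError(f"m must be in [1, {modes.n_modes}], got {m}")
    v = modes.eigenvectors[:, :m]
    lam = modes.eigenvalues[:m]
    if modes.kind == "stiffness":
        return np.sum(v ** 2 / lam, axis=1)
    return np.sum(v ** 2 * lam, axis=1)


def mode_overlap(U: ModeSet, V: ModeSet, m: int) -> float:
    """Subspace overlap Q_m between the m slowest modes of two models."""
    if U.n != V.n:
        raise ValueError(f"dimension mismatch: {U.n} vs {V.n}")
    if m < 1 or m > min(U.n_modes, V.n_modes):
        raise ValueError(f"m={m} exceeds available nonzero modes")
    P = U.eigenvectors[:, :m].T @ V.eigenvectors[:, :m]
    return float(np.sum(P ** 2) / m)


def overlap_curves(A: ModeSet, B: ModeSet,
                   fractions: np.ndarray | None = None) -> np.ndarray:
    """Mobility correlation and Q_m as a function of mode fraction.

    Returns a structured record array with fields ``fraction``, ``m``,
    ``mobility_cc`` and ``Q``; the default grid runs 2%..100% in 2%
    steps of the smaller model's nonzero mode count.
    """
    if A.n != B.n:
        raise ValueError(f"dimension mismatch: {A.n} vs {B.n}")
    if fractions is None:
        fractions = np.arange(0.02, 1.0001, 0.02)
    n_avail = min(A.n_modes, B.n_modes)
    rows = []
    for f in fractions:
        m = min(max(1, int(np.ceil(f * n_avail))), n_avail)
        ma = msf_from_modes(A, m)
        mb = msf_from_modes(B, m)
        if np.std(ma) == 0 or np.std(mb) == 0:
            cc = np.nan
        else:
            cc = float(np.corrcoef(ma, mb)[0, 1])
        rows.append((float(f), m, cc, mode_overlap(A, B, m)))
    return np.array(rows, dtype=[("fraction", float), ("m", int),
                                 ("mobility_cc", float), ("Q", float)])
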