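"""Rigid-body superposition and idealized backbone construction.

Internal helpers: least-squares (Kabsch) superposition used by the
ensemble machinery, and a torsion-driven chain builder used to generate
ideal α-helical and extended-chain backbones for fixtures and synthetic
ensembles.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DegenerateGeometryError

# Standard backbone internal coordinates (Engh-Huber-like averages), Å / deg.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

ALPHA_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (-139.0, 135.0)


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation matrix best superposing centered `mobile` onto centered `target`.

    Both inputs must already have zero centroid. Uses the SVD solution of
    the orthogonal Procrustes problem with the proper-rotation correction.
    """
    h = mobile.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    return vt.T @ diag @ u.T


def superpose_onto(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares superpose one coordinate set onto another.

    Returns the transformed copy of ``mobile``; raises
    :class:`DegenerateGeometryError` when the point set cannot define a
    unique rotation (fewer than 3 points or collinear geometry).
    """
    if mobile.shape[0] < 3:
        raise DegenerateGeometryError(
            f"need >=3 points for superposition, got {mobile.shape[0]}"
        )
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    # collinearity check: rank of the centered cloud
    if np.linalg.matrix_rank(mc, tol=1e-9 * max(1.0, np.abs(mc).max())) < 2:
        raise DegenerateGeometryError("collinear point set: rotation ill-defined")
    rot = kabsch_rotation(mc, tc)
    return mc @ rot.T + target.mean(axis=0)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two N×3 coordinate sets."""
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position a fourth atom from three predecessors and internal coordinates.

    Natural-extension-reference-frame construction: the new atom D is
    placed at distance ``bond`` from C, with angle B-C-D = ``angle`` (deg)
    and torsion A-B-C-D = ``torsion`` (deg).
    """
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(n_residues: int, phi: float, psi: float,
                   omega: float = 180.0) -> dict[str, np.ndarray]:
    """Build an ideal polypeptide backbone with uniform (φ, ψ, ω).

    Returns arrays of shape (n_residues, 3) for atom names ``N``, ``CA``,
    ``C`` and ``O``. The carbonyl oxygen is placed trans to the next
    residue's nitrogen; the C-terminal oxygen uses the same in-plane
    geometry extrapolated from ψ.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    N = np.zeros((n_residues, 3))
    CA = np.zeros((n_residues, 3))
    C = np.zeros((n_residues, 3))
    # seed triad for residue 0
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [BOND_N_CA, 0.0, 0.0]
    ang = np.deg2rad(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_residues):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N,
                          ANGLE_CA_C_N, psi)
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], BOND_N_CA,
                           ANGLE_C_N_CA, omega)
        C[i] = place_atom(C[i - 1], N[i], CA[i], BOND_CA_C,
                          ANGLE_N_CA_C, phi)
    O = np.zeros((n_residues, 3))
    for i in range(n_residues):
        if i + 1 < n_residues:
            # O trans to the next N across the carbonyl carbon
            O[i] = place_atom(N[i + 1], CA[i], C[i], BOND_C_O,
                              ANGLE_CA_C_O, 180.0)
        else:
            O[i] = place_atom(N[i], CA[i], C[i], BOND_C_O,
                              ANGLE_CA_C_O, psi + 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


def ideal_helix_backbone(n_residues: int) -> dict[str, np.ndarray]:
    """Ideal α-helix backbone (φ = −57°, ψ = −47°)."""
    return build_backbone(n_residues, *ALPHA_PHI_PSI)


def extended_backbone(n_residues: int) -> dict[str, np.ndarray]:
    """Fully extended (β-like) backbone with no turn structure."""
    return build_backbone(n_residues, *EXTENDED_PHI_PSI)
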