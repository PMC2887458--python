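"""Entropy-maximized optimal force constants (OFCs).

Given the scalar covariance matrix C of an ensemble and a set π of
residue pairs whose covariances we claim to know, the maximum-entropy
distribution over fluctuations is the Gaussian ρ(Δr) ∝ exp(−½ Δrᵀ K Δr)
whose interaction matrix K has K_ij = 0 for every off-diagonal pair not
in π and reproduces the constrained covariances exactly:

    (K⁻¹)_ij = C_ij   for (i,j) ∈ π and (by default) the diagonal.

K is found by minimizing the strictly convex functional

    f(K, C) = trace(K·C) − log det K,

whose gradient is C − K⁻¹; the constrained entries are adjusted against
the gradient while all other off-diagonal entries stay exactly zero.
Off-diagonal elements of the solution are the negative spring constants
of an elastic network: K_ij = −γ_ij. Multiplying K by 3·k_B·T gives
force constants in kcal/mol/Å².
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ensemble import MeanStructure, ScalarCovariance
from .exceptions import (
    ConstraintError,
    ConvergenceError,
    NormalizationError,
    SingularMatrixError,
)

#: Boltzmann constant, kcal/mol/K.
KB_KCAL = 1.9872e-3

#: Package-wide pseudoinverse rule: eigenvalues below this fraction of the
#: largest are treated as null modes.
NULL_EIG_REL = 1e-8


@dataclass(frozen=True)
class ConstraintSet:
    """The set π of off-diagonal pairs whose covariances are constrained."""

    pairs: tuple[tuple[int, int], ...]
    include_diagonal: bool = True

    @classmethod
    def from_pairs(cls, pairs, include_diagonal: bool = True) -> "ConstraintSet":
        canon = set()
        for i, j in pairs:
            if i == j:
                raise ConstraintError(f"self-pair ({i},{i}) not allowed in pi")
            canon.add((min(i, j), max(i, j)))
        return cls(pairs=tuple(sorted(canon)),
                   include_diagonal=include_diagonal)

    @classmethod
    def all_pairs(cls, n: int, include_diagonal: bool = True) -> "ConstraintSet":
        return cls(pairs=tuple((i, j) for i in range(n)
                               for j in range(i + 1, n)),
                   include_diagonal=include_diagonal)

    @property
    def q(self) -> int:
        return len(self.pairs)

    def mask(self, n: int) -> np.ndarray:
        """Boolean N×N mask of adjustable entries of K."""
        m = np.zeros((n, n), dtype=bool)
        for i, j in self.pairs:
            if j >= n:
                raise ConstraintError(f"pair ({i},{j}) out of range for N={n}")
            m[i, j] = m[j, i] = True
        if self.include_diagonal:
            np.fill_diagonal(m, True)
        return m


@dataclass
class OptimizerSettings:
    """Knobs of the constrained descent.

    tolerance is the dimensionless convergence constant: iteration stops
    once every constrained covariance is reproduced to within
    tolerance × its scale (see :func:`constraint_residual`).
    """

    tolerance: float = 0.01
    max_steps: int = 100_000
    initial_step: float | None = None
    ridge_epsilon: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


@dataclass
class InteractionMatrix:
    """Symmetric matrix of Lagrange multipliers K (units Å⁻²).

    Off-diagonal K_ij = −γ_ij; entries outside the constraint set are
    exactly zero. ``converged`` and ``n_steps`` record the fit history.
    """

    K: np.ndarray
    constraints: ConstraintSet | None = None
    converged: bool = False
    n_steps: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.K.shape[0]

    def gamma(self, i: int, j: int) -> float:
        """Spring constant of the (i, j) interaction, γ_ij = −K_ij."""
        return -float(self.K[i, j])


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, InteractionMatrix):
        return x.K
    if isinstance(x, ScalarCovariance):
        return x.C
    return np.asarray(x, dtype=float)


def _chol_logdet(K: np.ndarray) -> float | None:
    """log det K via Cholesky; None if K is not positive definite."""
    try:
        L = np.linalg.cholesky(K)
    except np.linalg.LinAlgError:
        return None
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def objective(K, C) -> float:
    """The convex functional f(K, C) = trace(K·C) − log det K."""
    Km, Cm = _as_matrix(K), _as_matrix(C)
    logdet = _chol_logdet(Km)
    if logdet is None:
        lam = float(np.linalg.eigvalsh(Km)[0])
        raise SingularMatrixError(
            f"K not positive definite (smallest eigenvalue {lam:.3e})",
            eigenvalue=lam)
    return float(np.trace(Km @ Cm)) - logdet


def gradient(K, C) -> np.ndarray:
    """Gradient of the objective with respect to K: G = C − K⁻¹."""
    Km, Cm = _as_matrix(K), _as_matrix(C)
    if _chol_logdet(Km) is None:
        lam = float(np.linalg.eigvalsh(Km)[0])
        raise SingularMatrixError(
            f"K not positive definite (smallest eigenvalue {lam:.3e})",
            eigenvalue=lam)
    return Cm - np.linalg.inv(Km)


def residual_scale(C: np.ndarray) -> np.ndarray:
    """Per-entry scale for the convergence criterion.

    max(|C_ij|, 10⁻²·trace(C)/N) guards the relative residual against
    division blow-up where C_ij ≈ 0.
    """
    floor = 1e-2 * np.trace(C) / C.shape[0]
    return np.maximum(np.abs(C), floor)


def constraint_residual(K: np.ndarray, C: np.ndarray,
                        mask: np.ndarray) -> float:
    """Largest scaled violation |(K⁻¹)_ij − C_ij| / scale over π."""
    Kinv = np.linalg.inv(K)
    rel = np.abs(Kinv - C) / residual_scale(C)
    return float(rel[mask].max()) if mask.any() else 0.0


def _initial_K(C: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Feasible SPD start: scaled Kirchhoff of π, else diagonal 1/C_ii."""
    n = C.shape[0]
    K0 = np.zeros((n, n))
    off = mask.copy()
    np.fill_diagonal(off, False)
    K0[off] = -1.0
    np.fill_diagonal(K0, -K0.sum(axis=1))
    eig = np.linalg.eigvalsh(K0)
    if eig[0] > NULL_EIG_REL * max(eig[-1], 1.0):
        K0 *= np.trace(np.linalg.inv(K0)) / np.trace(C)
        return K0
    return np.diag(1.0 / np.diag(C))


def optimize_K(C: ScalarCovariance | np.ndarray, pi: ConstraintSet,
               settings: OptimizerSettings | None = None,
               K0: np.ndarray | None = None) -> InteractionMatrix:
    """Fit the maximum-entropy interaction matrix to constrained covariances.

    Projected gradient descent on the constrained entries,
    K ← K − η·P_π(C − K⁻¹), with a Barzilai-Borwein step-size proposal
    safeguarded by backtracking that rejects any step losing positive
    definiteness or increasing the objective. The minimum is unique, so
    initialization affects only the step count.

    If C is rank-deficient by the package pseudoinverse rule, a ridge
    ε·trace(C)/N·I is added first and recorded in the result metadata.

    Raises
    ------
    ConstraintError
        If any constrained diagonal entry of C is nonpositive.
    ConvergenceError
        If ``settings.max_steps`` is exhausted; carries the best iterate.
    """
    settings = settings or OptimizerSettings()
    Cm = np.array(_as_matrix(C), dtype=float)
    if not np.allclose(Cm, Cm.T, atol=1e-10 * max(1.0, np.abs(Cm).max())):
        raise ConstraintError("C must be symmetric")
    Cm = 0.5 * (Cm + Cm.T)
    n = Cm.shape[0]
    mask = pi.mask(n)
    meta: dict = {}
    if pi.include_diagonal and np.any(np.diag(Cm) <= 0):
        raise ConstraintError("constrained MSFs must be positive")

    eig = np.linalg.eigvalsh(Cm)
    if eig[0] <= NULL_EIG_REL * max(eig[-1], 0.0):
        ridge = settings.ridge_epsilon * np.trace(Cm) / n
        Cm = Cm + ridge * np.eye(n)
        meta["ridge"] = ridge

    K = _initial_K(Cm, mask) if K0 is None else np.array(K0, dtype=float)
    scale = residual_scale(Cm)

    # adjustable entries as a flat parameter vector (upper triangle + diag)
    ia, ja = np.nonzero(np.triu(mask))
    offdiag = ia != ja

    def residual_vec(Kinv):
        return (Kinv - Cm)[ia, ja] / scale[ia, ja]

    def insert(K, delta):
        out = K.copy()
        out[ia, ja] += delta
        out[ja[offdiag], ia[offdiag]] += delta[offdiag]
        return out

    def spring_scale(x):
        # guard against zero-crossing entries when measuring relative
        # per-step spring changes
        ref = np.abs(x[offdiag]) if offdiag.any() else np.abs(x)
        floor = 1e-2 * (float(ref.mean()) if ref.size else 1.0)
        return np.maximum(np.abs(x), floor)

    Kinv = np.linalg.inv(K)
    R = residual_vec(Kinv)
    res = float(np.abs(R).max()) if R.size else 0.0
    best = (res, K.copy(), 0)
    converged = res <= settings.tolerance
    step = 0
    while not converged and step < settings.max_steps:
        step += 1
        # Newton step for the stationarity system (K^-1)_e = C_e:
        # J[a,b] = d(K^-1)_{e_a} / dx_{e_b}, symmetrized entries
        A = Kinv[np.ix_(ia, ia)] * Kinv[np.ix_(ja, ja)]
        B = Kinv[np.ix_(ia, ja)] * Kinv[np.ix_(ja, ia)]
        J = -(A + B)
        J[:, ~offdiag] *= 0.5  # diagonal parameters enter K once
        J /= scale[ia, ja][:, None]
        try:
            delta = np.linalg.solve(J, -R)
        except np.linalg.LinAlgError:
            delta = -np.sign(R) * 0.0
        if not np.all(np.isfinite(delta)) or not np.any(delta):
            # fall back to a scaled-gradient direction
            delta = R * scale[ia, ja] / max(float(np.sum(R * R)), 1e-30)
        accepted = False
        t = 1.0
        for _ in range(60):
            K_try = insert(K, t * delta)
            if _chol_logdet(K_try) is not None:
                lam_min = float(np.linalg.eigvalsh(K_try)[0])
                if lam_min > 1e-12 * np.trace(K_try) / n:
                    Kinv_try = np.linalg.inv(K_try)
                    R_try = residual_vec(Kinv_try)
                    if np.linalg.norm(R_try) < np.linalg.norm(R):
                        accepted = True
                        break
            t *= 0.5
        if not accepted:
            break
        x_new = K_try[ia, ja]
        rel_move = float(np.max(np.abs(t * delta) / spring_scale(x_new))) \
            if x_new.size else 0.0
        K, Kinv, R = K_try, Kinv_try, R_try
        res = float(np.abs(R).max()) if R.size else 0.0
        if res < best[0]:
            best = (res, K.copy(), step)
        # converged once every constrained covariance is reproduced to
        # tolerance AND the interactions themselves have stopped moving
        # by more than tolerance in relative terms
        if res <= settings.tolerance and rel_move <= settings.tolerance:
            converged = True

    if not converged:
        result = InteractionMatrix(K=best[1], constraints=pi,
                                   converged=False, n_steps=step,
                                   meta=meta)
        raise ConvergenceError(
            f"no convergence in {step} steps "
            f"(best residual {best[0]:.3e} > tol {settings.tolerance})",
            best=result, residual=best[0])

    K = np.where(mask | np.eye(n, dtype=bool), K, 0.0)
    return InteractionMatrix(K=0.5 * (K + K.T), constraints=pi,
                             converged=True, n_steps=step, meta=meta)


def covariance_from_K(K: InteractionMatrix | np.ndarray,
                      n_models: int = 0) -> ScalarCovariance:
    """Model covariance predicted by an interaction matrix, C = K⁺.

    Uses the package pseudoinverse rule: eigenvalues below 10⁻⁸ of the
    largest are discarded as null modes.
    """
    Km = _as_matrix(K)
    lam, vec = np.linalg.eigh(Km)
    keep = lam > NULL_EIG_REL * lam[-1]
    C = (vec[:, keep] / lam[keep]) @ vec[:, keep].T
    return ScalarCovariance(C=C, n_models=n_models,
                            meta={"null_modes": int((~keep).sum())})


def force_constant_table(K: InteractionMatrix, structure: MeanStructure,
                         annotations=None) -> pd.DataFrame:
    """Per-edge table of fitted spring constants with annotations.

    One row per off-diagonal constrained pair: 1-based residue positions
    i < j, Cα distance d (Å) in the mean structure, contact order
    k = |i−j|, spring constant gamma = −K_ij, secondary-structure codes
    of both residues, and whether the pair is backbone hydrogen-bonded.
    """
    if K.constraints is None:
        raise ConstraintError("interaction matrix has no constraint set")
    rows = []
    coords = structure.coords
    for i, j in K.constraints.pairs:
        d = float(np.linalg.norm(coords[i] - coords[j]))
        ss_i = ss_j = "other"
        hbond = False
        if annotations is not None:
            ss_i = annotations[i].ss_code
            ss_j = annotations[j].ss_code
            hbond = j in annotations[i].hbond_partners
        rows.append((i + 1, j + 1, d, abs(i - j), -float(K.K[i, j]),
                     ss_i, ss_j, hbond))
    return pd.DataFrame(rows, columns=["i", "j", "d", "k", "gamma",
                                       "ss_i", "ss_j", "hbond"])


def normalize_ofc(table: pd.DataFrame) -> pd.DataFrame:
    """Scale spring constants so their mean magnitude is unity.

    Normalization removes per-protein environmental scale (covariance
    magnitude trades off inversely with interaction magnitude), making
    force constants comparable across proteins. The mean runs over
    nonzero off-diagonal constrained pairs.
    """
    nonzero = table["gamma"] != 0.0
    if not nonzero.any():
        raise NormalizationError("all force constants are zero")
    scale = table.loc[nonzero, "gamma"].abs().mean()
    out = table.copy()
    out["gamma"] = out["gamma"] / scale
    return out


def to_physical_units(K: InteractionMatrix,
                      temperature: float = 300.0) -> InteractionMatrix:
    """Convert Å⁻² interaction units to kcal/mol/Å² by the factor 3·k_B·T."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    factor = 3.0 * KB_KCAL * temperature
    out = replace(K, K=K.K * factor, meta=dict(K.meta))
    out.meta["units"] = "kcal/mol/A^2"
    out.meta["temperature_K"] = temperature
    return out


def prune_weak_interactions(K: InteractionMatrix,
                            fraction: float) -> InteractionMatrix:
    """Zero the weakest |γ| fraction of constrained off-diagonal pairs.

    The pruned pairs leave the constraint set; ties in |γ| are broken by
    ascending pair index. The pruned network's covariance is obtained
    with :func:`covariance_from_K` (pseudoinverse), mirroring the
    robustness probe of discarding the smallest interactions.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    if K.constraints is None:
        raise ConstraintError("interaction matrix has no constraint set")
    pairs = list(K.constraints.pairs)
    n_drop = int(round(fraction * len(pairs)))
    if n_drop == 0:
        return replace(K, meta=dict(K.meta))
    order = sorted(pairs, key=lambda p: (abs(K.K[p[0], p[1]]), p))
    drop = set(order[:n_drop])
    keep = [p for p in pairs if p not in drop]
    Knew = K.K.copy()
    for i, j in drop:
        Knew[i, j] = Knew[j, i] = 0.0
    return InteractionMatrix(
        K=Knew,
        constraints=ConstraintSet(pairs=tuple(keep),
                                  include_diagonal=K.constraints.include_diagonal),
        converged=K.converged, n_steps=K.n_steps,
        meta={**K.meta, "pruned": n_drop})
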