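"""Statistical characterization of fitted force constants.

Groups spring constants by contact order, secondary structure or
hydrogen bonding; summarizes the decay of interaction magnitude with
distance and fits it to the two standard functional forms (Gaussian
A·exp(−d²/r₀²) and inverse power A/d^α); computes correlations between
force constants of nested contact orders; and measures how well a model
covariance reproduces an observed one, split by element type (MSFs,
interacting pairs, non-interacting pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .enm import ContactTopology, WeightedNetwork
from .ensemble import ScalarCovariance
from .exceptions import FitError, InsufficientDataError
from .maxent import InteractionMatrix, covariance_from_K


@dataclass
class StratifiedStats:
    """Per-group summary of a force-constant table."""

    key: str
    table: pd.DataFrame  # columns: group, mean, std, count
    histograms: dict = field(default_factory=dict)  # group -> (edges, counts)

    def group(self, name) -> pd.Series:
        return self.table.set_index("group").loc[name]


@dataclass
class DistanceFit:
    """Fitted distance dependence of mean force-constant magnitude."""

    form: str            # "gaussian" or "power"
    amplitude: float
    parameter: float     # r0 (Å) for gaussian, exponent alpha for power
    correlation: float

    def predict(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        if self.form == "gaussian":
            return self.amplitude * np.exp(-d ** 2 / self.parameter ** 2)
        return self.amplitude / d ** self.parameter


_GROUP_KEYS = ("k", "ss_pair", "hbond", "aa_pair")


def _group_labels(table: pd.DataFrame, key: str) -> pd.Series:
    if key == "k":
        return table["k"]
    if key == "hbond":
        return table["hbond"]
    if key == "ss_pair":
        return table.apply(
            lambda r: "-".join(sorted((r["ss_i"], r["ss_j"]))), axis=1)
    if key == "aa_pair":
        return table.apply(
            lambda r: "-".join(sorted((r["aa_i"], r["aa_j"]))), axis=1)
    raise KeyError(f"unknown grouping key {key!r}; use one of {_GROUP_KEYS}")


def stratify(table: pd.DataFrame, key: str = "k",
             bin_width: float = 0.25) -> StratifiedStats:
    """Group force constants and summarize each group.

    Means/SDs are exact group statistics (population SD); a histogram of
    the constants is attached per group with the given bin width in the
    table's γ units (0.25 in normalized units by default).
    """
    if table.empty:
        raise InsufficientDataError("empty force-constant table")
    labels = _group_labels(table, key)
    rows, hists = [], {}
    for name, grp in table.groupby(labels)["gamma"]:
        values = grp.to_numpy()
        rows.append((name, float(values.mean()), float(values.std()),
                     len(values)))
        lo = np.floor(values.min() / bin_width) * bin_width
        hi = np.ceil(values.max() / bin_width) * bin_width + bin_width / 2
        edges = np.arange(lo, hi + bin_width, bin_width)
        counts, edges = np.histogram(values, bins=edges)
        hists[name] = (edges, counts)
    stats = pd.DataFrame(rows, columns=["group", "mean", "std", "count"])
    return StratifiedStats(key=key, table=stats, histograms=hists)


def mean_magnitude_vs_distance(table: pd.DataFrame,
                               bin_width: float = 0.5) -> pd.DataFrame:
    """Average |γ| per distance bin; empty bins are omitted.

    Returns a frame with columns ``d`` (bin center, Å), ``mean_abs_gamma``
    and ``count``.
    """
    if table.empty:
        raise InsufficientDataError("empty force-constant table")
    d = table["d"].to_numpy()
    g = np.abs(table["gamma"].to_numpy())
    idx = np.floor(d / bin_width).astype(int)
    rows = []
    for b in np.unique(idx):
        sel = idx == b
        rows.append(((b + 0.5) * bin_width, g[sel].mean(), int(sel.sum())))
    return pd.DataFrame(rows, columns=["d", "mean_abs_gamma", "count"])


def _corr_for_param(d, y, form, p) -> float:
    model = np.exp(-d ** 2 / p ** 2) if form == "gaussian" else d ** (-p)
    if np.std(model) == 0:
        return -1.0
    return float(np.corrcoef(model, y)[0, 1])


def fit_distance_dependence(curve: pd.DataFrame,
                            form: str = "gaussian",
                            bounds: tuple[float, float] | None = None
                            ) -> DistanceFit:
    """Fit ⟨|γ|⟩(d) to A·exp(−d²/r₀²) or A/d^α by correlation maximization.

    The shape parameter (r₀ or α) maximizes the Pearson correlation
    between the model curve and the binned means (coarse grid scan
    refined by bounded scalar optimization — correlation is independent
    of the amplitude); the amplitude is then set by least squares.
    """
    if form not in ("gaussian", "power"):
        raise ValueError("form must be 'gaussian' or 'power'")
    if len(curve) < 3:
        raise InsufficientDataError("need >=3 distance bins to fit")
    d = curve["d"].to_numpy(dtype=float)
    y = curve["mean_abs_gamma"].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise FitError("constant curve: distance fit undefined")
    if bounds is None:
        bounds = (0.5, 50.0) if form == "gaussian" else (0.1, 8.0)
    grid = np.linspace(bounds[0], bounds[1], 200)
    cc_grid = np.array([_corr_for_param(d, y, form, p) for p in grid])
    best = int(np.argmax(cc_grid))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = minimize_scalar(lambda p: -_corr_for_param(d, y, form, p),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    p = float(res.x)
    model = np.exp(-d ** 2 / p ** 2) if form == "gaussian" else d ** (-p)
    amp = float(model @ y / (model @ model))
    return DistanceFit(form=form, amplitude=amp, parameter=p,
                       correlation=_corr_for_param(d, y, form, p))


def inter_order_correlation(table: pd.DataFrame, k: int, n: int,
                            scope: str = "all") -> float:
    """Correlation between order-k constants and nested order-n averages.

    For each position i with a defined γ_{i,i+k}, the comparator is the
    average of the k−n+1 order-n constants nested within the span,
    γ̄ = mean(γ_{j,j+n}, j = i..i+k−n); the returned value is the Pearson
    correlation of the two series over positions where every nested
    constant is present. ``scope`` restricts to pairs whose residues all
    carry the helix ("helix") or strand ("strand") code.
    """
    if not n < k:
        raise ValueError("need n < k")
    if scope not in ("all", "helix", "strand"):
        raise ValueError("scope must be all/helix/strand")
    want = {"helix": "H", "strand": "E"}.get(scope)

    gam: dict[tuple[int, int], float] = {}
    ss: dict[int, str] = {}
    for row in table.itertuples():
        gam[(row.i, row.j)] = row.gamma
        ss[row.i], ss[row.j] = row.ss_i, row.ss_j

    def pair_ok(a, b):
        if (a, b) not in gam:
            return False
        return want is None or (ss.get(a) == want and ss.get(b) == want)

    xs, ys = [], []
    for i in sorted({a for a, b in gam if b - a == k}):
        if not pair_ok(i, i + k):
            continue
        nested = [(j, j + n) for j in range(i, i + k - n + 1)]
        if not all(pair_ok(a, b) for a, b in nested):
            continue
        xs.append(gam[(i, i + k)])
        ys.append(np.mean([gam[p] for p in nested]))
    if len(xs) < 3:
        raise InsufficientDataError(
            f"only {len(xs)} positions with complete order-{k}/{n} data")
    return float(np.corrcoef(xs, ys)[0, 1])


def node_weight_vs_msf(model: InteractionMatrix | WeightedNetwork,
                       C: ScalarCovariance) -> tuple[pd.DataFrame, float]:
    """Node weights against MSFs, and the correlation of MSF with 1/weight.

    The weight of node i is Σ_j |γ_ij| for a fitted interaction matrix
    and the degree (edge count) for a GNM-style network. A degenerate
    (constant) weight vector yields NaN correlation.
    """
    if isinstance(model, WeightedNetwork):
        weights = model.degrees.astype(float)
    else:
        off = model.K - np.diag(np.diag(model.K))
        weights = np.abs(off).sum(axis=1)
    msf = C.msf
    frame = pd.DataFrame({"weight": weights, "msf": msf})
    if np.std(weights) == 0 or np.std(msf) == 0:
        return frame, float("nan")
    return frame, float(np.corrcoef(1.0 / weights, msf)[0, 1])


def covariance_agreement(C_obs: ScalarCovariance | np.ndarray,
                         C_pred: ScalarCovariance | np.ndarray,
                         topology: ContactTopology,
                         n_modes: int | None = None) -> dict[str, float]:
    """Element-type-resolved agreement between two covariance matrices.

    Pearson correlations over four element classes: ``msf`` (diagonals),
    ``interacting`` (off-diagonal pairs joined by a network edge),
    ``non_interacting`` (remaining off-diagonal pairs) and ``all``
    (every off-diagonal pair). With ``n_modes`` set, both matrices are
    first replaced by their rank-m reconstruction from the m
    largest-variance modes (the "top modes" variant).
    """
    A = C_obs.C if isinstance(C_obs, ScalarCovariance) else np.asarray(C_obs)
    B = C_pred.C if isinstance(C_pred, ScalarCovariance) else np.asarray(C_pred)
    if A.shape != B.shape:
        raise ValueError("covariance shapes differ")
    if n_modes is not None:
        A = _lowrank(A, n_modes)
        B = _lowrank(B, n_modes)
    n = A.shape[0]
    inter = np.zeros((n, n), dtype=bool)
    for i, j in topology.edges:
        inter[i, j] = inter[j, i] = True
    offdiag = ~np.eye(n, dtype=bool)
    out = {}
    for name, sel in (("msf", np.eye(n, dtype=bool)),
                      ("interacting", inter),
                      ("non_interacting", offdiag & ~inter),
                      ("all", offdiag)):
        a, b = A[sel], B[sel]
        if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
            out[name] = float("nan")
        else:
            out[name] = float(np.corrcoef(a, b)[0, 1])
    return out


def _lowrank(M: np.ndarray, m: int) -> np.ndarray:
    lam, vec = np.linalg.eigh(M)
    order = np.argsort(-lam)[:m]
    return (vec[:, order] * lam[order]) @ vec[:, order].T


def ofc_gnm_agreement(K: InteractionMatrix, C_obs: ScalarCovariance,
                      topology: ContactTopology,
                      n_modes: int | None = None) -> dict[str, float]:
    """Agreement of the fitted-K model covariance with the observed one."""
    return covariance_agreement(C_obs, covariance_from_K(K.K), topology,
                                n_modes=n_modes)
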