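"""Population-spread statistics: mean squared displacement, quantile fronts,
diffusion coefficients, changepoint detection and replicate-level inference.

The central quantity is the mean squared displacement of the detected
population at minute ``t``,

    MSD_t = (1/N_t) * sum_i x_it^2 ,

with ``N_t`` the number of detections at ``t`` and ``x_it`` signed linear
positions (cm).  Detections within a moving window are pooled across
replicates, so replicates contribute in proportion to their detection
counts.  The diffusion coefficient ``D`` is, operationally, the OLS slope of
MSD against time (cm²·min⁻¹; also reported in m²·h⁻¹, factor 0.006), with an
initial transient excluded from the fit.  Departures from linear (diffusive)
growth are assessed with a continuous two-segment (piecewise linear)
regression whose significance is bootstrapped.  Uncertainty on any
replicate-level statistic uses the percentile bootstrap, always resampling
whole replicates (detections within a replicate are autocorrelated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DiffusionFit",
    "compute_msd",
    "compute_quantiles",
    "fit_diffusion",
    "fit_piecewise",
    "piecewise_significance",
    "bootstrap_ci",
    "compare_treatments",
    "CM2_PER_MIN_TO_M2_PER_H",
]

#: cm² min⁻¹ → m² h⁻¹
CM2_PER_MIN_TO_M2_PER_H = 60.0 / 1e4


@dataclass
class DiffusionFit:
    """Result of a linear or piecewise-linear fit of MSD against time.

    ``D`` is the slope in cm²·min⁻¹ (``D_m2h`` in m²·h⁻¹); for a piecewise
    fit ``breakpoint`` is the changepoint (min) and ``D_before``/``D_after``
    the two segment slopes, with ``p_piecewise`` the bootstrap p-value of the
    improvement over a single line.  ``edge_breakpoint`` flags a breakpoint
    on the boundary of the searched window (unreliable).
    """

    D: float
    intercept: float
    t_min: float
    t_max: float
    rss: float
    breakpoint: float | None = None
    D_before: float | None = None
    D_after: float | None = None
    p_piecewise: float | None = None
    edge_breakpoint: bool = False

    @property
    def D_m2h(self) -> float:
        return self.D * CM2_PER_MIN_TO_M2_PER_H

    def to_dict(self) -> dict:
        d = {
            "D_cm2_min": self.D,
            "D_m2_h": self.D_m2h,
            "intercept": self.intercept,
            "t_min": self.t_min,
            "t_max": self.t_max,
            "rss": self.rss,
        }
        if self.breakpoint is not None:
            d.update(
                breakpoint=self.breakpoint,
                D_before_cm2_min=self.D_before,
                D_after_cm2_min=self.D_after,
                D_before_m2_h=self.D_before * CM2_PER_MIN_TO_M2_PER_H,
                D_after_m2_h=self.D_after * CM2_PER_MIN_TO_M2_PER_H,
                p_piecewise=self.p_piecewise,
                edge_breakpoint=self.edge_breakpoint,
            )
        return d


def _window_pool(table: pd.DataFrame, window: float):
    """Yield (t, pooled positions) for every integer minute, pooling
    detections within [t-window, t+window] across replicates."""
    t_arr = table["t"].to_numpy(dtype=float)
    x_arr = table["s"].to_numpy(dtype=float)
    order = np.argsort(t_arr, kind="stable")
    t_arr, x_arr = t_arr[order], x_arr[order]
    t_grid = np.arange(1, int(np.max(t_arr)) + 1)
    lo = np.searchsorted(t_arr, t_grid - window - 1e-9, side="left")
    hi = np.searchsorted(t_arr, t_grid + window + 1e-9, side="right")
    return t_grid, x_arr, lo, hi


def compute_msd(table: pd.DataFrame, window: float = 7.0) -> pd.DataFrame:
    """Mean squared displacement series over moving windows of ±``window`` min.

    Detections from all replicates within the window are pooled, which
    weights replicates by their detection counts.  Minutes with no
    detections yield NaN (a gap), never zero.

    Returns a DataFrame with columns ``t, msd, n_detections``.
    """
    if table.empty:
        raise ValueError("detection table is empty")
    if window < 0:
        raise ValueError("window must be non-negative")
    t_grid, x_arr, lo, hi = _window_pool(table, window)
    x2 = np.concatenate([[0.0], np.cumsum(x_arr**2)])
    n = hi - lo
    with np.errstate(invalid="ignore"):
        msd = np.where(n > 0, (x2[hi] - x2[lo]) / np.maximum(n, 1), np.nan)
    return pd.DataFrame({"t": t_grid, "msd": msd, "n_detections": n})


def compute_quantiles(
    table: pd.DataFrame,
    p_list=(50, 75, 90, 95, 98, 99),
    window: float = 7.0,
) -> pd.DataFrame:
    """Population-quantile series: the distance from the release point within
    which p% of detected individuals are found.

    Quantiles are computed on absolute distance |x| over the pooled window,
    with the linear-interpolation percentile convention.  Returns a tidy
    DataFrame with columns ``t, p, q, n_detections``.
    """
    for p in p_list:
        if not 0 < p < 100:
            raise ValueError(f"percentage {p} outside (0, 100)")
    t_grid, x_arr, lo, hi = _window_pool(table, window)
    absx = np.abs(x_arr)
    rows = []
    p_arr = np.asarray(p_list, dtype=float)
    for i, t in enumerate(t_grid):
        xs = absx[lo[i]:hi[i]]
        if xs.size == 0:
            q = np.full(p_arr.size, np.nan)
        else:
            q = np.percentile(xs, p_arr)
        for pj, qj in zip(p_list, q):
            rows.append((t, pj, qj, xs.size))
    return pd.DataFrame(rows, columns=["t", "p", "q", "n_detections"])


def _valid_window(series: pd.DataFrame, t_min: float, y_col: str):
    sub = series.dropna(subset=[y_col])
    sub = sub[sub["t"] >= t_min]
    return sub["t"].to_numpy(dtype=float), sub[y_col].to_numpy(dtype=float)


def fit_diffusion(series: pd.DataFrame, t_min: float = 30.0, y_col: str = "msd") -> DiffusionFit:
    """OLS fit of MSD against time over ``t >= t_min``.

    The slope is the diffusion coefficient in the operational sense used
    throughout the package (no 1/2 or 2 factor).  The initial transient
    (default first 30 min: release conditions and latency phase) is
    excluded.
    """
    t, y = _valid_window(series, t_min, y_col)
    if t.size < 2:
        raise ValueError("need at least 2 time points after exclusion")
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return DiffusionFit(
        D=float(beta[1]),
        intercept=float(beta[0]),
        t_min=float(t.min()),
        t_max=float(t.max()),
        rss=float(resid @ resid),
    )


def _piecewise_scan(t: np.ndarray, y: np.ndarray, candidates: np.ndarray):
    """Best continuous two-segment fit over candidate breakpoints.

    Model: y = a + b*t + c*(t - bp)_+ ; returns (bp, a, b, c, rss)."""
    best = (np.nan, 0.0, 0.0, 0.0, np.inf)
    ones = np.ones_like(t)
    for bp in candidates:
        hinge = np.maximum(t - bp, 0.0)
        X = np.column_stack([ones, t, hinge])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        if rss < best[4]:
            best = (float(bp), float(beta[0]), float(beta[1]), float(beta[2]), rss)
    return best


def fit_piecewise(
    series: pd.DataFrame,
    t_min: float = 30.0,
    y_col: str = "msd",
    bootstrap_B: int = 0,
    seed: int = 0,
    n_candidates: int = 200,
) -> DiffusionFit:
    """Continuous two-segment (piecewise linear) fit of MSD against time.

    The breakpoint is found by grid search over interior times minimising the
    residual sum of squares.  When ``bootstrap_B > 0`` a p-value for the
    improvement over a single straight line is computed by a residual
    bootstrap under the single-line null: the relative RSS improvement
    ``(RSS_lin - RSS_pw) / RSS_pw`` of the data is compared to its null
    distribution on surrogate series built from the linear fit plus resampled
    linear-fit residuals.  (For treatment-level series with replicate
    structure, prefer :func:`piecewise_significance`.)
    """
    t, y = _valid_window(series, t_min, y_col)
    if t.size < 10:
        raise ValueError("need at least 10 time points for a piecewise fit")
    lin = fit_diffusion(series, t_min, y_col)

    inner = t[2:-2]
    candidates = np.unique(
        inner if inner.size <= n_candidates
        else np.quantile(inner, np.linspace(0, 1, n_candidates))
    )
    bp, a, b, c, rss = _piecewise_scan(t, y, candidates)
    edge = bp <= candidates[0] or bp >= candidates[-1]
    stat_obs = (lin.rss - rss) / rss if rss > 0 else np.inf

    p_val = None
    if bootstrap_B > 0:
        rng = np.random.default_rng(seed)
        resid = y - (lin.intercept + lin.D * t)
        exceed = 0
        for _ in range(bootstrap_B):
            y_b = lin.intercept + lin.D * t + rng.choice(resid, size=resid.size, replace=True)
            Xl = np.column_stack([np.ones_like(t), t])
            beta_l, *_ = np.linalg.lstsq(Xl, y_b, rcond=None)
            rss_l = float(np.sum((y_b - Xl @ beta_l) ** 2))
            *_, rss_p = _piecewise_scan(t, y_b, candidates)
            stat_b = (rss_l - rss_p) / rss_p if rss_p > 0 else np.inf
            exceed += stat_b >= stat_obs
        p_val = (exceed + 1) / (bootstrap_B + 1)

    return DiffusionFit(
        D=lin.D,
        intercept=float(a),
        t_min=float(t.min()),
        t_max=float(t.max()),
        rss=rss,
        breakpoint=bp,
        D_before=float(b),
        D_after=float(b + c),
        p_piecewise=p_val,
        edge_breakpoint=bool(edge),
    )


def piecewise_significance(
    table: pd.DataFrame,
    window: float = 7.0,
    t_min: float = 30.0,
    B: int = 200,
    seed: int = 0,
) -> dict:
    """Replicate-bootstrap test for a change of diffusion slope.

    Resamples whole replicates with replacement, recomputes the pooled MSD
    series and the piecewise fit, and collects the slope difference
    ``D_after - D_before``.  The two-sided p-value is the percentile-bootstrap
    probability that the slope difference crosses zero; the bootstrap unit is
    the replicate, never the detection.

    Returns a dict with the observed fit, the slope-difference CI and p.
    """
    reps = table["replicate"].unique()
    obs = fit_piecewise(compute_msd(table, window), t_min)
    rng = np.random.default_rng(seed)
    grouped = {r: sub for r, sub in table.groupby("replicate")}
    diffs = np.empty(B)
    for b in range(B):
        pick = rng.choice(reps, size=reps.size, replace=True)
        boot = pd.concat([grouped[r] for r in pick], ignore_index=True)
        fit_b = fit_piecewise(compute_msd(boot, window), t_min)
        diffs[b] = fit_b.D_after - fit_b.D_before
    frac_pos = np.mean(diffs > 0)
    p = 2.0 * min(frac_pos, 1.0 - frac_pos)
    p = min(max(p, 1.0 / B), 1.0)
    return {
        "fit": obs,
        "slope_diff": obs.D_after - obs.D_before,
        "slope_diff_ci": tuple(np.percentile(diffs, [2.5, 97.5])),
        "p_piecewise": p,
    }


def bootstrap_ci(
    statistic,
    replicates,
    B: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
):
    """Percentile-bootstrap CI of a statistic of a set of replicates.

    ``statistic`` maps a list of replicate objects to a scalar or 1-D array;
    whole replicates are resampled with replacement ``B`` times and the
    ``alpha/2`` and ``1 - alpha/2`` percentiles of the recomputed statistic
    are returned as ``(low, high)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    replicates = list(replicates)
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    vals = []
    n = len(replicates)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        vals.append(statistic([replicates[i] for i in idx]))
    vals = np.asarray(vals, dtype=float)
    lo, hi = np.nanpercentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    return lo, hi


def compare_treatments(values_by_treatment: dict, fdr: bool = True) -> pd.DataFrame:
    """Pairwise rank tests on per-replicate statistics across treatments.

    Uses the two-sided Wilcoxon rank-sum test for every treatment pair
    (treatments are independent replicate sets) with Benjamini–Hochberg
    adjustment across the family.  Groups with fewer than 3 replicates are
    flagged ``underpowered``.

    Returns a DataFrame with columns ``group_a, group_b, statistic, p,
    p_adjusted, underpowered``.
    """
    names = list(values_by_treatment)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            xa = np.asarray(values_by_treatment[a], dtype=float)
            xb = np.asarray(values_by_treatment[b], dtype=float)
            if np.array_equal(xa, xb):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.ranksums(xa, xb)
            rows.append((a, b, float(stat), float(p), xa.size < 3 or xb.size < 3))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p", "underpowered"])
    if fdr:
        df["p_adjusted"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["p_adjusted"] = df["p"]
    return df
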