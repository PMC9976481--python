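"""Centred distribution fits and the resident/explorer decomposition.

During population spread the distribution of signed positions is symmetric
about the release point but strongly leptokurtic: a narrow core of *resident*
individuals plus broad tails of *explorer* individuals.  This module fits,
by maximum likelihood, a family of zero-mean candidate models to pooled
positions —

* a centred Gaussian (classical diffusion),
* zero-mean Gaussian mixtures with 2 or 3 components (discrete behavioural
  modes; EM with means pinned at 0),
* a centred Student t (a continuous scale-mixture of Gaussians, i.e. fully
  heterogeneous diffusivities),

compares them with AIC, and tracks the two-component decomposition through
time: the explorer weight pi_e(t), the component scales sigma_r(t) <
sigma_e(t), and the explorer-component MSD sigma_e(t)^2, whose growth rate is
the explorer diffusion coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from spiralspread.spread_stats import DiffusionFit, fit_diffusion, fit_piecewise

__all__ = [
    "MixtureFit",
    "StudentFit",
    "fit_centred_mixture",
    "fit_centred_student",
    "select_model",
    "track_components",
    "component_diffusion",
    "gaussianity_diagnostics",
]

_SCALE_FLOOR = 1e-8
_NU_CAP = 1e3


@dataclass
class MixtureFit:
    """A zero-mean Gaussian mixture fit.

    ``weights`` and ``scales`` are sorted by increasing scale, so for K=2
    component 0 is the resident (narrow) and component 1 the explorer
    (broad) component.  ``AIC = 2*(2K-1) - 2*loglik`` (zero means are fixed,
    so a K-component mixture has K scales and K-1 free weights).
    """

    K: int
    weights: np.ndarray
    scales: np.ndarray
    loglik: float
    n: int
    converged: bool = True
    degenerate: bool = False

    @property
    def aic(self) -> float:
        return 2.0 * (2 * self.K - 1) - 2.0 * self.loglik

    @property
    def effectively_unimodal(self) -> bool:
        """Scales closer than 10% are reported as a single effective mode."""
        return self.K >= 2 and self.scales[-1] / max(self.scales[0], _SCALE_FLOOR) < 1.1

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return sum(
            w * stats.norm.pdf(x, 0.0, s) for w, s in zip(self.weights, self.scales)
        )

    def to_dict(self) -> dict:
        return {
            "model": f"gmix{self.K}" if self.K > 1 else "gaussian",
            "K": self.K,
            "weights": self.weights.tolist(),
            "scales": self.scales.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "n": self.n,
            "converged": self.converged,
            "degenerate": self.degenerate,
        }


@dataclass
class StudentFit:
    """A centred Student-t fit: scale (cm) and degrees of freedom nu.

    ``AIC = 2*2 - 2*loglik``; nu is capped at 1e3, the practical Gaussian
    limit."""

    scale: float
    df: float
    loglik: float
    n: int
    converged: bool = True

    @property
    def aic(self) -> float:
        return 4.0 - 2.0 * self.loglik

    def to_dict(self) -> dict:
        return {
            "model": "student",
            "scale": self.scale,
            "df": self.df,
            "loglik": self.loglik,
            "aic": self.aic,
            "n": self.n,
            "converged": self.converged,
        }


def _em_zero_mean(x2: np.ndarray, weights: np.ndarray, scales: np.ndarray,
                  tol: float = 1e-8, max_iter: int = 500):
    """EM for a zero-mean Gaussian mixture; operates on squared data.

    Returns (weights, scales, loglik, converged, loglik_trace)."""
    n = x2.size
    ll_old = -np.inf
    trace = []
    converged = False
    for _ in range(max_iter):
        var = np.maximum(scales**2, _SCALE_FLOOR**2)
        # log component densities, (n, K)
        logp = -0.5 * (np.log(2.0 * np.pi * var)[None, :] + x2[:, None] / var[None, :])
        logp = logp + np.log(np.maximum(weights, 1e-300))[None, :]
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        trace.append(ll)
        resp = np.exp(logp - lse[:, None])
        nk = resp.sum(axis=0)
        weights = nk / n
        scales = np.sqrt(np.maximum((resp * x2[:, None]).sum(axis=0) / np.maximum(nk, 1e-300),
                                    _SCALE_FLOOR**2))
        if ll - ll_old < tol * max(1.0, abs(ll)) and ll >= ll_old - 1e-9:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    return weights, scales, ll_old, converged, trace


def fit_centred_mixture(
    x,
    K: int = 2,
    n_starts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    return_trace: bool = False,
):
    """Maximum-likelihood zero-mean Gaussian mixture via EM.

    All component means are pinned at 0 (release-point symmetry); only the
    weights and scales are updated.  ``n_starts`` seeded initialisations are
    run (scales jittered around {0.5, ..., 2} x sample SD, equal weights)
    and the best log-likelihood is kept.  Components are returned sorted by
    scale.  K=1 reduces to the closed-form centred Gaussian MLE
    sigma^2 = sum(x^2)/n.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 10 * K:
        raise ValueError(f"need at least {10 * K} observations for K={K}")
    x2 = x**2
    if K == 1:
        sigma = float(np.sqrt(x2.mean()))
        sigma = max(sigma, _SCALE_FLOOR)
        ll = float(np.sum(stats.norm.logpdf(x, 0.0, sigma)))
        fit = MixtureFit(1, np.array([1.0]), np.array([sigma]), ll, n)
        return (fit, [ll]) if return_trace else fit

    sd = max(float(np.sqrt(x2.mean())), _SCALE_FLOOR)
    rng = np.random.default_rng(seed)
    base = np.geomspace(0.5, 2.0, K) * sd
    best = None
    best_trace = None
    for start in range(n_starts):
        scales0 = base if start == 0 else base * np.exp(rng.normal(0.0, 0.5, K))
        w, s, ll, conv, trace = _em_zero_mean(
            x2, np.full(K, 1.0 / K), scales0.copy(), tol, max_iter
        )
        if best is None or ll > best[2]:
            best = (w, s, ll, conv)
            best_trace = trace
    w, s, ll, conv = best
    order = np.argsort(s)
    w, s = w[order], s[order]
    degenerate = bool(np.any(s <= _SCALE_FLOOR * 10) or np.any(w < 1e-6))
    fit = MixtureFit(K, w, s, ll, n, converged=conv, degenerate=degenerate)
    return (fit, best_trace) if return_trace else fit


def fit_centred_student(x, nu_cap: float = _NU_CAP) -> StudentFit:
    """Maximum-likelihood centred Student-t fit (location fixed at 0).

    Optimises (log scale, log nu) numerically; nu is capped at ``nu_cap``
    (the Gaussian limit), where the fit is refreshed at the boundary."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 10:
        raise ValueError("need at least 10 observations")
    sd = max(float(np.std(x)), _SCALE_FLOOR)

    def nll(params):
        log_scale, log_nu = params
        scale = np.exp(log_scale)
        nu = np.exp(log_nu)
        return -np.sum(stats.t.logpdf(x, df=nu, loc=0.0, scale=scale))

    best = None
    for nu0 in (3.0, 30.0):
        res = optimize.minimize(
            nll,
            x0=[np.log(sd), np.log(nu0)],
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    scale = float(np.exp(best.x[0]))
    nu = float(np.exp(best.x[1]))
    converged = bool(best.success)
    if nu >= nu_cap:
        nu = nu_cap
        # profile the scale at the capped nu
        res = optimize.minimize_scalar(
            lambda ls: -np.sum(stats.t.logpdf(x, df=nu, loc=0.0, scale=np.exp(ls))),
            bounds=(np.log(sd) - 3, np.log(sd) + 3),
            method="bounded",
        )
        scale = float(np.exp(res.x))
    ll = float(np.sum(stats.t.logpdf(x, df=nu, loc=0.0, scale=scale)))
    return StudentFit(scale=scale, df=nu, loglik=ll, n=x.size, converged=converged)


def select_model(x, seed: int = 0) -> dict:
    """Fit all four centred candidates and rank them by AIC.

    Returns ``{"fits": {name: fit}, "aic": {name: aic}, "best": name,
    "ranking": [names]}`` over Gaussian, 2- and 3-component zero-mean
    Gaussian mixtures, and the centred Student t.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 30:
        raise ValueError("need at least 30 observations for model selection")
    fits = {
        "gaussian": fit_centred_mixture(x, K=1),
        "gmix2": fit_centred_mixture(x, K=2, seed=seed),
        "gmix3": fit_centred_mixture(x, K=3, seed=seed),
        "student": fit_centred_student(x),
    }
    aic = {k: f.aic for k, f in fits.items()}
    ranking = sorted(aic, key=aic.get)
    return {"fits": fits, "aic": aic, "best": ranking[0], "ranking": ranking}


def track_components(
    table: pd.DataFrame,
    grid_step: float = 15.0,
    window: float = 10.0,
    B: int = 600,
    min_pooled: int = 50,
    reliable_after: float = 60.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Time-resolved resident/explorer decomposition.

    Every ``grid_step`` minutes, detections within a ``window``-minute window
    (i.e. ±window/2) are pooled across replicates and a two-component
    zero-mean mixture is fitted; the explorer weight, both scales and the
    explorer-component MSD (sigma_e^2) are recorded, with replicate-bootstrap
    percentile CIs (``B`` resamplings) on the explorer weight.  Estimates
    before ``reliable_after`` minutes are flagged unreliable (the
    distribution is still near-Gaussian there and the decomposition is
    weakly identified).  Windows with fewer than ``min_pooled`` detections
    are skipped.

    Returns a DataFrame with columns ``t, pi_explorer, pi_ci_low, pi_ci_high,
    sigma_resident, sigma_explorer, msd_explorer, n, reliable``.
    """
    rng = np.random.default_rng(seed)
    t_max = float(table["t"].max())
    grid = np.arange(grid_step, t_max + 1e-9, grid_step)
    reps = table["replicate"].unique()
    by_rep = {r: sub for r, sub in table.groupby("replicate")}
    half = window / 2.0
    rows = []
    for tc in grid:
        mask = (table["t"] >= tc - half) & (table["t"] <= tc + half)
        x = table.loc[mask, "s"].to_numpy(dtype=float)
        if x.size < min_pooled:
            continue
        fit = fit_centred_mixture(x, K=2, seed=seed)
        pi_e = float(fit.weights[1])
        ci = (np.nan, np.nan)
        if B > 0 and reps.size >= 2:
            boot = np.empty(B)
            for b in range(B):
                pick = rng.choice(reps, size=reps.size, replace=True)
                xb = np.concatenate(
                    [
                        by_rep[r].loc[
                            (by_rep[r]["t"] >= tc - half) & (by_rep[r]["t"] <= tc + half), "s"
                        ].to_numpy(dtype=float)
                        for r in pick
                    ]
                )
                if xb.size < min_pooled:
                    boot[b] = np.nan
                    continue
                fb = fit_centred_mixture(xb, K=2, n_starts=2, seed=b)
                boot[b] = fb.weights[1]
            ci = tuple(np.nanpercentile(boot, [2.5, 97.5]))
        rows.append(
            (
                tc,
                pi_e,
                ci[0],
                ci[1],
                float(fit.scales[0]),
                float(fit.scales[1]),
                float(fit.scales[1] ** 2),
                x.size,
                tc >= reliable_after,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "t",
            "pi_explorer",
            "pi_ci_low",
            "pi_ci_high",
            "sigma_resident",
            "sigma_explorer",
            "msd_explorer",
            "n",
            "reliable",
        ],
    )


def component_diffusion(
    traj: pd.DataFrame,
    t_min: float = 30.0,
    bootstrap_B: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> DiffusionFit:
    """Linear or piecewise fit of the explorer-component MSD sigma_e(t)^2.

    Fits both models on the reliable part of the trajectory; the piecewise
    fit is preferred when its bootstrap p-value is below ``alpha``."""
    sub = traj.rename(columns={"msd_explorer": "msd"})[["t", "msd"]]
    if len(sub) < 10:
        raise ValueError("need at least 10 grid points")
    pw = fit_piecewise(sub, t_min=t_min, bootstrap_B=bootstrap_B, seed=seed)
    if pw.p_piecewise is not None and pw.p_piecewise < alpha and not pw.edge_breakpoint:
        return pw
    return fit_diffusion(sub, t_min=t_min)


def gaussianity_diagnostics(
    x=None,
    per_replicate: list | None = None,
    deciles=(10, 20, 30, 40, 50, 60, 70, 80, 90),
) -> dict:
    """Excess kurtosis and QQ percentile deviations against a centred Gaussian.

    Pass either pooled positions ``x`` or ``per_replicate`` (a list of
    position arrays): in the latter case every replicate is standardised to
    unit variance before pooling, which removes inter-replicate variance
    heterogeneity — true within-replicate scale mixtures stay leptokurtic
    under this renormalisation while between-replicate heterogeneity does
    not.

    Returns ``{"excess_kurtosis", "qq_deviation", "deciles", "n"}`` where
    ``qq_deviation`` is observed minus fitted-Gaussian decile, in units of
    the fitted sigma.
    """
    if per_replicate is not None:
        parts = []
        for arr in per_replicate:
            arr = np.asarray(arr, dtype=float).ravel()
            sd = np.sqrt(np.mean(arr**2))
            if sd > 0:
                parts.append(arr / sd)
        x = np.concatenate(parts)
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 30:
        raise ValueError("need at least 30 observations")
    sigma = float(np.sqrt(np.mean(x**2)))
    obs_q = np.percentile(x, deciles)
    the_q = stats.norm.ppf(np.asarray(deciles) / 100.0, loc=0.0, scale=sigma)
    return {
        "excess_kurtosis": float(stats.kurtosis(x, fisher=True, bias=True)),
        "qq_deviation": (obs_q - the_q) / sigma,
        "deciles": np.asarray(deciles, dtype=float),
        "n": x.size,
    }
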