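"""Dispersal-kernel estimation and the movement-to-parasitism linkage.

The dispersal kernel is the spatial distribution of parasitism events: the
fraction of host eggs parasitised as a function of their signed distance
from the release point.  Its standard deviation is the dispersal
coefficient sigma.  This module also quantifies the behavioural pathway
from movement to parasitism: the spatial profile of the on-host fraction,
host first-discovery times, the assignment of each parasitised host to the
behavioural mode (resident/explorer) most likely to have discovered it, the
saturating gain function P(parasitised | total visit time), and
cross-replicate correlations between front position, total parasitism and
the dispersal coefficient.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "dispersal_kernel",
    "on_host_fraction",
    "discovery_times",
    "assign_discoverer",
    "gain_curve",
    "correlate_metrics",
]


def _smooth(x: np.ndarray, y: np.ndarray, frac: float = 0.5) -> np.ndarray:
    """Local-regression (LOWESS) trend of y on x, evaluated at x."""
    if x.size < 4:
        return y.astype(float)
    sm = lowess(y, x, frac=frac, return_sorted=False)
    return np.asarray(sm, dtype=float)


def dispersal_kernel(hosts: pd.DataFrame, bin_width: float = 30.0) -> dict:
    """Binned dispersal kernel and its Gaussian fit.

    Hosts are binned by signed position (default 30-cm bins, the spacing of
    consecutive clumped patches) and the per-bin fraction parasitised is
    computed.  The dispersal coefficient ``sigma_dispersal`` is the standard
    deviation of the signed positions of parasitised hosts, and a centred
    Gaussian ``A * exp(-s^2 / (2 sigma^2))`` is fitted to the binned
    fractions by least squares.

    Returns a dict with ``bin_centres, fraction_parasitized, n_per_bin,
    sigma_dispersal, gaussian_amplitude, gaussian_sigma, gaussian_rmse,
    n_hosts, n_parasitized, flat_kernel``.
    """
    if hosts.empty:
        raise ValueError("host table is empty")
    s = hosts["s"].to_numpy(dtype=float)
    par = hosts["parasitized"].to_numpy(dtype=bool)
    edges = np.arange(
        bin_width * np.floor(s.min() / bin_width),
        bin_width * np.ceil(s.max() / bin_width) + bin_width / 2,
        bin_width,
    )
    idx = np.clip(np.digitize(s, edges) - 1, 0, edges.size - 2)
    n_per_bin = np.bincount(idx, minlength=edges.size - 1)
    n_par_bin = np.bincount(idx, weights=par.astype(float), minlength=edges.size - 1)
    keep = n_per_bin > 0
    centres = (edges[:-1] + edges[1:])[keep] / 2.0
    frac = n_par_bin[keep] / n_per_bin[keep]

    n_par = int(par.sum())
    if n_par > 0:
        sigma_disp = float(np.std(s[par]))
    else:
        sigma_disp = np.nan

    amp = sigma_g = rmse = np.nan
    flat = False
    if np.any(frac > 0):
        try:
            (amp, sigma_g), _ = optimize.curve_fit(
                lambda x, a, sg: a * np.exp(-(x**2) / (2.0 * sg**2)),
                centres,
                frac,
                p0=[max(frac.max(), 1e-3), max(sigma_disp if np.isfinite(sigma_disp) else 50.0, 1.0)],
                maxfev=10000,
            )
            sigma_g = abs(float(sigma_g))
            amp = float(amp)
            rmse = float(np.sqrt(np.mean((frac - amp * np.exp(-(centres**2) / (2 * sigma_g**2))) ** 2)))
            # a flat kernel has no central peak for the Gaussian to latch onto
            flat = bool(frac.std() < 0.05 * max(frac.mean(), 1e-12) or sigma_g > np.ptp(centres))
        except RuntimeError:
            flat = True
    return {
        "bin_centres": centres,
        "fraction_parasitized": frac,
        "n_per_bin": n_per_bin[keep],
        "sigma_dispersal": sigma_disp,
        "gaussian_amplitude": amp,
        "gaussian_sigma": sigma_g,
        "gaussian_rmse": rmse,
        "n_hosts": int(len(hosts)),
        "n_parasitized": n_par,
        "flat_kernel": flat,
    }


def on_host_fraction(
    table: pd.DataFrame,
    host_positions,
    times,
    reactive_distance: float = 0.4,
    bin_width: float = 10.0,
    time_window: float = 5.0,
) -> pd.DataFrame:
    """Spatial profile of the fraction of individuals in immediate proximity
    of a host, at each focal time.

    "Immediate proximity" means within the reactive distance along the
    linear coordinate.  Detections within ±``time_window`` min of each focal
    time are pooled, binned by position (default 10-cm bins), and the
    per-bin on-host fraction computed; a LOWESS trend is attached.  Empty
    bins are skipped.

    Returns a tidy DataFrame with columns ``time, bin_centre, fraction,
    n, smoothed``.
    """
    hp = np.sort(np.asarray(host_positions, dtype=float))
    if hp.size == 0:
        return pd.DataFrame(columns=["time", "bin_centre", "fraction", "n", "smoothed"])
    rows = []
    for tc in times:
        sub = table[(table["t"] >= tc - time_window) & (table["t"] <= tc + time_window)]
        if sub.empty:
            continue
        x = sub["s"].to_numpy(dtype=float)
        i = np.searchsorted(hp, x)
        d_lo = np.abs(x - hp[np.clip(i - 1, 0, hp.size - 1)])
        d_hi = np.abs(x - hp[np.clip(i, 0, hp.size - 1)])
        on = np.minimum(d_lo, d_hi) <= reactive_distance
        edges = np.arange(
            bin_width * np.floor(x.min() / bin_width),
            bin_width * np.ceil(x.max() / bin_width) + bin_width / 2,
            bin_width,
        )
        idx = np.clip(np.digitize(x, edges) - 1, 0, edges.size - 2)
        n_bin = np.bincount(idx, minlength=edges.size - 1)
        n_on = np.bincount(idx, weights=on.astype(float), minlength=edges.size - 1)
        keep = n_bin > 0
        centres = (edges[:-1] + edges[1:])[keep] / 2.0
        frac = n_on[keep] / n_bin[keep]
        sm = _smooth(centres, frac)
        for c, f, n, s_ in zip(centres, frac, n_bin[keep], sm):
            rows.append((tc, c, f, int(n), s_))
    return pd.DataFrame(rows, columns=["time", "bin_centre", "fraction", "n", "smoothed"])


def discovery_times(hosts: pd.DataFrame) -> pd.DataFrame:
    """First-discovery time of each discovered host versus distance from
    the centre, with a LOWESS trend.

    Undiscovered hosts are excluded.  Returns a DataFrame with columns
    ``host_id, s, abs_s, first_discovery, smoothed`` sorted by ``abs_s``.
    """
    disc = hosts.dropna(subset=["first_discovery"]).copy()
    if disc.empty:
        raise ValueError("no discovered hosts")
    disc["abs_s"] = disc["s"].abs()
    disc = disc.sort_values("abs_s").reset_index(drop=True)
    disc["smoothed"] = _smooth(
        disc["abs_s"].to_numpy(dtype=float), disc["first_discovery"].to_numpy(dtype=float)
    )
    return disc[["host_id", "s", "abs_s", "first_discovery", "smoothed"]]


def assign_discoverer(
    hosts: pd.DataFrame,
    traj: pd.DataFrame,
    threshold: float = 0.5,
    reliable_after: float = 60.0,
) -> pd.DataFrame:
    """Assign each discovered host to the behavioural mode most likely to
    have discovered it.

    Using the time-resolved two-component decomposition ``traj`` (from
    :func:`spiralspread.distribution_fits.track_components`), the posterior
    probability that the discoverer was an explorer is

        p_e(s, t) = pi_e(t) phi(s; sigma_e(t))
                    / [pi_e(t) phi(s; sigma_e(t)) + (1 - pi_e(t)) phi(s; sigma_r(t))]

    with phi the centred Gaussian density, evaluated at the host position
    and its first-discovery time (mixture parameters linearly interpolated
    on the trajectory grid).  Hosts discovered before ``reliable_after`` min
    (the latency/unreliable window) or at times not covered by the
    trajectory, or where the fitted mixture is degenerate, are labelled
    ``unassigned``.

    Returns a DataFrame with columns ``host_id, s, first_discovery,
    p_explorer, label``.
    """
    disc = hosts.dropna(subset=["first_discovery"])
    tg = traj["t"].to_numpy(dtype=float)
    rows = []
    for _, h in disc.iterrows():
        t = float(h["first_discovery"])
        s = float(h["s"])
        if t < reliable_after or t < tg.min() or t > tg.max():
            rows.append((h["host_id"], s, t, np.nan, "unassigned"))
            continue
        pi_e = np.interp(t, tg, traj["pi_explorer"])
        sig_r = np.interp(t, tg, traj["sigma_resident"])
        sig_e = np.interp(t, tg, traj["sigma_explorer"])
        if sig_e / max(sig_r, 1e-12) < 1.1 or not (0.0 < pi_e < 1.0):
            rows.append((h["host_id"], s, t, np.nan, "unassigned"))
            continue
        num = pi_e * stats.norm.pdf(s, 0.0, sig_e)
        den = num + (1.0 - pi_e) * stats.norm.pdf(s, 0.0, sig_r)
        if den <= 0:  # far in the tails of both components: broad one wins
            p_e = 1.0
        else:
            p_e = float(num / den)
        rows.append((h["host_id"], s, t, p_e, "explorer" if p_e > threshold else "resident"))
    return pd.DataFrame(rows, columns=["host_id", "s", "first_discovery", "p_explorer", "label"])


def gain_curve(hosts: pd.DataFrame, bin_width: float = 15.0) -> dict:
    """Empirical gain function: P(parasitised) versus total visit time.

    Hosts are binned by cumulated visit time and the per-bin fraction
    parasitised computed, with a LOWESS trend and a fitted saturating
    exponential ``1 - exp(-T / tau)`` whose asymptote diagnoses saturation.

    Returns a dict with ``bin_centres, proportion, n_per_bin, smoothed,
    tau_hat, asymptote``.
    """
    T = hosts["total_visit"].to_numpy(dtype=float)
    par = hosts["parasitized"].to_numpy(dtype=bool)
    if T.size == 0 or np.all(T == 0):
        return {
            "bin_centres": np.empty(0),
            "proportion": np.empty(0),
            "n_per_bin": np.empty(0, dtype=int),
            "smoothed": np.empty(0),
            "tau_hat": np.nan,
            "asymptote": np.nan,
        }
    edges = np.arange(0.0, T.max() + bin_width, bin_width)
    idx = np.clip(np.digitize(T, edges) - 1, 0, edges.size - 2)
    n_bin = np.bincount(idx, minlength=edges.size - 1)
    n_par = np.bincount(idx, weights=par.astype(float), minlength=edges.size - 1)
    keep = n_bin > 0
    centres = (edges[:-1] + edges[1:])[keep] / 2.0
    prop = n_par[keep] / n_bin[keep]
    sm = _smooth(centres, prop)
    tau_hat = asymptote = np.nan
    try:
        (tau_hat,), _ = optimize.curve_fit(
            lambda t, tau: 1.0 - np.exp(-t / tau), T, par.astype(float), p0=[60.0], maxfev=10000
        )
        tau_hat = float(abs(tau_hat))
        asymptote = float(1.0 - np.exp(-T.max() / tau_hat))
    except RuntimeError:
        pass
    return {
        "bin_centres": centres,
        "proportion": prop,
        "n_per_bin": n_bin[keep],
        "smoothed": sm,
        "tau_hat": tau_hat,
        "asymptote": asymptote,
    }


def correlate_metrics(per_replicate: pd.DataFrame, pairs=None) -> pd.DataFrame:
    """Spearman rank correlations between per-replicate summary metrics.

    ``per_replicate`` holds one row per replicate with (at least) the
    columns named in ``pairs``; by default the three canonical pairs among
    the end-of-run 98% front position, total parasitism fraction and
    dispersal coefficient are tested.  Alternative predictors (other
    quantiles, MSD) can be supplied via ``pairs``.  Constant inputs yield an
    undefined correlation, flagged NaN.

    Returns a DataFrame with columns ``x, y, rho, rho2, p, n``.
    """
    if len(per_replicate) < 5:
        raise ValueError("need at least 5 replicates")
    if pairs is None:
        pairs = [
            ("front_98", "sigma_dispersal"),
            ("front_98", "total_parasitism"),
            ("total_parasitism", "sigma_dispersal"),
        ]
    rows = []
    for a, b in pairs:
        xa = per_replicate[a].to_numpy(dtype=float)
        xb = per_replicate[b].to_numpy(dtype=float)
        ok = np.isfinite(xa) & np.isfinite(xb)
        if ok.sum() < 5 or np.ptp(xa[ok]) == 0 or np.ptp(xb[ok]) == 0:
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.spearmanr(xa[ok], xb[ok])
        rows.append((a, b, rho, rho**2 if np.isfinite(rho) else np.nan, p, int(ok.sum())))
    return pd.DataFrame(rows, columns=["x", "y", "rho", "rho2", "p", "n"])
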