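"""Agent-based simulator of a switching heterogeneous random walk in the
linear tunnel, with host encounter, parasitism and imperfect detection.

The model the analysis pipeline is designed to infer: each individual walks
the linear coordinate with a per-minute Gaussian step whose standard
deviation depends on its behavioural mode — *resident* (narrow, slowly
spreading) or *explorer* (broad, fast-diffusing).  Mode switching is
dynamic and density-dependent:

* resident → explorer with a per-minute hazard that increases linearly with
  the number of neighbours within a perception radius in excess of a
  crowding threshold, and is boosted by recent host contact;
* explorer → resident with a constant hazard that only applies when the
  local density is low *and* the individual has had no recent host contact
  (so hosts suppress the reversion and sustain spread).

During an initial latency phase all individuals are resident and switching
is suppressed.  Individuals that come within the reactive distance of a
host egg board it, accrue visit time, and leave with a per-minute
probability; each minute spent on a host parasitises it with hazard 1/tau,
so that the probability a host ends up parasitised given total visit time T
is 1 - exp(-T/tau) — a saturating, concave gain function.

The simulator records a ground-truth detection table (every agent, every
minute); :func:`thin_detections` applies the imperfect-detection model of
the imaging pipeline (independent Bernoulli thinning, spatially unbiased).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from spiralspread.geometry import HostLayout, make_host_layout

__all__ = [
    "SimConfig",
    "simulate_replicate",
    "thin_detections",
    "simulate_experiment",
    "treatment_preset",
    "TRUTH_COLUMNS",
    "TREATMENTS",
]

#: ground-truth columns stripped by detection thinning
TRUTH_COLUMNS = ("agent_id", "mode")

TREATMENTS = ("low", "high", "high+diffuse", "high+clumped")


@dataclass
class SimConfig:
    """Parameters of one simulated replicate.

    Units: positions and radii in cm, times in minutes, step scales in
    cm·min^-1/2, switching parameters as per-minute hazards.
    """

    n_agents: int = 70
    duration: int = 480
    dt: float = 1.0
    tunnel_half_length: float = 315.0
    release_spread: float = 10.0
    sigma_resident: float = 0.5
    sigma_explorer: float = 5.0
    latency: float = 25.0
    switch_re_base: float = 5e-4
    switch_re_density_coef: float = 2e-3
    switch_re_host_boost: float = 0.05
    switch_er_hazard: float = 8e-3
    re_density_threshold: int = 12
    er_density_threshold: int = 3
    host_memory: float = 60.0
    perception_radius: float = 3.0
    reactive_distance: float = 0.4
    leave_host_prob: float = 0.2
    tau_parasitism: float = 60.0
    detection_prob: float = 0.33
    host_layout: str = "none"
    host_cutoff: float = 300.0
    initial_explorer_fraction: float = 0.0
    replicate_id: int = 0
    treatment: str = "custom"
    chirality: str = "levogyrous"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection_prob must be in [0, 1]")
        if self.sigma_resident < 0 or self.sigma_explorer < 0:
            raise ValueError("step scales must be non-negative")
        for p in (self.leave_host_prob, self.initial_explorer_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")

    def layout(self) -> HostLayout:
        return make_host_layout(self.host_layout, self.tunnel_half_length, self.host_cutoff)

    def to_dict(self) -> dict:
        return asdict(self)


def _neighbour_counts(x: np.ndarray, radius: float) -> np.ndarray:
    """Number of *other* agents within ``radius`` of each agent (linear cm)."""
    order = np.argsort(x)
    xs = x[order]
    hi = np.searchsorted(xs, xs + radius, side="right")
    lo = np.searchsorted(xs, xs - radius, side="left")
    counts = np.empty_like(x, dtype=int)
    counts[order] = hi - lo - 1
    return counts


def simulate_replicate(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run one replicate; return (ground-truth DetectionTable, HostTable).

    The detection table has one row per agent per minute with columns
    ``replicate, treatment, t, s, agent_id, mode``; the host table one row
    per host egg with columns ``host_id, s, patch_id, first_discovery,
    total_visit, parasitized, discoverer_mode`` (the last is ground truth:
    the mode of the first agent to board the host).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_agents
    layout = config.layout()
    n_hosts = layout.n_eggs
    host_pos = np.sort(layout.positions) if n_hosts else np.empty(0)
    host_order = np.argsort(layout.positions) if n_hosts else np.empty(0, dtype=int)

    n_steps = int(round(config.duration / config.dt))
    x = rng.uniform(-config.release_spread / 2.0, config.release_spread / 2.0, size=n)
    explorer = rng.random(n) < config.initial_explorer_fraction
    on_host = np.full(n, -1, dtype=int)  # index into sorted host_pos
    since_host = np.full(n, np.inf)

    first_discovery = np.full(n_hosts, np.nan)
    discoverer_explorer = np.full(n_hosts, -1, dtype=int)  # -1 undiscovered
    total_visit = np.zeros(n_hosts)
    parasitized = np.zeros(n_hosts, dtype=bool)
    p_par_step = 1.0 - np.exp(-config.dt / config.tau_parasitism)

    rec_t = np.empty((n_steps, n), dtype=float)
    rec_mode = np.empty((n_steps, n), dtype=bool)

    half = config.tunnel_half_length
    for step in range(n_steps):
        t = (step + 1) * config.dt
        free = on_host < 0

        # (1) movement with reflecting boundaries
        sd = np.where(explorer, config.sigma_explorer, config.sigma_resident)
        x_new = x + np.where(free, rng.normal(0.0, 1.0, n) * sd * np.sqrt(config.dt), 0.0)
        # fold back into [-half, half] (handles multiple reflections)
        x_new = half - np.abs((x_new + half) % (4.0 * half) - 2.0 * half)
        x = x_new

        # (2) behavioural switching (suppressed during the latency phase)
        if t > config.latency and (config.switch_re_base or config.switch_re_density_coef
                                   or config.switch_re_host_boost or config.switch_er_hazard):
            neigh = _neighbour_counts(x, config.perception_radius)
            recent_host = since_host <= config.host_memory
            crowd = np.maximum(neigh - config.re_density_threshold, 0)
            hz_re = (
                config.switch_re_base
                + config.switch_re_density_coef * crowd
                + np.where(recent_host, config.switch_re_host_boost, 0.0)
            )
            p_re = 1.0 - np.exp(-hz_re * config.dt)
            gate_er = (neigh < config.er_density_threshold) & ~recent_host & free
            p_er = np.where(gate_er, 1.0 - np.exp(-config.switch_er_hazard * config.dt), 0.0)
            u = rng.random(n)
            flip_up = ~explorer & (u < p_re)
            flip_dn = explorer & (u < p_er)
            explorer = explorer | flip_up
            explorer[flip_dn] = False

        if n_hosts:
            # (3a) boarding: free agents within the reactive distance of a host
            idx = np.searchsorted(host_pos, x)
            idx_lo = np.clip(idx - 1, 0, n_hosts - 1)
            idx_hi = np.clip(idx, 0, n_hosts - 1)
            d_lo = np.abs(x - host_pos[idx_lo])
            d_hi = np.abs(x - host_pos[idx_hi])
            nearest = np.where(d_lo <= d_hi, idx_lo, idx_hi)
            near = np.minimum(d_lo, d_hi) <= config.reactive_distance
            board = free & near
            on_host[board] = nearest[board]
            x[board] = host_pos[on_host[board]]

            # (3b) visits, discovery, parasitism, leaving
            occupied = on_host >= 0
            if occupied.any():
                hosts_now = on_host[occupied]
                modes_now = explorer[occupied]
                counts = np.bincount(hosts_now, minlength=n_hosts)
                total_visit += counts * config.dt
                newly = (counts > 0) & np.isnan(first_discovery)
                first_discovery[newly] = t
                for h in np.flatnonzero(newly):
                    discoverer_explorer[h] = int(modes_now[hosts_now == h][0])
                # each agent-minute on a host parasitises it with hazard 1/tau
                hit = np.flatnonzero(occupied)[rng.random(occupied.sum()) < p_par_step]
                parasitized[on_host[hit]] = True
                leave = occupied & (rng.random(n) < config.leave_host_prob)
                on_host[leave] = -1
            since_host = np.where(occupied, 0.0, since_host + config.dt)

        rec_t[step] = x
        rec_mode[step] = explorer

    detections = pd.DataFrame(
        {
            "replicate": config.replicate_id,
            "treatment": config.treatment,
            "t": np.repeat(np.arange(1, n_steps + 1) * config.dt, n),
            "s": rec_t.ravel(),
            "agent_id": np.tile(np.arange(n), n_steps),
            "mode": np.where(rec_mode.ravel(), "explorer", "resident"),
        }
    )

    # host table in original layout order
    inv = np.empty(n_hosts, dtype=int)
    if n_hosts:
        inv[np.arange(n_hosts)] = host_order  # sorted index -> original index
    disc_mode = np.where(
        discoverer_explorer < 0, "", np.where(discoverer_explorer == 1, "explorer", "resident")
    )
    hosts = pd.DataFrame(
        {
            "host_id": np.arange(n_hosts),
            "s": host_pos,
            "patch_id": layout.patch_id[host_order] if n_hosts else np.empty(0, dtype=int),
            "first_discovery": first_discovery,
            "total_visit": total_visit,
            "parasitized": parasitized,
            "discoverer_mode": disc_mode,
        }
    )
    hosts["replicate"] = config.replicate_id
    hosts["treatment"] = config.treatment
    return detections, hosts


def thin_detections(
    truth: pd.DataFrame, detection_prob: float, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Bernoulli-thin a ground-truth table to emulate imperfect detection.

    Each (agent, minute) row is kept independently with probability
    ``detection_prob``; positions are unaltered and ground-truth columns
    (agent identity, behavioural mode) are stripped, since the imaging
    pipeline yields anonymous detections.
    """
    if not 0.0 <= detection_prob <= 1.0:
        raise ValueError("detection_prob must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = rng.random(len(truth)) < detection_prob
    cols = [c for c in truth.columns if c not in TRUTH_COLUMNS]
    return truth.loc[keep, cols].reset_index(drop=True)


def treatment_preset(name: str, **overrides) -> SimConfig:
    """Base configuration for one of the four experimental treatments.

    ``low``: 25±5 individuals, no hosts; ``high``: 70±10, no hosts;
    ``high+diffuse`` / ``high+clumped``: 70±10 with the corresponding host
    layout.  The replicate-level agent count is drawn in
    :func:`simulate_experiment`; here the preset mean is used.
    """
    presets = {
        "low": dict(n_agents=25, host_layout="none"),
        "high": dict(n_agents=70, host_layout="none"),
        "high+diffuse": dict(n_agents=70, host_layout="diffuse"),
        "high+clumped": dict(n_agents=70, host_layout="clumped"),
    }
    if name not in presets:
        raise ValueError(f"unknown treatment preset: {name!r} (choose from {TREATMENTS})")
    kwargs = dict(presets[name], treatment=name)
    kwargs.update(overrides)
    return SimConfig(**kwargs)


#: half-ranges of the replicate-level agent-count draw per preset
_AGENT_RANGE = {"low": 5, "high": 10, "high+diffuse": 10, "high+clumped": 10}


def simulate_experiment(
    preset: str,
    n_replicates: int,
    seed: int = 0,
    rep_cv_switch: float = 0.5,
    rep_cv_sigma: float = 0.1,
    **overrides,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a batch of replicates for one treatment.

    Replicate agent counts are drawn uniformly within the preset's stated
    range (e.g. 25±5), per-replicate seeds derive deterministically from the
    master seed, and chirality alternates between replicates (it does not
    affect the linear dynamics but is recorded, as in the experiments).
    Cohorts differ from day to day, so the switching hazards and the
    explorer step scale carry multiplicative lognormal replicate effects
    (coefficients of variation ``rep_cv_switch`` and ``rep_cv_sigma``);
    set both to 0 for identical replicates.

    Returns concatenated ground-truth detection and host tables.
    """
    base = treatment_preset(preset, **overrides)
    half_range = _AGENT_RANGE[preset]
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * n_replicates, dtype=np.uint32)
    rng = np.random.default_rng(child_seeds[0])
    det_parts, host_parts = [], []
    for r in range(n_replicates):
        n_agents = int(rng.integers(base.n_agents - half_range, base.n_agents + half_range + 1))
        f_switch = float(rng.lognormal(0.0, rep_cv_switch)) if rep_cv_switch > 0 else 1.0
        f_sigma = float(rng.lognormal(0.0, rep_cv_sigma)) if rep_cv_sigma > 0 else 1.0
        cfg = replace(
            base,
            n_agents=n_agents,
            replicate_id=r,
            seed=int(child_seeds[r + n_replicates]),
            chirality="levogyrous" if r % 2 == 0 else "dextrogyrous",
            switch_re_base=base.switch_re_base * f_switch,
            switch_re_density_coef=base.switch_re_density_coef * f_switch,
            switch_re_host_boost=base.switch_re_host_boost * f_switch,
            switch_er_hazard=base.switch_er_hazard / f_switch,
            sigma_explorer=base.sigma_explorer * f_sigma,
        )
        det, hosts = simulate_replicate(cfg)
        det_parts.append(det)
        host_parts.append(hosts)
    return (
        pd.concat(det_parts, ignore_index=True),
        pd.concat(host_parts, ignore_index=True),
    )
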