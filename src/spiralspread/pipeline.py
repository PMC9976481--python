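"""End-to-end orchestration: simulate the four-treatment experiment, run the
spread, mixture and parasitism analyses, and write tidy result bundles.

All randomness derives from a single master seed; every stage consumes a
deterministic child seed, so a run is reproducible bit-for-bit from its
config.  Interchange formats are CSV (tables) and JSON (fits, manifest);
configs round-trip through YAML.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from spiralspread import __version__
from spiralspread.simulate import SimConfig, simulate_experiment, thin_detections, TREATMENTS
from spiralspread.spread_stats import (
    compute_msd,
    compute_quantiles,
    fit_diffusion,
    fit_piecewise,
    piecewise_significance,
)
from spiralspread.distribution_fits import select_model, track_components, component_diffusion
from spiralspread.parasitism import dispersal_kernel, gain_curve, correlate_metrics

logger = logging.getLogger("spiralspread")

__all__ = [
    "RunConfig",
    "run_experiment",
    "read_detections",
    "write_detections",
    "read_hosts",
    "write_hosts",
    "SchemaError",
]


class SchemaError(ValueError):
    """Raised when an input table violates the declared schema."""


DETECTION_SCHEMA = {"replicate": int, "treatment": str, "t": float, "s": float}
HOST_SCHEMA = {
    "host_id": int,
    "s": float,
    "first_discovery": float,
    "total_visit": float,
    "parasitized": bool,
}


@dataclass
class RunConfig:
    """Configuration of a full multi-treatment run."""

    treatments: tuple = TREATMENTS
    n_replicates: dict = field(
        default_factory=lambda: {"low": 20, "high": 20, "high+diffuse": 20, "high+clumped": 22}
    )
    sim_overrides: dict = field(default_factory=dict)
    msd_window: float = 7.0
    quantiles: tuple = (50, 75, 90, 95, 98, 99)
    mixture_grid: float = 15.0
    mixture_window: float = 10.0
    bootstrap_spread: int = 2000
    bootstrap_mixture: int = 600
    piecewise_B: int = 200
    regression_t_min: float = 30.0
    master_seed: int = 0
    out_dir: str = "results"

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        d["treatments"] = tuple(d["treatments"])
        d["quantiles"] = tuple(d["quantiles"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def validate(self) -> None:
        for tr in self.treatments:
            if tr not in TREATMENTS:
                raise ValueError(f"unknown treatment {tr!r}")
            if self.n_replicates.get(tr, 0) < 1:
                raise ValueError(f"treatment {tr!r} has no replicates configured")


def _validate(df: pd.DataFrame, schema: dict, path: str) -> pd.DataFrame:
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    for col, typ in schema.items():
        try:
            if typ is bool:
                df[col] = df[col].astype(str).str.lower().isin(("true", "1", "1.0"))
            elif typ is not str:
                df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            lines = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
            raise SchemaError(f"{path}: non-numeric values in {col!r} at line(s) {lines}") from exc
    return df


def read_detections(path, tunnel_half_length: float | None = 315.0) -> pd.DataFrame:
    """Read and validate a detection table from CSV."""
    df = _validate(pd.read_csv(path), DETECTION_SCHEMA, str(path))
    if tunnel_half_length is not None:
        bad = df["s"].abs() > tunnel_half_length
        if bad.any():
            lines = (df.index[bad] + 2).tolist()[:5]
            raise SchemaError(
                f"{path}: position outside ±{tunnel_half_length} cm at line(s) {lines}"
            )
    return df


def write_detections(table: pd.DataFrame, path, truth: bool = False) -> None:
    """Write a detection table as CSV; ground-truth columns only if ``truth``."""
    cols = list(table.columns)
    if not truth:
        cols = [c for c in cols if c not in ("agent_id", "mode")]
    table[cols].to_csv(path, index=False)


def read_hosts(path) -> pd.DataFrame:
    """Read and validate a host table from CSV."""
    return _validate(pd.read_csv(path), HOST_SCHEMA, str(path))


def write_hosts(hosts: pd.DataFrame, path, truth: bool = False) -> None:
    cols = list(hosts.columns)
    if not truth:
        cols = [c for c in cols if c != "discoverer_mode"]
    hosts[cols].to_csv(path, index=False)


def _child_seeds(master: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n, dtype=np.uint32)]


def replicate_metrics(det: pd.DataFrame, hosts: pd.DataFrame | None, quantile: float = 98.0,
                      window: float = 7.0) -> pd.DataFrame:
    """Per-replicate end-of-run summaries: p% front position, final MSD and,
    with hosts, total parasitism fraction and dispersal coefficient."""
    rows = []
    t_end = float(det["t"].max())
    for rep, sub in det.groupby("replicate"):
        tail = sub[sub["t"] >= t_end - 2 * window]
        absx = tail["s"].abs().to_numpy(dtype=float)
        row = {
            "replicate": rep,
            "front_98": float(np.percentile(absx, quantile)) if absx.size else np.nan,
            "msd_final": float(np.mean(tail["s"] ** 2)) if len(tail) else np.nan,
        }
        if hosts is not None and not hosts.empty:
            hr = hosts[hosts["replicate"] == rep]
            par = hr["parasitized"].to_numpy(dtype=bool)
            row["total_parasitism"] = float(par.mean()) if par.size else np.nan
            row["sigma_dispersal"] = (
                float(np.std(hr.loc[par, "s"])) if par.sum() > 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def run_experiment(config: RunConfig) -> dict:
    """Run the full simulate → analyse pipeline and write a result bundle.

    Per treatment: ground-truth and thinned detection tables, MSD and
    quantile series, linear and piecewise diffusion fits with significance,
    model-selection tables at three focal times, component trajectories with
    their diffusion fits, and (with hosts) kernel, gain and correlation
    outputs.  A manifest records config hash, seed, versions and per-stage
    timing.  Stage failures are logged and recorded; the run continues.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.master_seed, 4 * len(config.treatments) + 1)
    manifest = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "version": __version__,
        "stages": {},
        "incomplete": [],
    }
    results = {}
    si = 0
    for tr in config.treatments:
        tdir = out / tr.replace("+", "_")
        tdir.mkdir(exist_ok=True)
        t0 = time.time()
        truth, hosts = simulate_experiment(
            tr, config.n_replicates[tr], seed=seeds[si], **config.sim_overrides
        )
        p_detect = config.sim_overrides.get("detection_prob", SimConfig().detection_prob)
        det = thin_detections(truth, p_detect, seed=seeds[si + 1])
        si += 2
        write_detections(det, tdir / "detections.csv")
        write_hosts(hosts, tdir / "hosts.csv")
        manifest["stages"][f"{tr}/simulate"] = {
            "seconds": round(time.time() - t0, 2),
            "rows": int(len(det)),
        }
        res = {"detections": det, "truth": truth, "hosts": hosts}
        for stage, fn in (
            ("spread", _stage_spread),
            ("mixtures", _stage_mixtures),
            ("parasitism", _stage_parasitism),
        ):
            t0 = time.time()
            try:
                fn(res, config, tdir, seeds[si % len(seeds)])
                manifest["stages"][f"{tr}/{stage}"] = {"seconds": round(time.time() - t0, 2)}
            except Exception as exc:  # partial failure: log, mark, continue
                logger.exception("stage %s/%s failed", tr, stage)
                manifest["incomplete"].append(f"{tr}/{stage}: {exc}")
            si += 1
        results[tr] = res
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "config.yaml").write_text(config.to_yaml())
    results["manifest"] = manifest
    return results


def _stage_spread(res: dict, config: RunConfig, tdir: Path, seed: int) -> None:
    det = res["detections"]
    msd = compute_msd(det, config.msd_window)
    quant = compute_quantiles(det, config.quantiles, config.msd_window)
    msd.to_csv(tdir / "msd.csv", index=False)
    quant.to_csv(tdir / "quantiles.csv", index=False)
    lin = fit_diffusion(msd, config.regression_t_min)
    sig = piecewise_significance(
        det, config.msd_window, config.regression_t_min, B=config.piecewise_B, seed=seed
    )
    fits = {
        "linear": lin.to_dict(),
        "piecewise": sig["fit"].to_dict() | {
            "p_piecewise": sig["p_piecewise"],
            "slope_diff_ci": list(sig["slope_diff_ci"]),
        },
    }
    (tdir / "diffusion.json").write_text(json.dumps(fits, indent=2))
    res["msd"], res["quantiles"], res["diffusion"] = msd, quant, fits


def _stage_mixtures(res: dict, config: RunConfig, tdir: Path, seed: int) -> None:
    det = res["detections"]
    t_max = det["t"].max()
    selections = {}
    for tc in (15, int(t_max * 0.8), int(t_max * 0.96)):
        sub = det[(det["t"] >= tc - 5) & (det["t"] <= tc + 5)]
        if len(sub) < 30:
            continue
        sel = select_model(sub["s"].to_numpy(), seed=seed)
        selections[str(tc)] = {
            "best": sel["best"],
            "aic": sel["aic"],
            "fits": {k: f.to_dict() for k, f in sel["fits"].items()},
        }
    (tdir / "model_selection.json").write_text(json.dumps(selections, indent=2))
    traj = track_components(
        det,
        grid_step=config.mixture_grid,
        window=config.mixture_window,
        B=config.bootstrap_mixture,
        seed=seed,
    )
    traj.to_csv(tdir / "components.csv", index=False)
    res["model_selection"], res["components"] = selections, traj
    reliable = traj[traj["reliable"]]
    if len(reliable) >= 10:
        comp_fit = component_diffusion(reliable, t_min=0.0, bootstrap_B=config.piecewise_B)
        (tdir / "component_diffusion.json").write_text(json.dumps(comp_fit.to_dict(), indent=2))
        res["component_diffusion"] = comp_fit


def _stage_parasitism(res: dict, config: RunConfig, tdir: Path, seed: int) -> None:
    hosts = res["hosts"]
    det = res["detections"]
    metrics = replicate_metrics(det, hosts if not hosts.empty else None)
    metrics.to_csv(tdir / "replicate_metrics.csv", index=False)
    res["replicate_metrics"] = metrics
    if hosts.empty:
        return
    kern = dispersal_kernel(hosts)
    gain = gain_curve(hosts)
    pd.DataFrame(
        {
            "bin_centre": kern["bin_centres"],
            "fraction_parasitized": kern["fraction_parasitized"],
            "n": kern["n_per_bin"],
        }
    ).to_csv(tdir / "kernel.csv", index=False)
    (tdir / "kernel.json").write_text(
        json.dumps(
            {
                k: kern[k]
                for k in ("sigma_dispersal", "gaussian_amplitude", "gaussian_sigma",
                          "gaussian_rmse", "n_hosts", "n_parasitized", "flat_kernel")
            },
            default=float,
        )
    )
    res["kernel"], res["gain"] = kern, gain
    if len(metrics) >= 5 and "sigma_dispersal" in metrics:
        corr = correlate_metrics(metrics)
        corr.to_csv(tdir / "correlations.csv", index=False)
        res["correlations"] = corr
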