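# spiralspread

Analysis toolkit and agent-based simulator for the spatial spread of groups of
walking micro-insects released at the centre of a long, narrow channel folded
into a compact double-spiral arena. The package covers the full workflow:

- **geometry** — build the double-spiral channel skeleton, project 2-D
  detections onto the signed 1-D arclength coordinate, and generate host-egg
  layouts (diffuse or clumped) along that coordinate;
- **simulate** — an agent-based switching random walk: individuals alternate
  between a slow *resident* and a fast *explorer* movement mode with
  density-dependent switching, encounter and parasitise host eggs, and are
  observed through an imperfect-detection model;
- **spread_stats** — mean squared displacement (MSD) and quantile population
  fronts from anonymous detections, diffusion coefficients by linear
  regression, continuous two-segment (changepoint) regression with bootstrap
  significance, replicate-level bootstrap confidence intervals and
  rank-based treatment comparisons with false-discovery-rate control;
- **distribution_fits** — zero-mean Gaussian mixture (EM), centred Student-t
  and plain Gaussian fits of the position distribution with AIC model
  selection; time-resolved resident/explorer decomposition and the explorer
  diffusion coefficient; leptokurtosis diagnostics;
- **parasitism** — dispersal kernel (spatial distribution of parasitised
  hosts) and its dispersal coefficient, the saturating gain function
  P(parasitised | visit time), host discovery times, probabilistic assignment
  of each discovered host to the likely discoverer mode, and cross-replicate
  movement–parasitism correlations;
- **pipeline / cli** — an end-to-end, fully seeded simulate → analyse
  pipeline writing tidy CSV/JSON bundles, with schema-validated table I/O and
  a `spiralspread` command-line interface.

## Quickstart (command line)

```bash
# simulate one high-density treatment (20 replicates) and analyse its spread
spiralspread simulate --treatment high --replicates 20 --seed 1 --out sim/
spiralspread spread sim/detections.csv --out spread/

# behavioural-mode decomposition and parasitism analyses
spiralspread simulate --treatment high+diffuse --replicates 20 --seed 2 --out simd/
spiralspread mixtures simd/detections.csv --out mix/
spiralspread parasitism simd/hosts.csv --components mix/components.csv --out par/

# the full four-treatment experiment in one call
spiralspread run-all --seed 7 --out results/
```

## Quickstart (library)

```python
from spiralspread import (
    simulate_experiment, thin_detections,
    compute_msd, fit_diffusion, piecewise_significance,
    track_components, dispersal_kernel,
)

truth, hosts = simulate_experiment("high", n_replicates=20, seed=7)
detections = thin_detections(truth, 0.33, seed=8)          # imperfect detection

msd = compute_msd(detections, window=7)                    # pooled MSD series
print(fit_diffusion(msd).D_m2h)                            # diffusion coefficient, m²/h
sig = piecewise_significance(detections, B=200, seed=0)    # changepoint + bootstrap p
print(sig["fit"].breakpoint, sig["p_piecewise"])

traj = track_components(detections, B=600)                 # resident/explorer weights
kernel = dispersal_kernel(hosts)                           # sigma_dispersal etc.
```

Positions are signed centimetres along the channel from the release point,
times are minutes; diffusion coefficients are reported both in cm²·min⁻¹ and
m²·h⁻¹.

## Testing

```bash
python -m pytest -q tests/
```

The suite contains oracle-based unit tests for every module plus
`tests/test_acceptance.py`, an end-to-end property suite at study scale.
`python scripts/acceptance.py --seed 1 --out results/acceptance.json` runs the
main analyses and writes their headline quantities as JSON.

See `docs/methods.md` for the statistical methods and the simulator model.
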