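# Methods

This note documents the statistical definitions, the simulator model and the
main methodological decisions implemented in `spiralspread`.

## Coordinate system and geometry

The arena is a single channel of length ~630 cm folded as two interleaved
Archimedean spiral arms inside a 60 × 40 cm box, with the release point at the
centre. Movement is effectively one-dimensional, so all analyses work on the
*signed arclength* coordinate `s` (cm): negative on one arm, positive on the
other, zero at the release point. `build_spiral` constructs the channel
skeleton as a dense polyline with a closed-form arclength parameterisation
(`s(θ) = (b/2)(θ√(1+θ²) + asinh θ)` per arm, inverted numerically), and
`project_to_skeleton` maps a 2-D detection to `(s, offset)` by orthogonal
projection onto the nearest polyline segment; offsets beyond half the channel
width trigger a warning. Host layouts are defined directly on `s`: *diffuse*
= one egg every 5 cm starting ±2.5 cm; *clumped* = one patch of six
co-located eggs every 30 cm starting ±15 cm; with the default 300-cm cutoff
both hold exactly 120 eggs, equalising mean host density.

## Spread statistics

**MSD.** At each minute `t`, `MSD(t) = (1/N_t) Σ s_i²` over all detections in
a moving window of ±7 min, pooled across replicates (each detection counts
once, so replicates contribute proportionally to their detection counts).
Minutes with no detections are reported as missing, not zero. The population
*front* is the p-th percentile (50–99%) of |s| in the same windows.

**Diffusion coefficient.** `D` is the ordinary-least-squares slope of MSD
versus time — the operational definition used throughout, without the ½
factor of the textbook 1-D diffusion relation. The first 30 min (release
latency) are excluded from all regressions. `D` is reported in cm²·min⁻¹ and
m²·h⁻¹ (× 0.006).

**Changepoint.** The two-regime hypothesis is tested with a *continuous*
two-segment regression (hinge model `y = a + b·t + c·(t − τ)₊`), fitted by
exhaustive grid search over breakpoint candidates with closed-form OLS at
each candidate. Two significance routes are provided, matching the two input
shapes:

- `fit_piecewise(series, bootstrap_B=…)`: for a bare MSD series, a residual
  bootstrap under the single-line null of the relative RSS-improvement
  statistic `(RSS_lin − RSS_pw)/RSS_pw`;
- `piecewise_significance(detections, B=…)`: for replicate-structured
  detection tables, a replicate-resampling bootstrap (the resampling unit is
  always the replicate) of the slope difference `D_after − D_before` of the
  pooled refit; the two-sided p-value is the bootstrap sign test of that
  difference.

A *slowdown* ("tortoise–hare" break) is declared when the replicate-bootstrap
p-value is < 0.05 **and** `D_after < D_before`; a significant acceleration
(e.g. a conversion ramp early in a host treatment) is deliberately not
counted as a break.

**Uncertainty and treatment comparison.** All confidence intervals on
spread summaries are replicate-level percentile bootstraps (default
B = 2000). Treatments are compared on per-replicate summaries with Wilcoxon
rank-sum tests and Benjamini–Hochberg false-discovery-rate adjustment;
groups with fewer than three replicates are flagged underpowered.

## Distribution fits and the resident/explorer decomposition

The position distribution is symmetric about the release point but
leptokurtic. Four centred candidates are fitted by maximum likelihood and
compared with AIC: a Gaussian, zero-mean Gaussian mixtures with K = 2 and 3
(EM with all means pinned at 0, multi-start, AIC = 2(2K−1) − 2ℓ), and a
centred Student-t (ν capped at 10³, the practical Gaussian limit;
AIC = 4 − 2ℓ). The K = 2 mixture is the discrete two-mode model (narrow
*resident* + broad *explorer* component); the Student-t is its continuous
counterpart (a full scale mixture). For a discrete 0.5/0.5 scale mixture of
variances v₁, v₂ the excess kurtosis is `3·E[v²]/E[v]² − 3` (≈ 2.88 for
25/2500), which `gaussianity_diagnostics` checks against sample estimates;
its per-replicate renormalisation option standardises each replicate to unit
variance before pooling, so between-replicate variance heterogeneity is
removed while true within-replicate scale mixtures stay leptokurtic.

`track_components` refits the K = 2 mixture every 15 min on ±5-min pooled
windows, reporting the explorer weight π_e(t) with replicate-bootstrap CIs
(B = 600), both scales, and the explorer-component MSD σ_e²(t); estimates
before 60 min are flagged unreliable (the distribution is still
near-Gaussian and the decomposition weakly identified). The explorer
diffusion coefficient is the slope of σ_e²(t) (linear, or piecewise when the
changepoint is significant).

## Parasitism

The *dispersal kernel* is the fraction of hosts parasitised per 30-cm bin of
signed position; the dispersal coefficient σ is the standard deviation of
the signed positions of parasitised hosts, and a centred Gaussian
`A·exp(−s²/2σ²)` is least-squares fitted to the binned fractions. The *gain
function* is the fraction parasitised per bin of cumulated visit time T,
with the saturating model `1 − exp(−T/τ)` fitted across hosts. Discovered
hosts are assigned to the likely discoverer mode through the mixture
posterior `p_e(s,t) = π_e φ(s; σ_e) / [π_e φ(s; σ_e) + (1−π_e) φ(s; σ_r)]`
evaluated at the host position and first-discovery time; discoveries in the
unreliable window or under a degenerate mixture are left unassigned.
Cross-replicate Spearman correlations link the 98% front, total parasitism
and σ. Trend lines on binned curves use LOWESS.

## Simulator model

Each of N agents performs a per-minute Gaussian step on `s` with standard
deviation σ_r = 0.5 (resident) or σ_e = 5.0 cm·min^-1/2 (explorer), with
reflecting boundaries at ±315 cm. Agents are released uniformly over ±5 cm
and start resident; during the first 25 min (latency) switching is
suppressed. Afterwards, per-minute hazards govern switching:

- resident → explorer: `base + coef · max(0, n_neigh − n₀) + host boost`,
  with `n_neigh` the number of agents within a 3-cm perception radius,
  crowding threshold n₀ = 12, base 5·10⁻⁴, coef 2·10⁻³ and a 0.05 boost
  while a host was contacted within the last 60 min;
- explorer → resident: constant hazard 8·10⁻³, gated on *low* local density
  (fewer than 3 neighbours) and no recent host contact — hosts suppress
  reversion and sustain spread.

Agents within the 0.4-cm reactive distance of a host egg board it, stop
moving, accrue visit time, and leave with probability 0.2 per minute; each
agent-minute on a host parasitises it with hazard 1/τ (τ = 60 min), giving
the saturating gain `P(parasitised | T) = 1 − exp(−T/τ)` (≈ 0.96 at
T = 200 min). Detection is an independent Bernoulli thinning (default 0.33)
of the per-minute ground truth, with agent identity and mode stripped.
Treatment presets: low (25 ± 5 agents, no hosts), high (70 ± 10, no hosts)
and high with diffuse or clumped hosts; replicate batches draw the agent
count uniformly in the stated range and carry multiplicative lognormal
replicate effects on the switching hazards (CV 0.5) and σ_e (CV 0.1),
reflecting day-to-day cohort variability.

The hazard rates are not measured quantities; they were calibrated once so
that the simulator reproduces the documented qualitative regime — transient
density-boosted spread that collapses after a few hours at high density
without hosts, steady slow spread at low density, sustained elevated spread
with hosts, and final pooled MSD of order 0.5 m² — and then frozen. The
crowding threshold is what separates the regimes: at release the low-density
cohort has ≈ 11 neighbours within the perception radius and stays below
threshold, while the high-density cohort (≈ 35) converts quickly until the
core dilutes.

## Units note

Because the MSD is defined on the signed linear coordinate and D is the raw
MSD slope, magnitudes are internally consistent within this package (final
pooled MSD of order 0.5 m² corresponds to D of order 10 cm²·min⁻¹ ≈ 0.06
m²·h⁻¹ over 8 h). Published D values for comparable assays vary by orders of
magnitude depending on the exact MSD and slope conventions used; both unit
systems are therefore always reported side by side.

## Reproducibility

Every stochastic routine takes an explicit seed; batch runs derive child
seeds from a single master seed via `numpy.random.SeedSequence`, so any run
is bit-for-bit reproducible from its YAML config (hash recorded in the
output manifest).
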