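# Methods

## The scientific question

Resource pulses — episodic inputs of limiting nutrients — are common in
nature, and communities receiving them are expected to become more variable
over time.  `microstab` implements the statistical toolkit for asking, in a
protist-microcosm setting: does the *magnitude and timing* of nutrient
pulses (at fixed total input) change the temporal variability of the
recipient community, and if so, through which mechanism — synchronised
species fluctuations or destabilised dominant species?

The experimental design the package targets is a five-arm layout with eight
replicate microcosms per arm.  Every pulsed arm receives the same total
volume of concentrated medium (2.31 mL into ~100 mL over 42 days), but:

| arm         | delivery                                   |
|-------------|--------------------------------------------|
| Control     | none                                       |
| Early       | 1.155 mL on days 10 and 11                 |
| Coincident  | 1.155 mL on days 14 and 15                 |
| Late        | 1.155 mL on days 18 and 19                 |
| MultiPulses | 0.055 mL every day, days 1–42              |

Four invader species are introduced on day 14, so the three high-magnitude
arms place the pulse before, at, or after the invasion.  Communities are
censused weekly (days 7–42) by counting a 0.32 mL subsample.

## Metrics

For a community matrix `x[i, t]` (species × sampling occasions, ind/mL):

- **Temporal variability** `CV = sd(T)/mean(T)` with `T_t = Σ_i x[i, t]`;
  **temporal stability** is `1/CV`.  Population-level variability uses the
  same formula per species.
- **Community-wide synchrony** `phi = Var(T) / (Σ_i sd(x_i))²`, in [0, 1]
  by Cauchy–Schwarz; **asynchrony** is `1 − phi`.  For two species with
  equal SD, `phi = (1 + ρ)/2` with ρ their Pearson correlation — a useful
  analytic cross-check.
- **Dominance**: time-averaged relative abundance of the dominant species
  (argmax of mean share; ties broken lexicographically).
- **Richness**: number of *resident* species detected (density > 0) on at
  least one occasion, cumulatively over the run.

All SDs and variances use the sample (n−1) denominator.  With only six
occasions the choice is material; the sample form is the community-ecology
default, and `phi` is invariant to the choice provided numerator and
denominator agree.  Invaders are included in totals, synchrony and
dominance by default (they are counted protists like any other) and can be
excluded with `residents_only`; richness always counts residents only, and
treats recorded zeros as true zeros.

## Inference

Each microcosm is reduced to one derived value per metric, giving a one-way
layout (5 × 8, F on 4 and 35 df).  Because treatment arms differ strongly
in the spread of their CVs, the omnibus test is a Wald F built on a
heteroscedasticity-consistent covariance — HC3 by default, the standard
small-sample recommendation at 8 observations per group; the classical
pooled-variance F is always reported alongside.  The p-value uses the
F(k−1, n−k) reference distribution.

Post-hoc pairwise comparisons use Tukey's HSD on the classical pooled-MSE
scale, summarised by an insert-and-absorb compact letter display (letters
assigned in ascending order of group mean).  Running a robust omnibus test
over classical Tukey comparisons is a pragmatic mix: HSD has no canonical
sandwich version.  A `robust_pairwise` alternative (per-group HC3 variances,
Welch–Satterthwaite df, Holm adjustment) is provided for users who want the
post-hoc layer robust as well.

Mechanism correlations (asynchrony vs variability, dominant-species
stability vs community stability, dominance vs community stability) are
Pearson correlations pooling all 40 microcosms of a trophic component
across treatments, since each mechanism is posited as a single
community-level relationship.

## The simulator

No count data are deposited for this design, so the package ships a
generator whose output has the statistical structure the analysis assumes.
It is a discrete-day Euler consumer–resource chain:

- one lumped nutrient pool `R` (in units of standard-medium nutrient
  content per mL; fresh medium = 1), replenished by daily 1.4% medium
  replacement and by pulses.  The concentrate is worth 56.5 units/mL,
  chosen so a two-day high-magnitude pulse raises the nutrient content of a
  100 mL microcosm by ~130% of baseline;
- five resident algae with Monod growth `mu R/(K+R)` (mu 0.50–0.60/day,
  K 0.50–0.70 units/mL), drawing down `R` through a yield of 2.5×10⁵ cells
  per unit;
- five resident protozoa with lumped linear grazing (preferred prey at
  2×10⁻⁴ mL/ind/day, all others at 2×10⁻⁵), conversion efficiency 0.35 and
  mortalities 0.045–0.065/day;
- four invaders (two algae, two protozoa) at zero density until a
  10 ind/mL inoculum on day 14; invader protozoa are unspecialised grazers.

Species update multiplicatively, `x ← x·exp(r + ε)`, which preserves
non-negativity; populations below 10⁻³ ind/mL are set extinct.  Each
microcosm is initialised at the interior fixed point of the deterministic
daily map (solved by root-finding in log space; with the shipped traits
`R* ≈ 0.70`, algae ≈ 550–860 ind/mL each, protozoa ≈ 980–1040 ind/mL
each), so an unperturbed noise-free community is constant to machine
precision.

Process noise has two lognormal components: an independent per-species
daily shock (SD 0.05) representing demographic and micro-environmental
noise, and a pulse-driven shock on days with concentrate input, scaled
linearly with the day's volume (SD 0.5 per reference 1.155 mL pulse) and
correlated across species with `rho_env` (default 0.7).  The shared
component is the model's destabilising mechanism: species respond to a
pulse in a partially common way, which simultaneously raises the CV of the
aggregate and the synchrony index — exactly the coupling the analysis is
designed to detect.  Sampling is a Poisson census of the 0.32 mL subsample,
rescaled to per-mL units.

### Calibration of the shipped defaults

The free parameters (conversion efficiency, the two noise SDs) were set by
scanning a coarse grid over seeded simulated experiments until the design's
expected qualitative behaviour held robustly, then frozen: mean CV ordering
Control < MultiPulses < each high-magnitude arm, no Tukey separation among
Early/Coincident/Late, negative asynchrony–variability correlation, and
positive dominant-stability–community-stability correlation.  Higher
grazing conversion (0.35) shortens the post-pulse bloom–crash cycle, which
is what makes the three pulse timings statistically indistinguishable — a
slow crash would be truncated by the 42-day horizon for the Late arm and
create a spurious timing effect.

### What the generator does and does not emulate

It reproduces the design (arms, replicates, equal-total pulse budget,
invasion timing, weekly subsample censuses), plausible density magnitudes,
and the mechanistic coupling of pulses to synchrony and variability.  It
does not emulate: species-level taxonomy of responses (traits are loosely
spread, not fitted — no data are available to fit), bacterial dynamics
(protozoan bacterivory is folded into the nutrient→algae→protozoa chain),
demographic stochasticity at low density beyond the extinction cutoff, or
measurement error other than Poisson counting.  Passing pipeline tests on
this generator therefore demonstrates that the *analysis* recovers patterns
from data with the assumed structure — not that real microcosms have that
structure.

## Numerical choices

- Fixed point: `scipy.optimize.root` (hybr) on the log-parameterised
  discrete map, residual tolerance 1e-8; analytic quasi-diagonal guess.
- Synchrony is clipped to [0, 1] to absorb last-ulp roundoff; a zero
  denominator (all species constant) raises rather than returning NaN.
- Zero-total days are excluded from dominance with a warning; an all-zero
  subset is an undefined-metric error.  Per-microcosm metric failures are
  flagged rows in the stability table, never silent drops.
- Degenerate ANOVA inputs (zero residual variance) short-circuit to F = 0,
  p = 1 (equal means) or F = ∞, p = 0 (unequal means) with a flag.
- CSVs are written at 17 significant digits and read with round-trip float
  parsing, so write→read is bit-identical; report JSON and metrics CSV use
  12 significant digits for cross-platform byte-stable reruns.
- Per-microcosm RNG substreams come from `SeedSequence(seed, spawn_key=
  (arm_index, replicate))`, so any arm can be re-simulated independently.

## Problem sizes

Shipped analyses use the design's natural size (40 microcosms, 14 species,
6 occasions).  Replicated checks use 20 simulated experiments for the
qualitative patterns and 2,000 Monte-Carlo replicates for the HC3
calibration of the robust F under a 1:1:2:2:4 heteroscedastic null — sizes
at which the Monte-Carlo error is small relative to the effects being
checked.

## Known limitations

- The simulator is a stand-in, not a fitted model; its parameter values are
  field-plausible defaults, and quantitative outputs (F statistics, means)
  characterise the simulator, not any real experiment.
- Tukey letters on the classical MSE scale can over-separate groups when
  variances differ strongly; use `--robust-posthoc` when that matters.
- The HC3 Wald F with the F(4, 35) reference over-rejects mildly (about
  0.07 at nominal 0.05 in the shipped null calibration); this is a known
  small-sample property of sandwich tests, not an implementation artefact.
- No repeated-measures or mixed modelling: each microcosm contributes a
  single value per metric, as the design intends.
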