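# microstab

Temporal-stability analysis of pulsed-resource protist microcosm
communities, paired with a stochastic multi-trophic simulator of the
experimental design it analyses.

## The problem

Ecologists quantify the stability of a community by how little its
aggregate abundance fluctuates over time.  A central question is whether
*fluctuating* resource supply — nutrient pulses differing in magnitude,
duration and timing at fixed total input — destabilises the recipient
community, and through which mechanism: synchronised species responses
(loss of the portfolio effect) or destabilised dominant species.

`microstab` is aimed at community ecologists running (or simulating)
microcosm experiments of this kind: five treatment arms (Control; Early /
Coincident / Late high-magnitude two-day pulses placed around an invasion
event on day 14; MultiPulses dripping the same total daily), eight
replicate microcosms per arm, ten resident + four invader protist species
in two trophic groups (green algae, heterotrophic protozoa), censused
weekly from day 7 to day 42 by counting a 0.32 mL subsample.

## Metrics and models

For a species × occasion density matrix with total `T_t`:

- temporal variability `CV = sd(T)/mean(T)`; temporal stability `1/CV`
- community-wide synchrony `phi = Var(T) / (Σ_i sd(x_i))²` ∈ [0, 1];
  asynchrony `1 − phi`
- dominance: time-averaged relative abundance of the dominant species
- richness: resident species detected on ≥ 1 occasion

Treatment effects are tested with a one-way Wald F using a
heteroscedasticity-consistent (sandwich, default HC3) covariance — CVs of
different arms rarely share a variance — with Tukey HSD compact-letter
post-hocs; mechanism relationships are Pearson correlations across
microcosms.  Since no count data are deposited for this design, the package
ships a discrete-day Monod consumer–resource simulator (nutrient → algae →
protozoa) with pulse-synchronised lognormal process noise and Poisson
subsample censuses, so the whole pipeline runs end-to-end on synthetic
data.  See `docs/methods.md` for model details and calibration.

## Worked example

```python
from microstab import (default_config, simulate_experiment,
                       compute_stability_table, records_to_frame,
                       run_figures_analysis)
from microstab.pipeline import report_to_text

cfg = default_config(seed=1)
series = simulate_experiment(cfg)          # 40 microcosms, 14 species, 6 censuses
table = records_to_frame(compute_stability_table(series))
print(report_to_text(run_figures_analysis(table)))
```

prints (abridged):

```
== protozoan component (40 microcosms) ==
  temporal_variability: robust F_4,35 = 14.41 (p = 4.756e-07); classical F = 9.24 (p = 3.322e-05)
    means/letters: Coincident: 0.57 'c', Control: 0.0944 'a', Early: 0.443 'bc', Late: 0.569 'c', MultiPulses: 0.175 'ab'
  asynchrony_vs_variability: r = -0.793 (p = 1.049e-09, n = 40)
  dominant_stability_vs_community_stability: r = 0.578 (p = 9.35e-05, n = 40)
```

Read: protozoan temporal variability differs strongly among arms
(robust F on 4 and 35 df).  The Control mean CV (0.094) is lowest and
MultiPulses (0.175) sits between it and the three high-magnitude arms
(0.44–0.57), which share a Tukey letter — pulse *magnitude* matters, pulse
*timing* does not.  Microcosms whose species fluctuate more asynchronously
are less variable (r = −0.79), and communities whose dominant species is
stable are themselves stable (r = 0.58): both stabilising mechanisms are
visible in the simulated data.

The same run from a shell:

```sh
microstab reproduce --seed 1 --out runs/demo/
# runs/demo/community.csv  metrics.csv  report.json  report.txt  provenance.yaml
```

`simulate`, `metrics` and `analyze` expose the stages separately;
`--residents-only`, `--alpha`, `--hc HC0..HC3` and `--robust-posthoc`
control the analysis.  Input CSVs use the long format
`microcosm,treatment,day,species,trophic,origin,density`.

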