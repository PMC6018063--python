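# bgregime

Estimation of **background air pollution** — the lowest concentration regime
to which a population is chronically exposed — from univariate daily
pollutant time series, by probabilistic clustering under a common BIC
framework.

## The problem

A year of daily mean concentrations (NO₂, O₃, PM₁₀, CO, …) at a monitoring
site typically mixes several *regimes*: a persistent low background level and
one or more elevated regimes driven by local sources. Epidemiologists need
estimates of the background regime — its mean, spread and the fraction of the
year it prevails — but a single annual mean conflates all regimes.

`bgregime` treats regime identification as univariate clustering and compares
four techniques under one probabilistic roof:

- **fmm** — Gaussian finite mixture, fitted by EM with per-component
  variances ("V" configuration);
- **hc** — Ward agglomerative hierarchical clustering, each tree cut refined
  by an equal-variance ("E") EM run;
- **hmm** — Gaussian hidden Markov model fitted by Baum–Welch, which models
  the day-to-day persistence of regimes through a transition matrix Γ;
- **km** — k-means, re-expressed as an "E" mixture (weights = cluster
  representations, common variance = size-weighted within-cluster variance)
  and scored by a single E-step likelihood evaluation.

Every candidate solution with k = 1…9 clusters is scored with

```
BIC = 2·ln L − p·ln n        (larger is better)
```

where p is the technique's free-parameter count (3k−1 for "V" mixtures, 2k
for "E" mixtures, k²+2k−1 for the HMM). After selecting the max-BIC solution
and sorting clusters by ascending mean, the **first cluster** is the
background regime; its mixing proportion (*representation*, % of valid
days), mean *m* and standard deviation *sd* are the exposure estimates,
reported next to the annual mean *M*.

Raw hourly data are first aggregated to daily means, keeping a day only when
at least 80% of its expected hours are present.

## Worked example

```python
import bgregime as br

# a synthetic site-year: persistent low regime at 10 ug/m3, high at 40
spec = br.RegimeSpec(k_true=2, means=(10.0, 40.0), sds=(3.0, 3.0),
                     transition=((0.95, 0.05), (0.05, 0.95)),
                     site="torneo", pollutant="NO2", seed=7)
ds, states = br.simulate_hmm_series(spec)

cfg = br.FitConfig(seed=0)
regimes = [br.extract_background(ds, br.sweep_k(ds, t, cfg))
           for t in br.TECHNIQUES]
print(br.summarize_series(ds, regimes))
```

prints (one decimal shown):

```
technique  k  conc_min  conc_max  n_days  representation   m  sd    M
      fmm  2       1.7      16.2     188            51.5 9.7 2.8 24.2
       hc  2       1.7      16.2     188            51.5 9.7 2.9 24.2
      hmm  2       1.7      16.2     188            51.5 9.7 2.8 24.2
       km  2       1.7      16.2     188            51.5 9.7 2.9 24.2
```

All four techniques detect the two regimes in this well-separated series and
agree on the background estimate: it covers 188 of 365 days (51.5% of the
year, matching the chain's 50% stationary occupancy), with mean 9.7 µg/m³
(truth: 10) and spread ≈ 2.8 µg/m³ (truth: 3) — far below the annual mean
M = 24.2 µg/m³ that would otherwise be used as the exposure figure.

## Command line

The same pipeline is available as subcommands whose outputs chain on disk:

```
bgregime simulate --preset corpus -o sim/          # synthetic series + truth
bgregime aggregate hourly/*.csv -o daily/          # 80% completeness rule
bgregime background daily/*.csv -o results/        # sweeps + per-series table
bgregime tabulate results/ -o detection.csv        # k=1 vs k>1 counts
```

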