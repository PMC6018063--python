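# Methods

## Model

A site-year of daily mean concentrations x₁…xₙ (µg/m³) is modelled as a
k-regime process with Gaussian emissions. Two data-generating views are
fitted:

**Independent mixture.** xᵢ ~ Σⱼ πⱼ·N(mⱼ, sdⱼ²) with mixing proportions πⱼ.
Component variances are either free ("V" configuration) or constrained equal
("E"). Parameters are maximum-likelihood via EM.

**Hidden Markov model.** A latent first-order chain with initial
distribution δ and transition matrix Γ selects each day's emission component
N(mⱼ, sdⱼ²) ("V" configuration). The marginal day distribution is the same
mixture, but consecutive days are dependent — the feature that lets the HMM
exploit the multi-day persistence of pollution regimes. Parameters are
maximum-likelihood via Baum–Welch (EM with scaled forward–backward
recursions); decoding uses the Viterbi path.

The two hard-clustering techniques are mapped into the same likelihood
frame so that one selection criterion applies to all four:

- *k-means*: weights = cluster sizes/n, means = cluster centres, common
  variance = Σⱼ (nⱼ/n)·s²ⱼ with s²ⱼ the within-cluster ML variance. The
  likelihood of that fixed "E" parameter point is evaluated with a single
  E-step — deliberately no EM refinement, so the score reflects k-means
  itself.
- *Ward*: the agglomerative merge tree (merge cost n₁n₂/(n₁+n₂)·(m₁−m₂)²)
  is cut at each k and the cut partition seeds a full "E" EM run to
  convergence; the score reflects the hierarchical solution after
  model-based refinement.

## Model selection and background extraction

For each technique, every k in 1…9 is fitted and scored with
BIC = 2·lnL − p·ln n (maximized). Free-parameter counts: p = 3k−1 ("V"
mixture), 2k ("E" mixture, including both bridges), and k²+2k−1 for the HMM
— (k−1) initial probabilities, k(k−1) transition probabilities, k means and
k variances. Counting δ is a convention choice; the alternative (δ fixed,
p = k²+k) would shift every HMM BIC by the same ln n multiple at fixed k and
rarely change the argmax. Non-converged fits are excluded from the argmax;
ties within 10⁻⁹ resolve to the smaller k (parsimony). k = 1 is always a
candidate, so "no regime structure" is a possible verdict.

Clusters of the selected fit are sorted by ascending mean; the first cluster
is the background regime. Hard day assignment uses each technique's native
rule — maximum posterior for fmm/hc, nearest centre for km, Viterbi for the
HMM (a configuration switch exposes smoothed-posterior decoding instead;
Viterbi is the default because it yields contiguous day segments). Reported
are: representation = 100·n₁/n, the model parameters m and sd of the first
component (not the empirical moments of the assigned days — at k = 1 this
makes sd exactly the ML standard deviation of the data), the empirical
min–max of assigned observations, and the annual mean M. The data minimum is
not forced into the first cluster; under a "V" fit a wide second component
can in principle claim it.

## Numerical choices

- **Convergence**: EM and Baum–Welch stop when |lnLₜ − lnLₜ₋₁| ≤
  tol·|lnLₜ| with tol = 10⁻⁵ (relative change), iteration cap 10⁵ standing
  in for "unlimited".
- **Variance floor**: component variances are clipped at 10⁻⁶ × var(data),
  preventing the likelihood singularities of components collapsing onto
  near-duplicate points. A fit that drives a component's responsibility mass
  to ~0 is flagged non-converged and excluded from selection.
- **Mixture initialization**: EM runs from two deterministic starts — (i) an
  M-step on the k contiguous equal-count blocks of the sorted data, and
  (ii) an M-step on a seeded k-means partition (same k-means settings as the
  km bridge) — keeping the better converged fit. The second start makes the
  EM fit provably at least as good as the km parameterization it refines
  (EM monotonicity), so the cross-technique BIC comparison is coherent:
  a hard-clustering bridge can never outscore the EM route at equal p. With
  a single quantile start this guarantee fails in practice (observed BIC
  deficits of tens of units on two-regime data at larger k).
- **HMM initialization**: means at the k mid-quantiles, variances at the
  data variance, 0.8 self-transitions, uniform δ; plus 5 seeded starts with
  mean perturbations of 0.25·sd(data). Best converged final likelihood wins.
  All randomness flows from `FitConfig.seed`, so every fit is reproducible.
- **Ordering and ties**: components/states are relabelled by ascending mean
  everywhere (δ, Γ, paths and responsibilities permuted consistently);
  Viterbi ties resolve toward the lower state index.
- **Missing days**: dropped, never imputed; the HMM treats observed days as
  consecutive (one Γ step per adjacent observed pair). With the low
  missing-day rates of validated monitoring data (a few % of the year) the
  bias on Γ is small; gap-aware transitions (Γ raised to the gap length)
  are a possible extension.
- **Aggregation**: a daily mean is emitted iff present/expected hours ≥ 0.8,
  where expected hours follow the day's clock length (23/25 on DST
  transition days for zone-aware input). The threshold is a ratio test, so
  a 24-hour day needs ≥ 20 present hours.

## Synthetic data

Real monitoring series are available only on request, so the generators in
`bgregime.simulate` define the test bed: Markov-switching Gaussian emission
series (chain started from the stationary distribution, optional sinusoidal
seasonal term, truncation at zero, independent missing days), i.i.d. mixture
series (the null case without serial dependence), and an hourly variant
(regime level + diurnal sinusoid + noise, with missing hours) that exercises
the completeness rule.

The preset corpus is 5 sites × 4 pollutants of persistent two-regime years
(self-transitions 0.95/0.90, 2% missing days, n = 365), with regime levels
and spreads on the magnitude scales typical of urban monitoring: CO
(180/450 ± 45/110), NO₂ (22/48 ± 5/9), O₃ (20/65 ± 6/13), PM₁₀
(18/45 ± 5/10) µg/m³. Means sit ≥ 3 sd above zero, so zero-truncation
touches well under 1% of draws and sample moments remain valid oracles.

What the generators do *not* emulate: autocorrelation within a regime,
heavy-tailed or skewed emission noise, meteorological covariates, spatial
correlation between sites, and instrument drift. Passing tests therefore
demonstrate correctness of the machinery and recovery under the stated
Gaussian-Markov conditions, not performance on arbitrary real-world series.
On the well-separated preset corpus all four techniques typically detect
k > 1; the HMM's advantage over k-means widens as regimes overlap, since
only the HMM can use persistence to separate them — tests assert the
ordering (hmm ≥ km), not a fixed gap.

## Problem sizes

Simulation-backed checks use 100 replicates of year-long series (n = 365)
for selection/recovery rates and the 20-series corpus for corpus-level
properties; exactness checks run 50 random parameter draws at n ≤ 8, k ≤ 3
where brute-force enumeration over all kⁿ sequences is the oracle. These
sizes give binomial standard errors of ≤ 5 percentage points on rates while
keeping a full run in minutes on one core.

## Known limitations

- One pollutant, one site at a time; no joint multi-pollutant modelling.
- BIC consistency holds for the mixture families used; for the km bridge the
  "likelihood" is a surrogate at a fixed point, so its BIC is conservative
  by construction (see the dominance bound).
- The HMM likelihood surface is multimodal; 1+5 starts are a pragmatic
  guard, not a global-optimum guarantee.
- No interpretation of the second and higher regimes is attempted, and no
  unit conversion is performed (CO in mg/m³ must be converted by the
  caller).
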