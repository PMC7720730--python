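# Methods

## Model and procedures

All nine tests operate on (or alongside) a fixed-effects one-way ANOVA of k
groups with sizes n_i, total N, group means m_i, within-group mean square
MSE on ν = N − k residual degrees of freedom. Observations are assumed
independent, normal, homoscedastic. For each unordered pair (i, j):

* **Pairwise t (Bonferroni / Šidák)** — pooled two-sample t using only the
  pair's own groups, df = n_i + n_j − 2; raw two-sided p adjusted by
  min(1, mp) (Bonferroni) or 1 − (1 − p)^m (Šidák) with m = k(k−1)/2.
* **Fisher's LSD (none / Bonferroni / Šidák)** — t = (m_i − m_j) /
  √(MSE(1/n_i + 1/n_j)) on ν df, same optional adjusters. The two families
  differ only in which variance is pooled into the standard error: the pair's
  own (t family) vs the ANOVA-wide MSE (LSD family). That distinction is the
  only reading under which the two corrected families are distinct
  procedures, and it is what this package implements.
* **Tukey HSD** — q = |m_i − m_j| / √((MSE/2)(1/n_i + 1/n_j)), referred to
  the studentized range of k means on ν df. The standardization is the
  Tukey–Kramer form, which reduces to classical HSD when all n_i are equal;
  it is used for all range-based tests under unequal n.
* **Scheffé's S** — for a contrast c with Σc_i = 0, SS_c = (Σc_i m_i)² /
  (Σc_i²/n_i) and F = (SS_c/MSE)/(k−1) on (k−1, ν) df; pairwise comparisons
  use ±1 contrasts. Since max_c SS_c equals the between-group SS, a pairwise
  Scheffé p can never undercut the omnibus p: the test is *protected*.
* **SNK / Duncan's MRT** — step-down multiple-range procedures on the ordered
  sample means (ties broken by group order; probability-zero events under the
  continuous generator). A pair spanning r ordered means is tested with the
  studentized range of r on ν df; a pair may only be rejected if every
  enclosing range is rejected (blocking). SNK runs every span at level α;
  Duncan runs span r at the inflated level α_r = 1 − (1−α)^(r−1).

### Decision-equivalent p-values for the step-down tests

Step-down procedures natively produce decisions, not per-comparison
p-values, yet pooled p-value distributions are one of the study's outputs.
The convention here: the stepwise tail probability p_r of each range is
mapped to the working-α scale (identity for SNK; 1 − (1 − p_r)^(1/(r−1)) for
Duncan, the exact inverse of the α_r inflation), and the reported p of a pair
is the maximum mapped p over its own range and all enclosing ranges. This
encodes blocking (a nonsignificant enclosing range forces p ≥ α) and makes
`reject ⇔ p < α` exact for every test, so error counting can be done
uniformly on p-values. It is one defensible convention; others exist, and
quantitative p-density shapes (not the decisions) depend on it.

## Studentized range evaluation

P(Q ≤ q | k, ν) is the classical double integral over the location of the
maximum and the scale estimate (a χ_ν/√ν variable). Both integrals use fixed
Gauss–Legendre rules (24 scale nodes on the central 1−2·10⁻¹² chi mass, 96
location nodes on |z| ≤ 8.5), fully vectorised over arrays of q — roughly
10⁴ times faster per value than scalar reference implementations at ~10⁻⁸
absolute accuracy (validated against `scipy.stats.studentized_range` and a
10⁶-draw Monte-Carlo oracle in the tests). k = 2 uses the exact closed form
2·P(T_ν > q/√2). Relative accuracy degrades below p ≈ 10⁻⁶; immaterial here,
since all decisions and histograms live on the α = 0.05 scale. Quantiles are
obtained by bracketed Brent root-finding on the sf (tolerance ≪ 10⁻⁶).

## Synthetic-data generator

The generator emulates a deliberately simple scenario: k groups of i.i.d.
Normal(μ_g, σ) observations, σ = 3 for every group (a noise level that
separates the competing tests without saturating them), μ all 0 for type-I
cells and (1, 0, …, 0) for type-II cells — a single "control vs treatments"
shift of 1. The grid crosses balance × error type × four treatments (n = 10
or 100; k = 3 or 7), 16 cells. Unbalanced cells cycle the size menus
{5,10,15} / {85,100,115} in group order — (5,10,15) for k = 3 and
(5,10,15,5,10,15,10) for k = 7 — so the mean size equals the balanced n; the
exact assignment and the shifted group's identity are open choices (both
configurable), and unbalanced/type-II magnitudes are sensitive to them even
though the qualitative orderings are not. The generator does *not* emulate
skewness, heteroscedasticity, dependence, or multiple shifted means, so
passing benchmarks say nothing about the tests' behaviour under those
violations — only about their error-rate trade-offs when their own
assumptions hold.

Randomness: iteration i of design d draws from
`SeedSequence([master_seed, d, i])`, so every dataset is reproducible in
isolation and streams are independent across cells and iterations. Default
master seed 20240501.

## Error metrics

PCER is pooled over iterations: type-I = (#rejections)/(#all pairs ×
iterations) on complete-null cells; type-II = (#non-rejections among pairs
involving the shifted group)/(#those pairs × iterations). The asymmetric
denominators are intentional — under the null every pair can produce a false
positive, while only shifted-vs-null pairs can produce a miss. Pooling (vs
averaging per-iteration rates) has identical expectation and slightly
different variance. p-value distributions are pooled per test × cell and
binned at width 0.05, matching the granularity at which "peak near one" vs
"flat" density shapes are compared; no kernel smoothing.

## Problem sizes and numerical choices

Routine runs use 100 iterations per cell; ranking-stability checks and the
benchmark suite use 1,000 (orderings do not change beyond Monte-Carlo noise
between the two, which the per-cell binomial SEs make plain). Calibration
and power checks against closed forms use 10,000 single-cell iterations.
Degenerate draws (zero within-group variance — impossible under σ > 0 but
reachable through user configs) raise errors in the library and are
skipped-and-counted by the study runner rather than resampled, keeping RNG
streams aligned; silently reporting p = 0 would corrupt error-rate
estimates. α defaults to 0.05 everywhere and m = k(k−1)/2 always (all
pairs), matching the all-pairs extraction of the study.

## Known limitations

* The rejection-nesting chain Scheffé ⊆ Tukey ⊆ SNK ⊆ Duncan ⊆ LSD is
  provable under equal-n standardization; under Tukey–Kramer standardization
  with very unequal n an enclosing range can in principle standardize
  smaller than an inner pair, so the property tests exercise balanced draws
  (no unbalanced counterexample was observed in practice).
* Decision-equivalent p-values for SNK/Duncan are a convention; only their
  decisions are canonical.
* Nonparametric MCTs, Dunnett/Ryan/Waller–Duncan, FDR procedures, GLM
  link-scale comparisons and factorial interactions are out of scope.
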