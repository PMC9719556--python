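# Methods

## Segregation model

A mother clone carries `n` ISEs that segregate independently of the
regular chromosome set during female meiosis. The model assigns each
of the `2^n` pole configurations (every ISE to the egg pole or to a
polar body) a multiplicative weight: one marginal factor per element
(`1+tb` egg, `1−tb` polar body) and one interaction factor per
unordered pair (`1+cb` same pole, `1−cb` opposite poles). Class
frequencies are the normalised weight mass per egg-pole count `k`.
Because the weight depends on a configuration only through `k`
(`C(k,2)+C(n−k,2)` same-pole and `k(n−k)` opposite-pole pairs), the
implementation evaluates the closed form over `k` rather than looping
over `2^n` outcomes; a test verifies the equivalence by brute-force
enumeration of pole vectors, and a multinomial Monte-Carlo sampler
provides an independent stochastic check.

Assumptions and properties:

- `tb` and `cb` are clone-level constants: every element shares one
  drive strength, every pair one interaction. With per-pair factors
  applied multiplicatively to all pairs, the model extends the pairwise
  definition of cosegregation to `n ≥ 3` in the simplest exchangeable
  way. Other joint laws consistent with the pairwise definition exist;
  this one reproduces the two printed single-parameter cases exactly
  (transmission rate `(1+tb)/2` for one element; O/E = (0.7, 1.3, 0.7)
  at `n=2, cb=−0.3`) and degrades to Binomial(`n`, `(1+tb)/2`) at
  `cb = 0`.
- Parameters are restricted to the open interval (−1, 1). At
  `|cb| = 1` with `n ≥ 3` every configuration has zero weight (no
  assignment of three elements to two poles keeps all pairs on opposite
  poles), so the boundary is rejected rather than special-cased; the
  fitting grid stops at ±0.95.
- GS classes are indexed by the number of ISEs carried. Unequal ISE
  sizes shift the fluorescence position of a class member but not the
  class frequencies; the karyotype helper can place any carried subset
  on the genome-size axis. The female 2C reference is
  `2·core + Σ ISE sizes` (ISEs are unpaired in the diploid female).
- Enumeration is capped at `n = 12`; beyond it the model directs users
  to the Monte-Carlo path. Resolvable clones in practice have ≤ ~5
  elements.

## Grid fitting

The estimator evaluates the model at every combination of
`tb, cb ∈ {−0.95, −0.90, …, 0.95}` (default step 0.05, configurable)
and minimises the root-mean-squared error between predicted and
observed class-frequency vectors. RMSE is computed on frequencies, not
O/E ratios — frequencies are the model's output; O/E is a display
transform that amplifies the extreme classes. Ties within `1e−12` are
broken toward the smallest `|tb| + |cb|` (the most parsimonious
deviation from unbiased segregation), then lexicographically, so
results are deterministic. The full surface is returned for
inspection. For single-ISE clones the pair interaction never acts, so
`cb` is reported as NaN and the search is one-dimensional. When a
clone has replicate samples the pipeline fits the mean of the replicate
frequency vectors (renormalised); fitting replicates individually is
available through `fit_many`.

No confidence intervals are produced: the grid-search estimator is
kept deliberately simple, and sampling error is instead characterised
by the recovery tests (estimates land within one grid step of the
generating values at realistic sample sizes).

## Mixture decomposition

Fluorescence samples are modelled as finite mixtures of skew-normal
components (family `normal` available as a restriction; both share one
EM implementation). The skew-normal EM uses the convolution
representation `X = ξ + Δ|t| + e`, `t ~ N(0,1)` truncated to (0, ∞),
`e ~ N(0, Γ)`, with closed-form conditional moments of `t` and exact
M-step updates; the skew-normal density itself is evaluated through
`scipy.stats.skewnorm`. The component count `g` is chosen by BIC over
`g ∈ [g_min, g_max]` (default 3–8): the upper end intentionally
exceeds the number of GS classes because surplus components absorb
background fluorescence and split classes, improving resolution; they
are merged again downstream. A skew-t family (heavier tails) would
add robustness to instrument outliers at the cost of a substantially
more involved EM; the generator produces Gaussian peaks, and the
class-merging logic — the analysis-specific part — is family-agnostic,
so skew-t is intentionally not implemented and requesting it raises.

Numerical choices:

- Initialisation is a deterministic quantile split of the sorted
  events (equal-count chunks give starting weights, locations and
  scales; the starting skewness `±0.5` takes its sign from the chunk's
  sample skewness, since zero is a fixed point of the skewness update).
  Identical inputs therefore give identical fits; seeded random
  restarts occur only if a component loses essentially all posterior
  mass, bounded at three.
- Convergence: relative log-likelihood change below `tol` (default
  `1e−5`) or `max_iter` (default 1000) sweeps. Scales are floored at
  `1e−3` of the data standard deviation to prevent collapse.
- BIC uses `3g−1` free parameters for the normal family and `4g−1`
  for skew-normal.

Components are mapped to the nearest expected class position (male
genome size relative to the female 2C, scaled to the female
internal-standard peak) if within a ±5% relative window; components on
one class merge (weights summed, position weight-averaged using
component means, which include the skewness offset). Components outside
every window — or with weight < 0.02 and scale above 3× the
weight-weighted median scale of matched components — are background.
Adjacent expected positions closer than twice the window raise an
error: such classes are unresolvable by this instrument resolution, as
happens in clones with very many elements, and only density summaries
are meaningful there. After background removal, class proportions are
renormalised to one.

QC follows the female internal standard: its peak CV (robust estimate,
`1.4826·MAD/median`, which equals sd/mean for a clean Gaussian peak but
ignores debris events under the peak window) must not exceed 3.5%, or
the sample is excluded — excluded samples are reported, never silently
dropped.

## Count reconstruction and G-tests

Flow cytometry yields proportions; tests need counts. Counts are
reconstructed from the known number of males per sample by
largest-remainder (Hamilton) rounding, which preserves the total
exactly; remainder ties go to the lower class index for determinism.
The G statistic is `2 Σ O ln(O/E)` with `0·ln 0 = 0`, df = classes − 1,
p-values from the χ² upper tail; the Williams small-sample correction
is available behind a flag but off by default (the plain G formula).
Replicated tests decompose `total = pooled + heterogeneity` — an exact
algebraic identity for both G and df (heterogeneity df
`(replicates−1)(classes−1)`), verified to `1e−9` in tests, with null
calibration of both component tests checked by simulation.

## Synthetic data

The generator emulates the measurement, not the instrument: per-class
Gaussian peaks (CV configurable within 0.5–6%, defaults in the
empirically observed 1.7–3.95% female-peak range; skewness is left to
the mixture model to handle, not injected), a female internal-standard
peak at a fixed reference channel (1000), and uniform debris over
0.2–1.2× that channel at a configurable fraction (default 5%) — a
deliberately simple background model. Defaults are one sample of 200
males (the practical upper limit of manual male isolation) at 25
events per male and 2000 female events. Stage series (sync / accum /
hatched) share one meiotic class distribution unless per-class
viability weights are configured, modelling post-meiotic selection as
differential survival. The hatching-rate generator draws egg-level
Bernoulli outcomes with a logit-linear genome-size effect for males
and a flat rate for females, for use with any off-the-shelf binomial
GLM.

What passing tests show — and do not: synthetic peaks are Gaussian,
background is uniform, and event counts are balanced across males, so
end-to-end recovery results demonstrate the correctness of the
machinery under controlled conditions, not robustness to instrument
drift, asymmetric peaks, doublet contamination or unequal staining,
which real samples exhibit.

## Problem sizes and tolerances in the test suite

Enumeration-level claims are tested exactly (`1e−12`). Stochastic
claims use fixed seeds and conventional error bands: Monte-Carlo vs
enumeration within 4 standard errors at 10⁵ males over 20 random
parameter triples; grid recovery within one grid step from 5·10⁴
multinomial males; full-loop (events → mixture → fit) recovery within
one grid step at CV ≤ 3% with ~4·10⁴ events per sample, median over 3
seeds; mixture class-proportion recovery within 0.05 across the
1.7–3.9% CV range with classes ≥ 4 CVs apart, median over 3 seeds per
CV; G-test null calibration over 600 simulated replicate sets. These
sizes keep the full suite at a few minutes on one CPU while leaving
the acceptance bands unchanged.

## Known limitations

- The joint segregation law for `n ≥ 3` is one exchangeable extension
  of the pairwise definition of cosegregation; data with three or more
  elements cannot currently discriminate alternatives.
- The grid estimator reports point estimates only.
- Clones whose classes overlap beyond the window rule (very many or
  very small ISEs) are out of reach of class-resolved analysis by
  construction; the package raises rather than guessing.
- The skew-t mixture family is not implemented (see above).
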