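# Methods

## Scope and flow

The package turns a table of published vital-rate estimates into (i)
synthesised per-rate means with uncertainty, (ii) a stage-structured
projection matrix and its perturbation analysis, and (iii) a comparison of
per-transition study effort against per-transition demographic importance.
The stages are independent: the matrix can be built directly from a set of
mean rates without running the synthesis, and the mismatch statistic works
for any importance/effort fractions.

## Evidence database and screening

A record is one published estimate of one vital rate, carrying provenance
flags: whether the estimate was verified in its original source, whether it
is the midpoint of a reported range, the sex of the sampled birds, and an
independence-group label tying together estimates that draw on the same
underlying data. The default screening policy retains unverified and
midpoint estimates (their influence is assessed separately by
`sensitivity_compare`, which re-runs the synthesis without them and checks
whether each mean lies inside the other's 95% interval) and drops male-only
and mixed-sex **survival** estimates, because the projection is
female-based and survival estimates derive from nesting females;
nest-based rates (clutch size, hatching success, etc.) are inherently
female and exempt.

Independence is resolved per vital rate before synthesis: groups of
spatiotemporal replicates within a study are collapsed by a
sub-meta-analysis (the same estimator as the main synthesis, or a simple
mean when sample sizes are absent), while groups of genuinely competing
records need an explicit rule (`most_precise`, `largest_n`,
`{"keep": study_id}`, or a callable). Rules are data-driven because such
conflicts are resolved case-by-case in practice; an unresolved group is an
error, never silently averaged.

## Synthesis estimator

The weighted path is a one-sample random-effects model with mean-adjusted
precision weighting:

- s² = arithmetic mean of available study-level variances sᵢ²;
- vᵢ = s²/nᵢ for **every** study, including those that reported no
  variance — the point of the adjustment is that replication alone earns a
  weight, and a pooled variance removes the bias that poorly replicated
  studies introduce when they supply their own;
- T² = max(0, var(δᵢ) − mean(vᵢ)), a Cochran-type moment estimator with
  the (k−1)-divisor sample variance. The truncation at zero is the
  standard repair: a negative between-study variance is meaningless and
  would break the weights.
- Wᵢ = 1/(vᵢ + T²); mean ΣWᵢδᵢ/ΣWᵢ; meta-variance 1/ΣWᵢ.

Studies without a sample size cannot receive an error variance and are
excluded from the weighted path (the simple-mean path ignores n entirely).
The sᵢ² fed to the scheme are study-level variances as published — a
squared standard error where one was reported.

Method selection is deliberately conjunctive: a rate falls back to the
simple mean only when it has fewer than 20 independent estimates **and**
more than a third of them lack sample sizes. Either condition alone leaves
the weighted scheme usable. Both thresholds are configurable. For the
simple-mean path the reported variance is the (k−1)-divisor sample variance
of the estimates (zero for a single estimate), the natural dispersion
statement when no weighting is defensible.

Calibration (reproduced by the test suite and `examples/05`): across 1000
synthetic evidence bases with k = 30 studies, true mean 0.86, between-study
variance 0.001 and within-study variance 0.05, the synthesis mean is
unbiased to well under 0.005 and the nominal 95% interval covers the truth
with frequency ≈ 0.94; the T² estimator recovers a true value of 0.01
within 10% on average at k = 30, n = 20.

## Life cycle and matrix

Six stages, prebreeding census, female-only, birth-pulse. Choices that
matter:

- **Recruitment propensities are conditional.** BPₓ is the probability of
  recruiting at age x given not yet recruited, so they enter the matrix
  elements directly: (B ← 1yo) = s₂·BP₂, (PB3 ← PB2) = s_a·(1 − BP₃), and
  so on. BP₅ = 1 pins full recruitment by age 5.
- **Column survival.** The 1yo column uses second-year survival s₂ (those
  birds are living their second year during the projection interval); all
  older columns use adult survival s_a, there being no evidence base for
  age-splitting adult survival further.
- **Nonbreeder stage.** Surviving adults leave/re-enter breeding with the
  complementary propensities BP_eb and 1 − BP_eb; breeders and nonbreeders
  share s_a because disaggregated survival estimates do not exist. Setting
  BP_eb = 1 collapses the model to a standard breeder-only cycle (the NB
  stage becomes unreachable and carries zero stable-stage mass; the
  analysis handles this reducible case by accepting the zero-mass stage).
- **Fertility.** F = ½·CS·HS·s₁ sits only in the (1yo ← B) cell; fertility
  may exceed 1, all other entries are probability products and are
  validated to [0, 1].

### The first-year-survival ambiguity

The evidence base measures first-year survival two ways: directly from
hatching (mean 0.37) and as fledging success × survival from fledging
(0.22 × 0.75 = 0.165). The three supported pathways (`direct`,
`fledging_product`, and their unweighted `pooled` mean, the default for
general use) give materially different fertilities (0.46 / 0.21 / 0.33 at
the mean rates) and growth rates (1.08 / 0.98 / 1.03). Which pathway
produced the published headline growth rate of 0.99 is not recorded with
the mean estimates, so the workflow sweeps all three and
`select_mode` identifies the closest to the published headline quartet
(λ = 0.99, continued breeding 38%, state switching 24%, fertility 11%).
At the two-decimal published means the fledging-product pathway is closest,
agreeing with each published number to within one integer-percent point
(λ 0.98, 39/25/10%) — the residual gap is consistent with the published
analysis having used unrounded synthesis output. The published values are
used only to *select* the pathway; every reported number is computed from
the matrix.

A note on grouping: the published "24%" refers to the two transitions
*between* breeding and nonbreeding states (B→NB plus NB→B, which are
always equal by the structure of the adult block). Continued nonbreeding
(NB→NB, ≈ 4%) belongs to the broader four-cell "Breeding transitions"
group used for the study-effort comparison but not to the switching sum;
`nonbreeder_pathway_summary` reports all components separately.

## Perturbation analysis

A dense eigen-decomposition (`numpy.linalg.eig`) of the full matrix; the
dominant pair is chosen by largest real part, small imaginary/negative
components (numerical fuzz on a Perron root) are clipped at 1e-12, and a
complex dominant value beyond 1e-9 raises a degeneracy error rather than
guessing. w is scaled to sum 1, v so that ⟨v, w⟩ = 1; elasticities follow
as (aᵢⱼ/λ)vᵢwⱼ. Invariants enforced by tests: elasticities are nonnegative,
sum to 1 within 1e-10, vanish on structural zeros, have equal row and
column sums per stage, and match central finite differences of λ within
1e-4 relative error. Reported percentages round half away from zero to
match how integer percentages are conventionally printed.

## Study-effort mismatch

A study counts toward a transition group if it estimates any vital rate
underlying that group; adult survival underlies both the later recruitment
transitions and the breeder/nonbreeder transitions, so its studies count
toward both groups and group fractions need not sum to 1. Fractions are
never renormalised. The chance-deviation probability uses a Uniform(0, 1)
null for effort, independent of importance — the unique model consistent
with the one-sided worked rules P(over) = 1 − f and P(under) = f. The
simplex simulation (flat Dirichlet draws) is provided separately to make
the qualitative point that random fraction sets summing to one tend to
have one large and several small components; it is a companion
illustration, not the source of the reported probabilities.

## Synthetic data generator

Studies draw δᵢ ~ Normal(θ, T²_true + σ²/nᵢ) truncated to the rate's
domain, with nᵢ uniform on a configurable range; reported variances are
chi-square-noised estimates of the within-study variance σ² with nᵢ − 1
degrees of freedom; sample sizes, variances and provenance flags are
omitted/assigned with configured probabilities; replicate studies emit
per-year draws sharing a study identifier and independence group. Each
(rate, study) pair has its own counter-based substream, so enlarging a
database never perturbs earlier studies and output is byte-reproducible.

Truncated-normal rather than logit-normal noise is used because the
estimator operates on the raw probability scale; at realistic parameter
values (means well inside the unit interval, standard deviations below
~0.1) truncation bias is negligible, and the degenerate-configuration tests
monitor it. What the generator does **not** emulate: spatial covariance
among colonies, temporal autocorrelation and rate covariation, publication
bias, or heaped/rounded reporting — so passing recovery tests demonstrate
estimator correctness under the assumed model, not robustness to those
real-data features.

## Problem sizes and numerical choices

Monte-Carlo checks use 1000 replicate evidence bases for estimator
calibration, 10⁴ draws for the simplex closed-form checks (tolerance three
binomial standard errors) and 10⁵ draws for the null-consistency check
(tolerance 0.01) — sizes at which the checks are sharp yet the whole suite
runs in well under a minute apart from the calibration loop. Ties in the
pathway sweep break toward the documented mode order; the truncated-normal
generator retries up to 1000 rejections before clamping with a warning.

## Limitations

- Deterministic, time-invariant, density-independent projection; no
  transient analysis, no stochastic λ, no retrospective (LTRE) analysis.
- Single-sex (female) model; male demography enters only through screening.
- The synthesis assumes independent normal study means; small-sample and
  boundary rates (propensities near 1) are handled by truncation, not by a
  link function.
- The fertility-pathway selection is a model-identification step against
  published headline values, needed only because the pathway metadata is
  absent; all three pathways remain first-class and selectable.
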