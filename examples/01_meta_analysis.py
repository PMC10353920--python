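"""Precision-weighted synthesis of vital-rate estimates.

Runs the mean-adjusted random-effects synthesis on a tiny two-study
example, then on a synthetic 30-study evidence base with known truth.
"""

import numpy as np

import demosynth as ds

# Two studies of adult survival: means 0.8 and 0.9, both reporting a
# study-level variance of 0.01, with sample sizes 10 and 40.
result = ds.random_effects_meta([0.8, 0.9], [0.01, 0.01], [10, 40])
print("two-study synthesis:")
print(f"  pooled study variance s2 = {result.s2_pooled:.4f}")
print(f"  between-study variance T2 = {result.T2:.6f}")
print(f"  weighted mean = {result.mean:.5f}  (weights favour the larger study)")
print(f"  meta-variance = {result.variance:.7f}")

# A synthetic evidence base: true mean 0.86, modest between-study spread.
config = ds.RateConfig(
    true_mean=0.86,
    between_study_sd=float(np.sqrt(0.001)),
    within_study_variance=0.05,
    n_studies=30,
)
records = ds.generate_database(ds.SyntheticConfig(rates={"sa": config}, seed=0))
synthesis = ds.synthesize(records)
lo, hi = synthesis.ci()
print(f"\n30-study synthetic base (truth 0.86):")
print(f"  method = {synthesis.method}, k = {synthesis.k}")
print(f"  mean = {synthesis.mean:.4f}, 95% interval [{lo:.4f}, {hi:.4f}]")
print("  the interval should cover 0.86 in ~95% of regenerated bases")
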