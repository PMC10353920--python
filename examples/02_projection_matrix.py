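"""Assemble the 6-stage prebreeding projection matrix for the common eider.

Uses the published species-wide mean vital rates and prints the matrix and
its asymptotic growth rate.  Breeding propensity 0.72 routes 0.28 of
surviving adults to the reversible nonbreeder stage each year.
"""

import demosynth as ds

rates = ds.EIDER_MEAN_RATES
matrix = ds.build_matrix(rates, mode="fledging_product")

print("stage-structured projection matrix (columns: stage in year t):")
print(matrix.to_dataframe().round(4))

lam = ds.growth_rate(matrix)
print(f"\nfertility (daughters per breeder) = {ds.fertility(rates, 'fledging_product'):.4f}")
print(f"asymptotic growth rate lambda = {lam:.4f} (~{100 * (lam - 1):.1f}% per year)")
print(f"breeder -> nonbreeder entry = sa * 0.28 = {matrix['NB', 'B']:.4f}")
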