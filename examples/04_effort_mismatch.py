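"""Compare study effort against demographic importance per transition group.

Importance is the summed elasticity of a transition group; effort is the
fraction of studies informing it (published counts: 39 recruitment, 38
breeding-transition and 103 reproduction studies out of 129).  The chance
probability is the likelihood, under a uniform null, of a deviation from
the 1:1 line at least as large on the same side.
"""

import demosynth as ds

sweep = ds.mode_sweep(ds.EIDER_MEAN_RATES, modes=["fledging_product"])
importances = sweep["fledging_product"].group_sums
efforts = ds.fractional_effort(ds.EIDER_STUDY_COUNTS)

table = ds.mismatch_table(importances, efforts)
print(table.round(3).to_string(index=False))

print(
    "\nreproduction is studied far beyond its influence on lambda ('over'),"
    "\nwhile the breeder/nonbreeder transitions are understudied ('under')."
)

# the null surface behind the probabilities, on a coarse grid
grid = ds.contour_grid(step=0.1)
print(f"\nnull contour grid: {len(grid)} cells, e.g. "
      f"importance 0.3 / effort 0.6 -> "
      f"{float(grid.query('importance == 0.3 and effort == 0.6').probability.iloc[0]):.1f}")
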