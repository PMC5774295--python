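"""Project the model across periods and quantify the range dynamics.

Projects the fitted model onto all four climate periods (with clamping to
the training range), binarizes at the MTSS threshold, and prints per-
transition change tables, the overall centroid vector and the block-level
migration vectors.
"""

import numpy as np

from rangeshift import (
    SyntheticSpec, binarize, bias_surface, block_centroids, centroid_vector,
    change_map, change_table, make_bias_grid, make_climate_series,
    migration_vectors, mtss_threshold, predict_logistic, replicate_runs,
    sample_background, sample_occurrences, thin, true_suitability,
)
from rangeshift.dynamics import CentroidError

spec = SyntheticSpec(seed=0)
stacks = make_climate_series(spec)
present = next(s for s in stacks if s.period_label == "present")
truth = true_suitability(present, spec)
occ = thin(sample_occurrences(truth, make_bias_grid(present.template, spec), 200, 1), 10.0)
background = sample_background(bias_surface(occ, present.template, 60.0), 5000, 2)
report, model = replicate_runs(occ, background, present, k=5, seed=3)

names = model.features.var_names
pres_scores = model.predict_values(present.values_at(occ.xy[:, 0], occ.xy[:, 1], names))
bg_scores = model.predict_values(present.values_at(background.xy[:, 0], background.xy[:, 1], names))
t = mtss_threshold(pres_scores, bg_scores)
print(f"MTSS threshold: {t:.4f}\n")

binary = {s.period_label: binarize(predict_logistic(model, s), t, s.period_label)
          for s in stacks}
for label, bmap in binary.items():
    print(f"{label:>8}: suitable area {bmap.area_km2 / 1e4:8.1f} x10^4 km^2")

for early, late in zip(stacks, stacks[1:]):
    e, l = binary[early.period_label], binary[late.period_label]
    table = change_table(change_map(e, l))
    print(f"\n{table.pair_label}:")
    print(f"  contraction {table.areas['contraction'] / 1e4:7.1f} x10^4 km^2"
          f"  ({table.ratio_contraction}% of the earlier range)")
    print(f"  no change   {table.areas['no_change'] / 1e4:7.1f} x10^4 km^2"
          f"  ({table.ratio_no_change}% of the earlier range)")
    print(f"  expansion   {table.areas['expansion'] / 1e4:7.1f} x10^4 km^2"
          f"  ({table.ratio_expansion}% of the later range)")
    try:
        v = centroid_vector(e, l).vectors[0]
        print(f"  overall centroid shift: {v.distance_km:.0f} km at bearing {v.bearing_deg:.0f} deg")
        field = migration_vectors(block_centroids(e, 60.0), block_centroids(l, 60.0))
        med = np.median([w.distance_km for w in field.vectors])
        print(f"  {len(field)} block migration vectors, median length {med:.0f} km")
    except CentroidError as exc:
        print(f"  vectors unavailable: {exc}")
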