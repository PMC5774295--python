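"""Attribute range changes to the climate variable limiting suitability.

For each transition, finds the per-cell limiting factor on the later
period's climate (the variable whose substitution by its presence-sample
mean most raises the prediction) and prints the percentage share of each
variable within the contraction and expansion classes.
"""

import numpy as np

from rangeshift import (
    SyntheticSpec, binarize, bias_surface, change_map, factor_shares,
    limiting_factor_map, make_bias_grid, make_climate_series, mtss_threshold,
    predict_logistic, presence_variable_means, replicate_runs,
    sample_background, sample_occurrences, thin, true_suitability,
    variable_change_map,
)

spec = SyntheticSpec(seed=0)
stacks = make_climate_series(spec)
present = next(s for s in stacks if s.period_label == "present")
truth = true_suitability(present, spec)
occ = thin(sample_occurrences(truth, make_bias_grid(present.template, spec), 200, 1), 10.0)
background = sample_background(bias_surface(occ, present.template, 60.0), 5000, 2)
_, model = replicate_runs(occ, background, present, k=3, seed=3)

names = model.features.var_names
pres_scores = model.predict_values(present.values_at(occ.xy[:, 0], occ.xy[:, 1], names))
bg_scores = model.predict_values(present.values_at(background.xy[:, 0], background.xy[:, 1], names))
t = mtss_threshold(pres_scores, bg_scores)
means = presence_variable_means(present.subset(names), occ)

for early, late in zip(stacks, stacks[1:]):
    cmap = change_map(
        binarize(predict_logistic(model, early), t, early.period_label),
        binarize(predict_logistic(model, late), t, late.period_label),
    )
    lfmap = limiting_factor_map(model, late.subset(names), means)
    print(f"\n{cmap.pair_label}:")
    for cls in ("contraction", "expansion"):
        row = factor_shares(lfmap, cmap, cls)
        if row.undefined:
            print(f"  {cls}: no cells in this class")
            continue
        top = row.shares[row.shares["share_pct"] > 0].head(3)
        pretty = ", ".join(f"{r.variable} {r.share_pct}%" for r in top.itertuples())
        print(f"  {cls} ({row.n_cells} cells): {pretty}")
    # how much did the top factor itself change between the periods?
    lead = factor_shares(lfmap, cmap, "contraction")
    if not lead.undefined and lead.shares.iloc[0]["variable"] != "none":
        var = lead.shares.iloc[0]["variable"]
        delta = variable_change_map(early, late, var)
        print(f"  mean change in {var} (late minus early): {np.nanmean(delta.values):+.1f}")
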