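# Methods

This note documents the models, conventions and design choices behind
`rangeshift`, in the order the pipeline applies them.

## Scope and coordinate model

All analysis happens on pre-projected planar grids treated as equal-area:
a `Grid` is a 2-D value array, a north-up affine transform in metres
(row 0 = northernmost row, x east, y north, coordinates at cell centres)
and a nodata mask. The package never reprojects; occurrence coordinates
and rasters are expected in the same projected CRS. Cell area is
|dx·dy| / 10^6 km², so areas are cell counts times a constant. Grids
must align within 1e-6 of a cell width to stack; a looser tolerance
would mask genuine misregistration while a stricter one breaks files
round-tripped through text formats. The analysis extent is whatever the
input rasters cover — it is a property of the data, not of the method.

## Spatial thinning

The thinning objective is the maximum number of retained localities with
all pairwise distances ≥ d (default 10 km). Records closer than d form a
conflict graph; the retained subset is a maximum independent set,
computed exactly per connected component by bitset branch and bound for
components up to 25 records. The search visits records in sorted-id order
with the include-branch first and replaces the incumbent only on strict
improvement, which makes the tie-break deterministic and id-lexicographic.
Components above 25 records fall back to a randomized greedy with 1000
seeded restarts, keeping the best subset (largest, then lexicographically
earliest). Exactness at the tens-of-records scale typical of rare-species
datasets is cheap; the greedy bound keeps worst-case time in check for
dense datasets.

## Sampling-bias surface and background

Collections are spatially biased, which violates the equilibrium
assumption of presence-background models. The bias surface is a Gaussian
kernel density of the (thinned) occurrences with σ equal to the search
radius (default 60 km) and the kernel truncated at 3σ, rescaled to a
maximum of 1. "Search radius" conventions vary between tools (bandwidth,
σ, truncation radius); σ-with-truncation was chosen as the most common
reading and is a single parameter either way. With no occurrences the
surface degenerates to 1 on every unmasked cell (uniform background) by
documented fallback. Background cells (default 10 000, presence cells
eligible) are drawn without replacement with probability proportional to
the bias value, so the background carries the same spatial sampling
artifact as the presences and the model's contrast isolates climate.

## Variable screening

Pearson correlations are computed over all unmasked study-region cells
(not only occurrence cells — the model must discriminate over the whole
region, and cell-level correlation is the better-conditioned estimate).
Pruning removes variables until no retained pair exceeds the threshold
(default |r| > 0.85), handling the most-correlated pair first; a
physiological priority list decides survivors, otherwise the variable
with the lower mean absolute correlation to the others is kept, with
lexicographic tie-breaks throughout so results are order-independent.
The jackknife refits the model with each variable alone and with each
variable left out, reporting regularized training gains (penalized
log-likelihood improvement over the uniform model, hence non-negative)
and training AUCs. A percentage-contribution cutoff for dropping
low-contribution variables is reported but never applied silently; the
pipeline keeps every variable that survives correlation pruning.

## Maximum-entropy model

Features: linear ((v − min)/(max − min)), quadratic (its square) and
hinge (max(0, (v − k)/(max − k)) at 16 evenly spaced knots per variable),
bounds taken from the training data, everything in [0, 1]. This is the
standard feature complement for sample sizes in the tens-of-presences
range; classes and knot count are configurable. Constant variables lose
their features with a warning.

Fit: maximize (1/m) Σ η(x_i) − log Z − Σ β_j |λ_j| with per-feature
penalties β_j = β·s_j/√m, s_j the presence-sample feature standard
deviation floored at 5% of the feature's range (β defaults to 1). The
problem is solved in two stages: the smooth bound-constrained split
λ = λ⁺ − λ⁻ via L-BFGS-B, then proximal-Newton polish — exact Hessian of
log Z on the working set (active coefficients plus the worst violators,
capped at 300), an L1 quadratic subproblem by coordinate descent, and a
line search on the true objective. L-BFGS-B alone stalls around 1e-4
subgradient violation on ill-conditioned hinge sets because float-level
objective changes vanish before the gradient does; the Newton stage
reaches the 1e-6 tolerance regardless of conditioning. Accepted steps
never decrease the objective, so the recorded objective history is
monotone. If presences lie outside the background's feature support the
likelihood is unbounded (complete separation) and the fit raises an
error instead of returning a runaway model.

Output: the logistic transform p = e^H q / (1 + e^H q) with H the
entropy of the fitted distribution over the training background, chosen
over the cloglog alternative; an uninformative model (all λ = 0) scores
exactly 0.5 everywhere. Projection onto another period clamps variable
values to the training bounds by default — transfer beyond the training
range is exactly where unclamped features extrapolate wildly.

Evaluation: k seeded random presence splits (default 10 at 75/25; the
test partition gets ⌊(1−f)·m⌋ records, remainder trains), rank-based AUC
with ties counted ½, presences against the shared background. The model
used for mapping is refit on all presences: replicate models answer the
stability question, while the map should use every datum.

## Thresholds and change accounting

MTSS scans the union of observed scores and returns the smallest
threshold maximizing sensitivity(presences ≥ t) + specificity(background
< t); the background plays the negative class, matching the training-data
threshold convention of presence-background practice. The 10% training
presence threshold is the (⌊0.1·m⌋+1)-th order statistic of presence
scores. Binarization marks unmasked cells with score ≥ t; a cell exactly
at the threshold is suitable.

Change classes per cell: contraction (suitable early only), no change
(both), expansion (late only), absent (neither; masked cells are absent).
Class areas satisfy the identities early = contraction + no-change and
late = no-change + expansion exactly on unrounded values. Percentage
ratios divide contraction and no-change by the earlier-period area and
expansion by the later-period area, rounded to one decimal half away
from zero (fixed so table outputs are reproducible across platforms).
`change_ratios` also accepts explicit period-area denominators for
re-deriving ratios from published tables whose class areas were rounded
independently of the period totals. Zero denominators yield undefined
(None) ratios, never 0.

## Centroids and migration vectors

The overall centroid is the unweighted mean of suitable-cell centres;
one vector connects the earlier to the later centroid (distance in km,
bearing clockwise from north). Block vectors partition the raster into
block × block tiles (default 60 km) anchored at the raster origin —
deterministic and mask-independent, partial edge tiles allowed — take
per-tile centroids of suitable cells, and link each later-period centroid
to its nearest earlier-period centroid (ties: smallest distance, then
lexicographic coordinate order). Matching runs from the later period
back to the earlier one, so every new range patch is assigned the source
it most plausibly came from; earlier centroids never chosen (vanished
patches) are reported separately rather than vectorized, since a vector
from a patch that left no successor has no migration reading.

## Limiting factors

At each cell the prediction is recomputed with each model variable in
turn replaced by its mean at the presence localities (clamping as in
projection); the limiting factor is the variable whose substitution
raises the logistic output most, ties going to the first variable in
model order, and no factor is assigned where no substitution helps.
Substitution-by-presence-mean is the convention of the established
limiting-factor tooling; per-variable-optimum substitution is a known
alternative and out of scope. Shares per change class count cells (the
equal-area grid makes counts proportional to area) and include a "none"
row so unrounded shares sum to exactly 100%. In the pipeline the
limiting-factor map for a transition is evaluated on the *later* period's
climate for both contraction and expansion classes: the later climate is
the one doing the limiting after the change. Between-period difference
maps are always later minus earlier.

## Synthetic data generator

The generator emulates what the pipeline needs from real bioclimatic
data, at a continental-subregion scale: a 120 × 120 grid of 10-km cells,
six bioclim-style variables (mean annual temperature, temperature
seasonality, coldest-month minimum, annual precipitation, driest-month
precipitation, warm-quarter precipitation), four periods. Each variable
is a smooth directional gradient (temperatures rising southward,
seasonality northward, precipitation toward the southeast) plus Gaussian
noise smoothed at a 50-km correlation length; the standardized fields
are whitened and re-coloured by a Cholesky factor so designated pairs hit
their target correlation exactly (default: r = 0.9 between mean annual
temperature and coldest-month minimum, the classic collinear pair).
Periods share base fields and differ by additive offsets following the
glacial-interglacial pattern: the glacial maximum about 5.5 °C colder in
the annual mean and 8 °C in the winter minimum, 300 mm drier, more
seasonal; the interglacial slightly warmer than present; 2080 about
3.2 °C warmer. Ground truth is a logistic-linear function of the
standardized variables with fixed reference means/sds (so offsets
genuinely move suitability); the default coefficients describe a warm,
winter-mild, wet-adapted, seasonality-averse species, and the intercept
of −6 confines the range to ~16% of cells at present — a
restricted-range profile under which the glacial offsets collapse the
range to under 1% and warming re-expands it. Presences (default 200) are
drawn without replacement proportional to truth × bias, with the bias
kernel centred in the east (sd 300 km), mimicking uneven collection
effort.

What the generator does **not** emulate: topography and elevational
gradients, dispersal limitation (truth is climate-equilibrium by
construction), non-climatic habitat constraints, GCM-style spatially
structured climate anomalies (offsets are spatially constant), and
observation error in coordinates. Passing tests therefore demonstrate
the statistical machinery recovers a known climate-only truth under
biased sampling — not that any real species satisfies the equilibrium
assumption.

## Numerical and testing conventions

Fit tolerance 1e-6 on the subgradient; background Gibbs probabilities
sum to 1 within 1e-8 after every fit. All randomness flows from explicit
integer seeds; the pipeline derives one stream per stage by hashing the
stage name with the master seed, so changing one stage's workload leaves
the others' draws untouched, and identical configs and seeds give
byte-identical manifests. Ratio and share rounding is half away from
zero at one decimal. Problem sizes in the test and acceptance runs —
120 × 120 cells, 200 presences, 5000 background cells, 10 replicates,
thinning oracles at n ≤ 12, AUC oracles at ≤ 200 points — were chosen so
the full suite exercises every stage end-to-end in well under a minute
of compute while keeping estimates stable across seeds.

The ground-truth recovery checks draw the background from the
*generating* bias kernel rather than the kernel estimated from the 200
occurrences: with the exact bias, background weighting cancels the
sampling bias identically and the measured quantity is the model's
recovery, not the kernel estimator's bandwidth luck. The pipeline
itself always uses the estimated kernel (all a field study has); its
AUC is accordingly lower and no recovery guarantee is claimed for it.
The imposed-shift recovery uses a multi-patch range (compact 25-km-radius
patches ≥ 150 km apart) translated 70 km north by whole cells, so
centroid discretization is identical before and after and nothing clips
at the domain edge; a half-plane-shaped range produced by thresholding a
logistic-linear truth would clip at the boundary and bias the centroid.

## Known limitations

Exact thinning is exponential in component size past the greedy
fallback threshold; the bias-kernel bandwidth convention is a choice,
not a standard; the logistic output's prevalence constant e^H inherits
the background sample; block vectors depend on the tile anchoring (the
raster origin) and on the matching direction; and the limiting-factor
attribution is a local substitution argument, not a causal decomposition.
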