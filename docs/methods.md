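# Methods

This note documents the models and procedures `sdmsens` implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about real-data behaviour.

## The analysis chain

The package studies one question: how sensitive are binary SDM projections
onto climatically novel regions to the identity of the bioclimatic
predictors, when the candidate predictors are strongly correlated in the
calibration data?  The chain is: prepare presence/pseudo-absence data →
fit an ensemble SDM per predictor set → project binaries onto island
rasters → summarise suitable fractions → relate them to climatic niche
overlap via log-response ratios → partition variance and fit a mixed model.

## Synthetic climate domains

Random fields are linear mixtures of spatially smoothed independent
Gaussian noise fields.  Each field is smoothed with a Gaussian kernel of
width `spatial_smoothness` (cells, wrap-around boundaries), then the set of
fields is empirically whitened (centred, decorrelated, unit-scaled) before
mixing with the symmetric square root of the target correlation matrix.
Consequence: the realised inter-variable correlation matrix, per-variable
means and standard deviations equal the configured targets *exactly* at any
grid size, not merely in expectation, while spatial autocorrelation is
retained.  The square root is taken by eigendecomposition so perfectly
correlated (singular PSD) targets are handled; matrices with an eigenvalue
below −10⁻⁸ are rejected with the offending eigenvalue named.

A projection domain reuses the calibration config with (a) selected pairs'
target correlation set to zero — after zeroing, the matrix is clipped to
PSD and its unit diagonal restored — and (b) additive per-variable offsets
(`range_shift`).  Decoupling realises |r| ≈ 0 exactly; variances are
preserved.  Domains are planar by default (coordinate units read as km);
geographic mode switches distance computations to great circles.

Virtual species are products (or minima) of Gaussian or logistic response
curves over climate variables; occurrence records are drawn cell-wise with
probability proportional to suitability × sampling-bias weight, with
replacement, and jittered uniformly within the cell.  `prevalence_target`
is carried as metadata only: the sampler normalises suitability × bias to a
probability mass, so a global rescale of suitability cannot change where
records land.  A configurable fraction of records is corrupted into the
classic archive error categories (pre-cutoff year, excessive coordinate
uncertainty, longitude = latitude, 0/0 neighbourhood, capital / centroid /
institution / headquarters proximity); the category is written to a
`provenance` column that the pipeline itself never reads — it exists so
tests can assert exact removal counts.

## Occurrence preparation

Cleaning filters run in a fixed order — basis-of-record (fossil/machine by
default), year < 1981, uncertainty > 1 km, equal lon/lat, within 0.5° of
0/0, within 10 km of a capital, 1 km of a country centroid, 100 m of a
biodiversity institution, 0.5° of the archive headquarters — and each
record is charged to the first filter that removes it, so audit counts sum
exactly to rows-in − rows-out.  Set membership of the output is
order-independent; only the per-filter attribution depends on the order.

Records are aggregated to one per species per grid cell (coordinates moved
to cell centres; minimum year and uncertainty kept so the result is
invariant to row order), then thinned to a minimum pairwise distance
(10 km default; 2 units in the scenario).  Thinning repeatedly deletes the
record with the most neighbours inside the radius, ties broken uniformly at
random, then re-adds any deleted record whose neighbours were themselves
all deleted (the greedy pass alone is not maximal), and keeps the best of
`reps` randomized runs.  On random instances of ≤ 12 points the retained
count matches an exhaustive-subset oracle.

Pseudo-absences are drawn at cell resolution, per draw as many as there are
thinned presences but at least 100, only in regions holding strictly more
than 10 presence records (grid quadrants stand in for continents on
synthetic domains), never from presence cells, without replacement, with
probability proportional to the bias weight.  Five draws by default.

## SDM battery and ensemble

Member models = algorithms × pseudo-absence draws × stratified 70/30
splits.  Defaults mirror a conventional ensemble-SDM configuration:

| knob | default | note |
|---|---|---|
| algorithms | glm, gam, rf, brt | glm: unpenalised logistic + quadratic terms; gam: cubic-spline logistic (5 knots); rf: 500 trees, min leaf 5; brt: 2500 trees, learning rate 0.01, depth 7 |
| splits | 3 × 70/30 | stratified by label |
| pseudo-absence draws | 5 | |
| committee cut | TSS > 0.5 (strict) | an empty committee is a *status*, not an exception |
| combination | unweighted mean of member probabilities | |
| n_perm (importance) | 10 | |

Each member is evaluated on its held-out 30% at its own maxTSS threshold;
the ensemble's binarisation threshold is the maxTSS cutoff of the mean
member scores over the pooled presence + pseudo-absence table.  The maxTSS
candidate set is the midpoints between consecutive distinct scores plus one
sentinel below and above all scores; ties break toward the lowest
threshold.  Whether member-level committee screening should use maxTSS or a
fixed 0.5 cutoff is not observable from the outside; maxTSS (the
ensemble-platform convention) is used.  Ensemble averaging is unweighted;
TSS-weighted averaging is a plausible alternative and is deliberately not
implemented to keep the committee rule single-parameter.

Variable importance: per member and variable, 1 − Pearson r between
predictions on intact data and on data with that variable's column
permuted, averaged over permutations, clipped at zero, then averaged over
committee members.  A constant-output member scores 0 for every variable.

A preflight check warns (never errors) when a predictor set contains a pair
with |r| ≥ 0.7 on the calibration data: strongly correlated pairs can be a
deliberate part of a sensitivity design.

## Projection and summaries

A cell is suitable iff the ensemble score is ≥ the binarisation threshold;
cells with any missing predictor are excluded from the denominator rather
than counted unsuitable.  An island is predicted occupied when ≥ 1 cell is
suitable.  Island-level confusion statistics treat the recorded species set
as truth and the modelled-species pool minus the recorded set as negatives;
an island with no recorded species has undefined sensitivity and is
reported as missing, not zero.  Archipelago grouping (several islands
pooled before summaries) is a config-level map; grouped fractions pool cell
counts, grouped climate ranges take the union of bounds.

## Overlap and log-response ratios

Per-variable overlap is the percentage of a species' (cleaned, snapped,
thinned — the same records the models saw) occurrence values lying
inclusively within the island's min–max range for that variable.
Cumulative overlap weights each variable's overlap by its ensemble
importance, normalised to sum to one, so Ω is a convex combination on the
0–100 scale (an all-zero importance vector falls back to equal weights).
The baseline model is the set with the highest unweighted mean Ω across
species × island pairs, ties broken by id order and logged.

`lrr(x₁, x₂) = ln((x₂ + c)/(x₁ + c))` with `c = 10⁻⁵` applied to both
proportions; the constant guards zero proportions and makes the measure
exactly antisymmetric.  One LRR pair (suitability, overlap) is produced per
species × island × non-baseline set; rows with a failed ensemble on either
side are dropped and counted.

## Variance partition and mixed model

The η² partition uses sequential (Type I) sums of squares in the fixed
order island_size, island, species, model, island×species, island×model,
species×model, residual, computed by incremental least squares on the
term's design-matrix block; η² = SSQ / total SSQ × 100 with the residual in
the denominator, so terms sum to exactly 100.  Island size (total cell
count) enters first as a continuous covariate.  Because island size is a
deterministic function of island identity, the design is intentionally
partially aliased; the island factor absorbs only the part of its span not
already covered — the behaviour of R's pivoting `lm()`/`anova()`.  A term
adding *no* estimable information at all raises an error naming it (with
≤ 2 islands the island factor is fully absorbed by intercept + size, which
is a genuinely degenerate design for this partition).

The mixed model regresses suitability LRR on overlap LRR with crossed
(unnested) random intercepts for island and species, estimated by REML
(implemented as variance components over a single all-rows group).
Singular (zero-variance) random effects are reported, never hidden.  An
exactly linear, noise-free input has no REML solution (zero scale); it is
detected via the OLS residual and returned through the OLS path with zero
random-effect standard deviations.  Parameter recovery at the full study
design (142 species × 8 islands × 6 comparisons; slope 1.458, island sd
0.9, species sd 1.3, residual sd 1.0) achieves mean absolute slope error
well under 0.1 with nominal interval coverage.

## The shipped non-analogue scenario

`make_nonanalogue_scenario` encodes the designed experiment: a calibration
domain (80 × 80 cells) with summer-like (BIO5) and winter-like (BIO6)
temperatures correlated at r = 0.9, an annual-mean-like blend of the two
(BIO1, correlated 0.97 with each), annual precipitation (BIO12) and
precipitation seasonality (BIO15); 20 virtual species with Gaussian niches
on BIO5 (optima within ±1 sd of the domain mean, breadths 0.2–0.4 sd) and
a broader secondary response on BIO12 (breadths 0.5–0.9 sd); an east-west
sampling-effort gradient; 300 target records per species with 10% dirty;
and three islands (20–30 cells square) where the temperature trio is
decoupled, BIO5 is shifted 6–8 sd below the calibration mean and BIO1 by
0.3× of that, while BIO6, BIO12 and BIO15 stay inside their calibrated
ranges.  Islands carry half the calibration's per-variable standard
deviation: a small island spans a much narrower climatic band than a
global calibration extent.  Three predictor sets differ only in
temperature identity — {BIO5, BIO12, BIO15}, {BIO1, BIO12, BIO15} and
{BIO6, BIO12, BIO15} — giving a strongly under-projecting, an
intermediate, and a strongly over-projecting model.

Three design ratios matter and were chosen to reflect the situation the
scenario emulates.  First, niche breadth must sit well below the background
climatic spread — species must be genuinely climate-limited — or presences
are statistically indistinguishable from background and no committee forms;
the chosen breadths put internal member TSS around 0.5–0.7, in line with a
well-performing presence/pseudo-absence analysis.  Second, the summer shift
must clear the *occupied* range of every species (optima ±1 sd, breadths
≤ 0.4 sd, island spread ±~2 sd of half-scale), which −6 sd and beyond
guarantees.  Third, the annual blend must shift by much less than summer —
mild winters pull it back — so that island BIO1 values stay within reach of
the cold-adapted species' optima; 0.3× of the summer shift produces the
intermediate projections that identify the overlap→suitability regression
(a blend shifted as far as the raw average of the two shifts would clear
every occupied range and collapse the gradation).  The battery is scaled to
the problem (GLM + 100-tree RF, 2 splits × 2 draws); the full
four-algorithm defaults remain available in `SDMConfig` for larger studies.

The scenario's "recorded island species" checklist — needed only for the
island-level confusion summaries — is a seeded random subset of the roster
standing in for an independent survey list (synthetic by construction: the
virtual truth makes the shifted islands genuinely unsuitable, as a real
checklist would not be derivable from the model inputs at all).

## What the synthetic tests do and do not show

They establish that every operation implements its definition (closed-form
and oracle checks), that the pipeline is deterministic under a single seed,
and that the designed non-analogue mechanism behaves as theory predicts:
the predictor set containing the range-exceeded limiting variable projects
far less suitable area than the set substituting its decoupled partner,
while internal evaluation barely separates the sets, and projected
suitability tracks climatic overlap with a positive mixed-model slope.
They do not establish anything about real occurrence archives (taxonomic
error, spatially structured effort beyond a smooth gradient, niche
truncation by dispersal limits), about raster resampling/projection
artefacts (synthetic domains share one geometry), or about the absolute
magnitudes a real-data analysis would produce.

## Problem sizes and numerical choices

The test suite runs one full scenario (20 species × 3 sets × 8 members,
~1.5 min), three reduced scenario seeds, and twenty mixed-model fits at the
142 × 8 × 6 design; the acceptance script repeats the scenario and the
recovery study for the seed it is given.  Tolerances: correlation control
is exact by construction (tested at 0.05 against sampling noise on derived
statistics); η² sums to 100 within 10⁻⁶; LRR identities hold to 10⁻¹²;
recovery uses the analytic-SE-scaled bound ±0.15 per fit.  Thresholding
uses ≥ (score equal to threshold is suitable) everywhere; maxTSS tie-breaks
go to the lowest candidate; baseline ties go to the first set id.
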