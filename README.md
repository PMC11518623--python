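# sdmsens

**Predictor-set sensitivity analysis for species distribution models
projected onto non-analogue climates.**

Species distribution models (SDMs) relate species occurrences to bioclimatic
predictors and are routinely projected onto regions or futures whose climate
was never part of the calibration data.  Such *non-analogue* conditions come
in two forms: individual variables exceed the calibrated value range, and the
correlation structure between variables changes — for instance, a place where
mild winters coincide with summers colder than anywhere the species occurs.
When two predictors are strongly correlated in the calibration data,
modellers usually keep one and drop the other; under non-analogue conditions
that seemingly harmless choice can flip a projection from "almost entirely
suitable" to "entirely unsuitable" without any warning from internal
evaluation statistics.

`sdmsens` implements the full analysis chain needed to quantify this
sensitivity, exercisable end to end on synthetic virtual-species data with
known truth:

1. **Synthetic data** (`sdmsens.synthetic`) — multi-variable climate domains
   with exactly controlled inter-variable correlation, projection domains
   with decoupled pairs and range-shifted variables, virtual species with
   known response curves, sampling-bias surfaces, and occurrence tables with
   injected dirty records.
2. **Occurrence preparation** (`sdmsens.occurrences`) — the archive-quality
   filter chain (year, coordinate uncertainty, equal lon/lat, 0/0 radius,
   capital/centroid/institution/headquarters radii), grid-cell aggregation,
   randomized minimum-distance thinning, and bias-weighted pseudo-absence
   draws restricted to regions with more than 10 presence records.
3. **SDM engine** (`sdmsens.sdm`) — a battery of logistic (GLM), spline
   (GAM), bagged-tree (RF) and boosted-tree (BRT) members per predictor set
   × pseudo-absence draw × 70/30 split, each evaluated by the true skill
   statistic `TSS = sensitivity + specificity − 1` at its maxTSS threshold;
   members with TSS > 0.5 form an unweighted-mean ensemble with its own
   maxTSS binarisation threshold and permutation variable importance
   (`VI = 1 − r(intact, permuted predictions)`).
4. **Island projection** (`sdmsens.projection`) — binary projection onto
   island rasters, suitable-cell fractions, the at-least-one-cell island
   presence rule, and island-level confusion statistics against an
   independent record set.
5. **Niche overlap** (`sdmsens.overlap`) — per-variable range-interval
   overlap (percentage of occurrence records inside the island's min–max
   range), importance-weighted cumulative overlap
   `Ω = Σ_v O_v · VI_v / Σ VI`, baseline selection (highest mean Ω), and
   log-response ratios `LRR = ln((X₂ + c)/(X₁ + c))`, `c = 10⁻⁵`.
6. **Variance partition** (`sdmsens.variance`) — sequential (Type I) ANOVA
   η² of projected suitable-cell counts over island size, island, species,
   model and their two-way interactions, and a REML linear mixed model of
   suitability LRR on overlap LRR with crossed island and species random
   intercepts.
7. **Workbench** (`sdmsens.workbench`) — one-seed orchestration of the whole
   chain, YAML-round-trippable configs, stage caching/resumption, and the
   shipped non-analogue scenario preset.

## Worked example

`examples/05_nonanalogue_scenario.py` runs a reduced (8-species) version of
the shipped scenario: a calibration domain with summer-like (BIO5) and
winter-like (BIO6) temperatures correlated at r = 0.9 and an annual-mean
blend (BIO1) correlated 0.97 with each, and three islands where the
temperature trio is decoupled, BIO5 is shifted 6–8 standard deviations
below the calibration mean and BIO1 by a third of that.  It prints:

```
modelled ensembles: 23 (failed: 1)

mean member TSS per predictor set (internal 70/30 evaluation):
predictor_set  mean_member_tss
   BIO1_12_15         0.619159
   BIO5_12_15         0.683615
   BIO6_12_15         0.498714

mean suitable fraction, BIO5_12_15: 0.000
mean suitable fraction, BIO6_12_15: 0.647
species where the summer set projects less: 100%

baseline (highest mean cumulative overlap): BIO6_12_15

variance partition of projected suitable-cell counts:
                term        ssq  df  eta_sq_percent
         island_size  104103.38   1            3.47
           C(island)       0.65   1            0.00
          C(species)  164285.26   7            5.47
            C(model) 2341807.26   2           77.99
C(island):C(species)   15764.86  14            0.53
  C(island):C(model)  265575.89   4            8.84
 C(species):C(model)   98228.96  13            3.27
            residual   12984.55  26            0.43

overlap->suitability mixed model: slope 7.897 (SE 1.746), island sd 0.00, species sd 2.12
```

Reading this: internal evaluation cannot distinguish the predictor sets
(mean member TSS 0.50–0.68), yet the set using the range-exceeded summer
variable projects **0%** of island cells suitable while the set substituting
its still-in-range winter partner projects **65%**; predictor-set identity
(`C(model)`, 78%) dwarfs island and species identity in the variance
partition; and projected suitability rises with climatic overlap (positive
mixed-model slope).  The other examples demonstrate each stage in isolation
(domain generation, record preparation, ensemble fitting, projection and
overlap).

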