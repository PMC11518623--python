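"""Run a reduced version of the shipped non-analogue scenario end to end.

Eight virtual species limited by a summer-like temperature are modelled
under three predictor sets and projected onto three islands where summers
are colder than anywhere in the calibration data while winters stay mild.
The run prints the per-set projections, the variance partition and the
overlap-suitability mixed model.
"""
import warnings

from sdmsens.workbench import (
    SCENARIO_SETS,
    make_nonanalogue_scenario,
    predictor_contrast,
    run_experiment,
)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    config = make_nonanalogue_scenario(seed=1, n_species=8)
    result = run_experiment(config)

print(f"modelled ensembles: {result.manifest['n_modelled']} "
      f"(failed: {result.manifest['n_failed_ensembles']})")
print("\nmean member TSS per predictor set (internal 70/30 evaluation):")
print(result.set_mean_tss.to_string(index=False))

summer, winter = SCENARIO_SETS["summer"], SCENARIO_SETS["winter"]
con = predictor_contrast(result.suitability, summer, winter).dropna()
print(f"\nmean suitable fraction, {summer}: {con['fraction_low'].mean():.3f}")
print(f"mean suitable fraction, {winter}: {con['fraction_high'].mean():.3f}")
print(f"species where the summer set projects less: "
      f"{100 * (con['diff'] > 0).mean():.0f}%")

print(f"\nbaseline (highest mean cumulative overlap): {result.baseline}")
print("\nvariance partition of projected suitable-cell counts:")
print(result.anova.round(2).to_string(index=False))

if result.lmm and "slope" in result.lmm:
    print(f"\noverlap->suitability mixed model: "
          f"slope {result.lmm['slope']:.3f} (SE {result.lmm['slope_se']:.3f}), "
          f"island sd {result.lmm['island_sd']:.2f}, "
          f"species sd {result.lmm['species_sd']:.2f}")
print("\nInternal evaluation barely separates the predictor sets, yet their")
print("island projections diverge strongly - the signature of non-analogue risk.")
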