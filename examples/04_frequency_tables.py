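"""Produce threshold-filtered frequency tables with cautionary flags.

Percentages are distinct users over the cohort denominator, rounded half-up
to one decimal; extract formulas are reported at >=0.4%, crude decoction
drugs at >=0.1%, and formulas containing ingredients to be used cautiously
in pregnancy (rhubarb, peach kernel, moutan bark, ...) are flagged.
"""
from kampo_claims import (
    IngredientMap,
    SimParams,
    StudyConfig,
    classify_bundle,
    dedup_count,
    describe_cohort,
    estimate_episodes,
    flag_cautionary,
    select_cohort,
    simulate_bundle,
    tabulate,
)

params = SimParams(n_mothers=500, seed=7)
bundle, _ = simulate_bundle(params)
config = StudyConfig()
episodes = estimate_episodes(bundle, config)
cohort, _ = select_cohort(bundle, episodes, config)
assignments, events = classify_bundle(bundle.drugs, episodes, cohort, config)

freq = tabulate(dedup_count(assignments, cohort), len(cohort), config)
print(f"formulas above reporting threshold (denominator {freq.denominator}):")
cols = ["formula_name", "total_n", "total_pct", "pre_pct", "pregnancy_pct",
        "post_pct"]
print(freq.filtered[cols].head(8).to_string(index=False))

annotated, cautionary = flag_cautionary(freq, IngredientMap())
print("\nformulas with cautionary ingredients (pregnancy window):")
print(cautionary.to_string(index=False))

desc = describe_cohort(episodes, cohort, bundle, events)
print(f"\nmean age at delivery: {desc['mean_age_years']:.1f} "
      f"(SD {desc['sd_age_years']:.1f}) years")
print(f"mean gestation:       {desc['mean_gestation_days']:.1f} "
      f"(SD {desc['sd_gestation_days']:.1f}) days")
print(f"post-term capped:     {desc['n_capped']} "
      f"({100 * desc['capped_fraction']:.1f}%)")
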