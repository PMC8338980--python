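"""Generate a synthetic screening cohort and summarize its rare outcomes.

The generator plants known effect sizes: acute suicidal ideation (SI) is
driven mainly by the depression trait, a strong lifetime-suicide-attempt
effect, a major-depressive-episode (MaDE) effect and a direct anhedonia-item
effect, at a calibrated 1% prevalence.
"""

from ginscreen import default_outcome_spec, default_trait_spec, generate_cohort, summarize_cohort

cohort = generate_cohort(default_trait_spec(), default_outcome_spec(), n=20000, seed=1)
summary = summarize_cohort(cohort.table)

print(f"subjects: {summary.n}")
for name, count in summary.counts.items():
    print(f"{name}: {count} ({summary.percentages[name]}%)")
print(f"subjects with a true MaDE label: {int(cohort.table.MaDE_label.notna().sum())}")

# Counts are calibrated: acute SI sits near 1% (about 200 of 20,000), with a
# lifetime-attempt rate near 1.4% and a ~1.1% labeled MaDE subset — the
# extreme imbalance regime the resampling ensemble is designed for.
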