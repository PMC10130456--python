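"""Median Z-score signatures and %COVID/%HC ratio classification.

Each analyte is standardized to Z-scores, the reference cut-off is the
median HC Z-score, and a subgroup's signature is the percentage of its
subjects strictly above the cut-off (>50% = increased). The COVID/HC
ratio of those percentages is binned: <=0.3x decreased, 0.4-2x unaltered,
>=3x increased.
"""

from mediatornet import (SubgroupKey, compute_zscores, covid_hc_ratio,
                         derive_cutoffs, generate_cohort, paperlike_config,
                         signature_proportions)

cohort = generate_cohort(paperlike_config(seed=1))
z = compute_zscores(cohort)                      # combined reference, raw pg/mL
cutoffs = derive_cutoffs(z, mode="global_HC")    # median HC Z-score per analyte

print("global HC cut-offs are negative under right skew, e.g.:")
for analyte in ("CXCL8", "IL-6", "FGF-basic"):
    print(f"  {analyte}: {cutoffs.values[analyte]:+.2f}")

p_hc = signature_proportions(z, cutoffs, SubgroupKey("HC", 3))
p_cv = signature_proportions(z, cutoffs, SubgroupKey("COVID", 3))
ratios = covid_hc_ratio(p_cv, p_hc)

print("\n3rd trimester signature and ratio (selected analytes):")
for analyte in ("FGF-basic", "IL-9", "TNF-α", "CCL5"):
    row = ratios.table.loc[analyte]
    print(f"  {analyte}: %HC={p_hc.table.loc[analyte, 'proportion_above']:.0f} "
          f"%COVID={p_cv.table.loc[analyte, 'proportion_above']:.0f} "
          f"-> {row['display_ratio']}x ({row['class']})")
# analytes with large planted fold changes show high ratios classed
# 'increased'; CCL5 (lower in COVID) trends decreased/unaltered
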