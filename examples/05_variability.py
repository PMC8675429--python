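"""Age-band inter-individual variability and the lnSD meta-analysis.

Residuals around the selected trajectory are summarized per age band as
ln(mean squared residual); bands are compared with a Brown-Forsythe omnibus
test at the Bonferroni-corrected alpha 0.05/16 = 0.003125.  A DerSimonian-
Laird meta-analysis of per-site ln(SD) gives the complementary site-weighted
picture.
"""

import lifespanvol as lv
from lifespanvol.pipeline import _residuals

cohort = lv.generate_cohort(lv.default_sim_config(scale=0.3, seed=2))
table, _ = lv.filter_complete(cohort)
table, _ = lv.adjust_icv(table)
table, _ = lv.harmonize_table(table)
ages, sexes = table["age"].to_numpy(), table["sex"].to_numpy()
corrected = lv.bonferroni_threshold(0.05, 16)
print(f"corrected alpha for the 16-structure family: {corrected} (printed as 0.003)\n")

for col in ("hippocampus_L", "putamen_L"):
    y = table[col].to_numpy()
    fit = lv.select_fp(y, ages, sexes, table["site_id"].to_numpy())
    report = lv.variance_report(_residuals(fit, y, ages, sexes), ages, col,
                                corrected_alpha=corrected)
    bands = ", ".join(f"{b.label}={b.stat:.2f}" for b in report.per_band)
    print(f"{col}: ln(mean e^2) by band [{bands}]")
    print(f"  omnibus p={report.omnibus_p:.2e} -> "
          f"{'significant' if report.significant else 'not significant'}")

meta = lv.variability_by_band_meta(table, "hippocampus_L")
print("\nhippocampus pooled lnSD by band (meta-analytic):")
for band, res in meta.items():
    print(f"  {band:7s} {res.pooled_effect:.3f} +- {res.pooled_se:.3f} (tau^2={res.tau2:.4f})")
# The hippocampus is generated with age-increasing noise, so its omnibus
# test is significant while the putamen's is not.  The site-weighted meta
# picture agrees at full cohort size; at this reduced scale its late band
# rests on few elderly sites and is accordingly uncertain (large tau^2/SE).
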