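"""Generate a synthetic two-group cohort and run the validation battery.

Builds a 96-subject cohort (50 healthy controls, 46 with type-2 diabetes)
whose index column is linked to the risk-score latent at a target Spearman
correlation of 0.70, then reproduces the clinical analysis structure:
group comparison, rank correlations, univariate regressions and ROC
against the high-risk labels.
"""

from ramdi import CohortSimSpec, cohort_report, render_report, synth_cohort

spec = CohortSimSpec(n_control=50, n_t2dm=46, link_strength=0.70, seed=7)
table, truth = synth_cohort(spec)
print(f"cohort: {len(table)} subjects; planted population Spearman rho = {truth['target_rho']}")

report = cohort_report(table, seed=7)
print(render_report(report))
# With the link planted at 0.70, every risk-score correlation lands near
# 0.70 (sampling error ~0.06 at n=96) and the ROC separates the high-risk
# label well above chance.
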