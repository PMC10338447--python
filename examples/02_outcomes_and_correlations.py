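"""Score the two outcomes and map their correlation structure.

General psychopathology is the first principal component of the z-scored
symptom-scale totals (all scales load positively after orientation, so a
higher score means more symptoms). Proneness to aggression is the 12-item
BPAQ sum with four subfactors. Pairwise Pearson correlations between the
aggression scores and the individual symptom scales are reported with
Benjamini-Hochberg FDR control across the whole grid.
"""

from aggnet import (
    SyntheticConfig,
    compute_bpaq,
    compute_general_psychopathology,
    correlate_with_fdr,
    generate_cohort,
)
from aggnet.outcomes import pearson_with_p
from aggnet.synthetic import SYMPTOM_SCALES

table, outcomes, _ = generate_cohort(SyntheticConfig(seed=1))
complete = outcomes.dropna()

gp = compute_general_psychopathology(complete[SYMPTOM_SCALES])
print(f"p-factor: PC1 explains {100 * gp.variance_explained:.1f}% of the variance")
print("loadings (all positive after orientation):")
print(gp.loadings.round(3).to_string())

bpaq_cols = [c for c in complete.columns if c.startswith("bpaq")]
aggr = compute_bpaq(complete[bpaq_cols])
r, p = pearson_with_p(gp.score.to_numpy(), aggr.total.to_numpy())
print(f"\np-factor vs aggression total: r = {r:.3f} (p = {p:.2e})")

report = correlate_with_fdr(aggr.as_frame(), complete[SYMPTOM_SCALES])
print("\nsubfactor x symptom-scale correlations (q < 0.05 marked *):")
for row in report.r.index:
    cells = [
        f"{report.r.loc[row, col]:+.2f}{'*' if report.significant.loc[row, col] else ' '}"
        for col in report.r.columns
    ]
    print(f"  {row:>10}: {' '.join(cells)}")
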