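"""Pre- vs post-treatment group comparisons between pCR and non-pCR.

Wilcoxon rank-sum on the continuous ctDNA and PET metrics at each
timepoint, Fisher's exact test on post-treatment ctDNA status, and the
sensitivity/specificity of each metric at its Youden-optimal cutoff
(orientation: higher value predicts residual disease).
"""

import numpy as np
import pandas as pd

from common import RESULTS, load_cohort
from ctpet.pipeline import build_feature_matrix, label_cohort, quantify_cohort
from ctpet.stats import (
    fisher_exact,
    sens_spec_at_cutoff,
    wilcoxon_rank_sum,
    youden_cutoff,
)

variants, samples, _ = load_cohort()
quant = quantify_cohort(variants, samples)
labels = label_cohort(samples)
fm = build_feature_matrix(samples, quant, labels)
fm = fm[fm.cohort == "discovery"]
non_pcr = 1 - fm["pcr"].to_numpy()

metrics = [
    "ctdna_concentration", "relative_abundance", "max_vaf",
    "suvmean", "suvmax", "mtv", "tlg", "suvtbr",
]
rows = []
for tp in ("pre", "post"):
    for metric in metrics:
        col = f"{metric}_{tp}"
        values = fm[col].to_numpy(float)
        ok = ~np.isnan(values)
        x = values[ok][non_pcr[ok] == 0]  # pCR
        y = values[ok][non_pcr[ok] == 1]
        _, p = wilcoxon_rank_sum(x, y)
        cut = youden_cutoff(values[ok], non_pcr[ok])
        sens, spec = sens_spec_at_cutoff(
            values[ok], non_pcr[ok], cut.cutoff
        )
        rows.append({
            "timepoint": tp, "metric": metric, "wilcoxon_p": p,
            "youden_cutoff": cut.cutoff, "sensitivity": sens,
            "specificity": spec,
        })
table = pd.DataFrame(rows)
out = RESULTS / "03_group_comparisons.tsv"
table.to_csv(out, sep="\t", index=False, float_format="%.4g")

status_post = fm["ctdna_status_post"].to_numpy(float)
counts = np.array([
    [int(((status_post == 1) & (non_pcr == 1)).sum()),
     int(((status_post == 1) & (non_pcr == 0)).sum())],
    [int(((status_post == 0) & (non_pcr == 1)).sum()),
     int(((status_post == 0) & (non_pcr == 0)).sum())],
])
p_fisher, odds = fisher_exact(counts)

print(f"wrote {out}")
print("post-treatment ctDNA status vs pCR (Fisher):",
      f"p={p_fisher:.2e}, odds ratio={odds:.3g}")
sig_post = table[(table.timepoint == "post") & (table.wilcoxon_p < 0.05)]
sig_pre = table[(table.timepoint == "pre") & (table.wilcoxon_p < 0.05)]
print(f"metrics separating pCR at p<0.05: pre-treatment "
      f"{len(sig_pre)}/{len(metrics)}, post-treatment "
      f"{len(sig_post)}/{len(metrics)}")
print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
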