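"""ctDNA quantification: positivity, burden metrics, clearance classes.

Applies the 0.25% VAF positivity rule, computes relative abundance
(max VAF x cfDNA ng/ml) and ctDNA concentration (mean VAF x cfDNA pg/ml /
3.3 pg per haploid genome), and classifies each patient's pre/post pair.
"""

import pandas as pd

from common import RESULTS, load_cohort
from ctpet.pipeline import quantify_cohort
from ctpet.quant import clearance_status, detection_rate, gene_prevalence

variants, samples, _ = load_cohort()
results = quantify_cohort(variants, samples)

rows = [
    {
        "sample_id": r.sample_id,
        "timepoint": r.timepoint,
        "ctdna_positive": int(r.ctdna_positive),
        "relative_abundance": r.relative_abundance,
        "ctdna_concentration": r.ctdna_concentration,
        "max_vaf": r.max_vaf,
        "n_positive_variants": r.n_positive_variants,
    }
    for r in results
]
out = RESULTS / "02_quant.tsv"
pd.DataFrame(rows).to_csv(out, sep="\t", index=False, na_rep="NA")

by = {(r.sample_id, r.timepoint): r for r in results}
clearance = pd.Series(
    [
        clearance_status(by[(s.sample_id, "pre")],
                         by[(s.sample_id, "post")]).status
        for s in samples
    ]
).value_counts()
clearance.rename_axis("status").to_frame("n").to_csv(
    RESULTS / "02_clearance.tsv", sep="\t"
)

pre = [r for r in results if r.timepoint == "pre"]
post = [r for r in results if r.timepoint == "post"]
print(f"wrote {out}")
print(f"ctDNA detection: pre {detection_rate(pre):.1f}%, "
      f"post {detection_rate(post):.1f}%")
print(f"TP53 carriage:   pre {gene_prevalence(pre, 'TP53'):.0f}%, "
      f"post {gene_prevalence(post, 'TP53'):.0f}%")
print("clearance classes:")
print(clearance.to_string())
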