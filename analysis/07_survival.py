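"""Survival stratification: DFS and OS by model risk group and by pCR.

Kaplan-Meier curves and log-rank tests using the risk groups from the
model step (04); unresected patients are excluded from DFS (no surgery
date origin) but retained for OS.
"""

import pandas as pd

from common import RESULTS, load_cohort
from ctpet.pipeline import km_curves_by_group, label_cohort, survival_report

variants, samples, _ = load_cohort()
labels = label_cohort(samples)

risk_path = RESULTS / "04_risk_groups.tsv"
if not risk_path.exists():
    raise SystemExit("run 04_build_model.py first (needs its risk groups)")
risk_df = pd.read_csv(risk_path, sep="\t")
risk = dict(zip(risk_df.sample_id, risk_df.risk_group))

report = survival_report(samples, risk, labels)
report.to_csv(RESULTS / "07_survival.tsv", sep="\t", index=False,
              float_format="%.4g")
print(report.to_string(index=False, float_format=lambda v: f"{v:.4g}"))

rows = []
for endpoint in ("dfs", "os"):
    for group, curve in km_curves_by_group(samples, risk, endpoint).items():
        for t, s, r in zip(curve.event_times, curve.survival, curve.at_risk):
            rows.append({
                "endpoint": endpoint.upper(), "group": group,
                "time_months": t, "survival": s, "at_risk": r,
            })
pd.DataFrame(rows).to_csv(RESULTS / "07_km_curves.tsv", sep="\t",
                          index=False, float_format="%.5g")
print(f"\nwrote KM curves to {RESULTS / '07_km_curves.tsv'}")
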