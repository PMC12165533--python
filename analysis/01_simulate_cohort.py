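"""Generate the synthetic discovery (n=68) and validation (n=55) cohorts.

The generator encodes the study conditions: pCR rate ~25%, pre-treatment
TP53 carriage 63%, ctDNA detection ~75% pre and ~31% post treatment,
complete ctDNA clearance in every pCR patient, response-conditional
post-treatment PET metrics, and risk-group-linked exponential survival.
Writes the cohort TSVs plus the PPI-network, treatment-annotation and
transcript fixtures under results/cohort/.
"""

import pandas as pd

from common import COHORT_DIR, ensure_cohort

paths = ensure_cohort()
truth = pd.read_csv(paths["truth"], sep="\t")

print(f"cohort files under {COHORT_DIR}:")
for name, p in paths.items():
    print(f"  {name:22s} {p.name}")
print()
for cohort, prefix in (("discovery", "P"), ("validation", "V")):
    sub = truth[truth.sample_id.str.startswith(prefix)]
    print(
        f"{cohort}: n={len(sub)}, pCR={sub.is_pcr.mean():.1%}, "
        f"TP53 pre-treatment carriage={sub.driver_pre.mean():.1%}, "
        f"post={sub.driver_post.mean():.1%}"
    )
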