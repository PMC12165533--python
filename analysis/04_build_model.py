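"""Build and evaluate the integrated ctDNA + PET pCR prediction model.

LASSO feature selection (10-fold CV deviance) and bidirectional stepwise
AIC pruning on the discovery cohort, maximum-likelihood logistic
integration, LOOCV ROC in discovery, external evaluation in validation,
and a comparison against the frozen published scorer
(-0.9858 x SUVmean - 0.0109 x ctDNA concentration, low risk <= -2.6616).
"""

import numpy as np
import pandas as pd

from common import RESULTS, load_cohort
from ctpet.model import (
    PUBLISHED_MODEL,
    classify_risk,
    fit_logistic,
    lasso_select,
    loocv_auc,
    stepwise_aic,
    tertile_stratify,
)
from ctpet.pipeline import (
    DEFAULT_CANDIDATE_FEATURES,
    build_feature_matrix,
    label_cohort,
    quantify_cohort,
)
from ctpet.stats import delong_paired_test, roc_auc

variants, samples, _ = load_cohort()
quant = quantify_cohort(variants, samples)
labels = label_cohort(samples)
fm = build_feature_matrix(samples, quant, labels)
discovery = fm[fm.cohort == "discovery"].reset_index(drop=True)
validation = fm[fm.cohort == "validation"].reset_index(drop=True)

# continuous candidates only: the binary status feature quasi-separates
# (every pCR patient clears) and would destabilize the logistic fit
candidates = [c for c in DEFAULT_CANDIDATE_FEATURES if c != "ctdna_status_post"]
selected = lasso_select(discovery, candidates, seed=1)
selected = stepwise_aic(discovery, selected if selected else candidates)
fit = fit_logistic(discovery, selected)
print(f"selected features: {selected}")
print("fitted coefficients:",
      {n: round(c, 4) for n, c in
       zip(fit.spec.feature_names, fit.spec.coefficients)})

loocv = loocv_auc(discovery, selected)
print(f"discovery LOOCV AUC {loocv.auc:.3f} "
      f"(95% CI {loocv.ci_low:.3f}-{loocv.ci_high:.3f})")

rows = [{
    "cohort": "discovery", "model": "fitted", "auc": loocv.auc,
    "ci_low": loocv.ci_low, "ci_high": loocv.ci_high, "n": len(discovery),
}]
val_scores = fit.spec.score(validation)
val_roc = roc_auc(-val_scores, 1 - validation["pcr"].to_numpy())
rows.append({
    "cohort": "validation", "model": "fitted", "auc": val_roc.auc,
    "ci_low": val_roc.ci_low, "ci_high": val_roc.ci_high,
    "n": len(validation),
})
print(f"validation AUC {val_roc.auc:.3f} "
      f"(95% CI {val_roc.ci_low:.3f}-{val_roc.ci_high:.3f})")

# frozen published scorer on both cohorts (no refitting)
for name, sub in (("discovery", discovery), ("validation", validation)):
    scores = PUBLISHED_MODEL.score(sub)
    roc = roc_auc(-scores, 1 - sub["pcr"].to_numpy())
    rows.append({
        "cohort": name, "model": "frozen_published", "auc": roc.auc,
        "ci_low": roc.ci_low, "ci_high": roc.ci_high, "n": len(sub),
    })

# does the integrated model beat its single-feature components?
for single in selected:
    roc_single = roc_auc(
        -discovery[single].to_numpy() * np.sign(
            dict(zip(fit.spec.feature_names, fit.spec.coefficients))[single]
        ),
        1 - discovery["pcr"].to_numpy(),
    )
    comparison = delong_paired_test(
        -fit.spec.score(discovery),
        -discovery[single].to_numpy(),
        1 - discovery["pcr"].to_numpy(),
    )
    print(f"integrated vs {single}: AUC {roc_single.auc:.3f}, "
          f"DeLong p={comparison.pvalue:.4f}")

pd.DataFrame(rows).to_csv(
    RESULTS / "04_model_auc.tsv", sep="\t", index=False, float_format="%.4f"
)

# tertile risk groups on the pooled score. Under the fitted (negative)
# coefficients a higher score means less residual disease, so the
# low-RISK group is the TOP tertile; the direction flag makes that
# explicit (the published rule's verbatim text has the opposite
# orientation — see the methods note on the sign convention)
pooled = pd.concat([discovery, validation], ignore_index=True)
strata = tertile_stratify(fit.spec.score(pooled), low_is_lowest=False)
risk = pd.DataFrame({
    "sample_id": pooled["sample_id"],
    "cohort": pooled["cohort"],
    "score": fit.spec.score(pooled),
    "risk_group": strata.groups,
})
risk.to_csv(RESULTS / "04_risk_groups.tsv", sep="\t", index=False,
            float_format="%.5g")
print(f"risk groups: {(strata.groups == 'low').sum()} low / "
      f"{(strata.groups == 'high').sum()} high "
      f"(tertile boundary {strata.boundary:.3f})")
# the printed rule applied verbatim: note its orientation (negative
# coefficients + "low iff score <= cutoff") labels high-burden patients
# low-risk; see the methods note on this sign convention
example = PUBLISHED_MODEL.score(
    {"suvmean_post": 3.0, "ctdna_concentration_post": 150.0}
)
print(f"printed-rule example: SUVmean 3.0, ctDNA 150 hGE/ml -> score "
      f"{example:.4f} -> {classify_risk(example)} risk")
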