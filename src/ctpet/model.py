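"""pCR prediction models: frozen published scorer and de-novo fitting.

The published integrated model is a two-term linear score over
post-treatment PET and ctDNA burden::

    score = -0.9858 * SUVmean - 0.0109 * ctDNA_concentration (hGE/ml)

with risk rule "low risk iff score <= -2.6616" (boundary inclusive), both
shipped verbatim as ``PUBLISHED_MODEL``. Note the orientation this implies:
because both coefficients are negative, a *larger* SUVmean or ctDNA burden
lowers the score and can only move a patient toward the low-risk side of
the printed rule. The rule is implemented exactly as printed;
``ModelSpec.low_risk_rule`` lets callers flip the direction explicitly.

De-novo model construction mirrors the published procedure: L1-penalized
logistic feature selection (10-fold cross-validated deviance over a
100-point penalty path), bidirectional stepwise pruning on logistic AIC,
maximum-likelihood logistic integration, and leave-one-out cross-validated
ROC evaluation. Risk groups come from the lowest tertile of the score.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .stats import DegenerateInputError, RocResult, roc_auc

logger = logging.getLogger(__name__)

#: coefficients and cutoff of the published integrated model
PUBLISHED_COEF_SUVMEAN = -0.9858
PUBLISHED_COEF_CTDNA = -0.0109
PUBLISHED_CUTOFF = -2.6616


class SeparationWarning(UserWarning):
    pass


@dataclass
class ModelSpec:
    """A linear score with a risk cutoff.

    ``low_risk_rule`` is "le" (low risk iff score <= cutoff) or "gt".
    """

    feature_names: tuple
    coefficients: tuple
    intercept: Optional[float]
    cutoff: float
    low_risk_rule: str = "le"
    separation: bool = False
    converged: bool = True

    def __post_init__(self):
        if len(self.feature_names) != len(self.coefficients):
            raise ValueError("one coefficient per feature required")
        if not math.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")
        if self.low_risk_rule not in ("le", "gt"):
            raise ValueError("low_risk_rule must be 'le' or 'gt'")

    def score(self, features: dict | pd.DataFrame | pd.Series):
        """Linear score; the intercept (if any) is excluded so scores stay
        comparable with the published cutoff convention."""
        if isinstance(features, pd.DataFrame):
            out = np.zeros(len(features))
            for name, c in zip(self.feature_names, self.coefficients):
                out = out + c * features[name].to_numpy(dtype=float)
            return out
        total = 0.0
        for name, c in zip(self.feature_names, self.coefficients):
            v = float(features[name])
            if math.isnan(v):
                return math.nan
            total += c * v
        return total

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        if self.intercept is None:
            raise ValueError("model has no intercept; probabilities undefined")
        lin = self.intercept + self.score(features)
        return 1.0 / (1.0 + np.exp(-lin))

    def to_text(self) -> str:
        lines = ["# linear risk score"]
        for name, c in zip(self.feature_names, self.coefficients):
            lines.append(f"coefficient\t{name}\t{c!r}")
        lines.append(f"intercept\t{'' if self.intercept is None else repr(self.intercept)}")
        lines.append(f"cutoff\t{self.cutoff!r}")
        lines.append(f"low_risk_rule\t{self.low_risk_rule}")
        return "\n".join(lines) + "\n"


PUBLISHED_MODEL = ModelSpec(
    feature_names=("suvmean_post", "ctdna_concentration_post"),
    coefficients=(PUBLISHED_COEF_SUVMEAN, PUBLISHED_COEF_CTDNA),
    intercept=None,
    cutoff=PUBLISHED_CUTOFF,
    low_risk_rule="le",
)


def published_score(suvmean: float, ctdna_concentration: float) -> float:
    """The frozen two-term score; missing inputs yield NaN, never zero."""
    if suvmean is None or ctdna_concentration is None:
        return math.nan
    if math.isnan(suvmean) or math.isnan(ctdna_concentration):
        return math.nan
    if not (math.isfinite(suvmean) and math.isfinite(ctdna_concentration)):
        raise ValueError("inputs must be finite")
    if suvmean < 0 or ctdna_concentration < 0:
        raise ValueError("SUVmean and ctDNA concentration are nonnegative")
    return (
        PUBLISHED_COEF_SUVMEAN * suvmean
        + PUBLISHED_COEF_CTDNA * ctdna_concentration
    )


def classify_risk(score: float, spec: ModelSpec = PUBLISHED_MODEL) -> str:
    """"low" or "high" under the spec's rule; the published rule is
    boundary-inclusive on the low side."""
    if math.isnan(score):
        raise ValueError("cannot classify a missing score")
    if spec.low_risk_rule == "le":
        return "low" if score <= spec.cutoff else "high"
    return "low" if score > spec.cutoff else "high"


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------


def _design(features: pd.DataFrame, columns: Sequence[str], outcome: str):
    X = features[list(columns)].to_numpy(dtype=float)
    y = features[outcome].to_numpy(dtype=int)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values; "
                         "apply the complete-case filter first")
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("outcome must contain both classes")
    return X, y


def lasso_select(
    features: pd.DataFrame,
    candidate_columns: Sequence[str],
    outcome: str = "pcr",
    seed: int = 0,
    n_folds: int = 10,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
) -> list[str]:
    """L1-penalized logistic feature selection.

    Columns are standardized internally; the penalty path runs 100
    log-spaced values down from the data-derived maximum (the smallest
    penalty that zeroes every coefficient), and the penalty minimizing
    k-fold cross-validated deviance is kept (no one-standard-error rule).
    Returns the original names of features with nonzero weight.
    """
    if len(candidate_columns) < 2:
        raise ValueError("need at least two candidate columns")
    keep = []
    for c in candidate_columns:
        if features[c].nunique() <= 1:
            logger.warning("dropping zero-variance column %r", c)
        else:
            keep.append(c)
    if not keep:
        return []
    X, y = _design(features, keep, outcome)
    Xs = StandardScaler().fit_transform(X)
    n = len(y)

    # glmnet-style lambda_max: smallest penalty with an all-zero solution
    resid = y - y.mean()
    lambda_max = np.abs(Xs.T @ resid).max() / n
    lambdas = np.geomspace(lambda_max, lambda_max * lambda_min_ratio, n_lambda)
    cs = 1.0 / (n * lambdas)  # sklearn's C parametrization

    cv = StratifiedKFold(n_splits=min(n_folds, int(np.bincount(y).min())),
                         shuffle=True, random_state=seed)
    deviance = np.zeros(len(cs))
    for train, test in cv.split(Xs, y):
        for k, c in enumerate(cs):
            clf = _l1_logit(c)
            clf.fit(Xs[train], y[train])
            p = np.clip(clf.predict_proba(Xs[test])[:, 1], 1e-12, 1 - 1e-12)
            deviance[k] += -2.0 * (
                y[test] * np.log(p) + (1 - y[test]) * np.log(1 - p)
            ).sum()
    best = int(np.argmin(deviance))
    clf = _l1_logit(cs[best])
    clf.fit(Xs, y)
    selected = [name for name, w in zip(keep, clf.coef_[0]) if w != 0.0]
    # the L1 optimum is non-unique under perfect collinearity; keep only
    # the first of any exactly collinear pair (deterministic tie-break)
    pruned: list[str] = []
    for name in selected:
        col = Xs[:, keep.index(name)]
        dup = any(
            abs(float(np.corrcoef(col, Xs[:, keep.index(prev)])[0, 1]))
            > 1 - 1e-12
            for prev in pruned
        )
        if dup:
            logger.warning("dropping %r: exactly collinear with an earlier "
                           "selected feature", name)
        else:
            pruned.append(name)
    return pruned


def _l1_logit(c: float) -> LogisticRegression:
    return LogisticRegression(
        l1_ratio=1.0, C=c, solver="liblinear", max_iter=1000,
    )


def _logit_fit(X: np.ndarray, y: np.ndarray):
    """Unpenalized ML logistic fit; returns (intercept, coefs, loglik)."""
    clf = LogisticRegression(C=np.inf, max_iter=2000, tol=1e-10)
    clf.fit(X, y)
    p = np.clip(clf.predict_proba(X)[:, 1], 1e-300, 1.0 - 1e-16)
    ll = float((y * np.log(p) + (1 - y) * np.log(1 - p)).sum())
    return float(clf.intercept_[0]), clf.coef_[0].copy(), ll


def _aic(features: pd.DataFrame, columns: Sequence[str], outcome: str) -> float:
    y = features[outcome].to_numpy(dtype=int)
    if not columns:
        p = y.mean()
        ll = float(
            (y * math.log(max(p, 1e-300))
             + (1 - y) * math.log(max(1 - p, 1e-300))).sum()
        )
        return 2.0 * 1 - 2.0 * ll
    X, y = _design(features, columns, outcome)
    _, _, ll = _logit_fit(X, y)
    return 2.0 * (len(columns) + 1) - 2.0 * ll


def stepwise_aic(
    features: pd.DataFrame,
    start: Sequence[str],
    outcome: str = "pcr",
    scope: Optional[Sequence[str]] = None,
    tol: float = 1e-9,
) -> list[str]:
    """Bidirectional stepwise logistic-AIC pruning.

    At each step every single drop (from the current set) and add (from
    ``scope``, defaulting to the start set) is scored by AIC; the best
    strictly-improving move is taken until none remains. Deterministic:
    candidate moves are evaluated in lexicographic order and ties keep the
    earlier move.
    """
    scope = sorted(set(scope if scope is not None else start))
    current = sorted(set(start))
    if not set(current) <= set(scope):
        raise ValueError("start must be a subset of the stepwise scope")
    if not scope:
        raise ValueError("empty start and empty candidate scope")
    best_aic = _aic(features, current, outcome)
    while True:
        moves = []
        for col in sorted(current):
            trial = [c for c in current if c != col]
            moves.append((("drop", col), trial))
        for col in scope:
            if col not in current:
                moves.append((("add", col), sorted(current + [col])))
        best_move = None
        for move, trial in moves:
            a = _aic(features, trial, outcome)
            if a < best_aic - tol and (best_move is None or a < best_move[0]):
                best_move = (a, move, trial)
        if best_move is None:
            return current
        best_aic, _, current = best_move


# ---------------------------------------------------------------------------
# logistic integration and evaluation
# ---------------------------------------------------------------------------


@dataclass
class LogisticFit:
    spec: ModelSpec
    log_likelihood: float
    n: int
    aic: float


def fit_logistic(
    features: pd.DataFrame,
    selected: Sequence[str],
    outcome: str = "pcr",
    cutoff: float = 0.0,
) -> LogisticFit:
    """Maximum-likelihood logistic fit on the selected columns.

    Quasi-complete separation is detected (all fitted probabilities within
    1e-6 of their labels) and flagged on the returned spec rather than left
    to diverge silently.
    """
    if not selected:
        raise ValueError("no features selected")
    X, y = _design(features, selected, outcome)
    intercept, coefs, ll = _logit_fit(X, y)
    p = 1.0 / (1.0 + np.exp(-(intercept + X @ coefs)))
    separation = bool(np.all(np.abs(p - y) < 1e-6))
    if separation:
        warnings.warn(
            "perfect separation detected; coefficients are unbounded",
            SeparationWarning, stacklevel=2,
        )
    spec = ModelSpec(
        feature_names=tuple(selected),
        coefficients=tuple(float(c) for c in coefs),
        intercept=intercept,
        cutoff=cutoff,
        low_risk_rule="le",
        separation=separation,
    )
    return LogisticFit(spec, ll, len(y), 2.0 * (len(selected) + 1) - 2.0 * ll)


def loocv_auc(
    features: pd.DataFrame,
    selected: Sequence[str],
    outcome: str = "pcr",
) -> RocResult:
    """Leave-one-out cross-validated ROC on pooled held-out scores.

    Only the logistic coefficients are refit per fold; the feature set is
    fixed (nested re-selection is the caller's concern). The pooled
    quantity is the intercept-free linear score (the package's score
    convention): per-fold intercepts are incomparable across folds and,
    under a null model, anticorrelate with the held-out label — pooling
    them biases the AUC pessimistically. Folds whose training outcome
    collapses to one class are skipped with a warning.
    """
    X, y = _design(features, selected, outcome)
    n = len(y)
    if n < 10:
        raise ValueError("LOOCV needs at least 10 patients")
    scores = np.full(n, np.nan)
    skipped = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            skipped += 1
            continue
        _, b, _ = _logit_fit(X[mask], y[mask])
        scores[i] = float(X[i] @ b)
    if skipped:
        warnings.warn(f"skipped {skipped} single-class LOOCV fold(s)",
                      stacklevel=2)
    ok = ~np.isnan(scores)
    return roc_auc(scores[ok], y[ok])


def resubstitution_auc(
    features: pd.DataFrame, selected: Sequence[str], outcome: str = "pcr"
) -> RocResult:
    X, y = _design(features, selected, outcome)
    b0, b, _ = _logit_fit(X, y)
    p = 1.0 / (1.0 + np.exp(-(b0 + X @ b)))
    return roc_auc(p, y)


# ---------------------------------------------------------------------------
# risk stratification
# ---------------------------------------------------------------------------


@dataclass
class TertileStrata:
    groups: np.ndarray  # "low"/"high" per patient
    boundary: float
    degenerate: bool = False


def tertile_stratify(scores, low_is_lowest: bool = True) -> TertileStrata:
    """Split at the empirical tertile of the score vector.

    The boundary is the ceil(n/3)-th order statistic of the scores (the
    low-risk group is the lowest tertile); ties at the boundary go to the
    boundary-inclusive (low) side. With ``low_is_lowest=False`` the top
    tertile is labeled low instead. All-equal scores collapse to a single
    group and are flagged degenerate.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 3:
        raise ValueError("tertile stratification needs n >= 3")
    if np.isnan(scores).any():
        raise ValueError("scores contain missing values")
    n = scores.size
    k = max(1, math.ceil(n / 3))
    srt = np.sort(scores)
    if srt[0] == srt[-1]:
        warnings.warn("all scores equal; stratification is degenerate",
                      stacklevel=2)
        return TertileStrata(
            np.full(n, "low" if low_is_lowest else "high", dtype=object),
            float(srt[0]), degenerate=True,
        )
    if low_is_lowest:
        boundary = float(srt[k - 1])
        groups = np.where(scores <= boundary, "low", "high")
    else:
        boundary = float(srt[n - k])
        groups = np.where(scores >= boundary, "low", "high")
    return TertileStrata(groups.astype(object), boundary)
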