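"""Statistical kernels used throughout the pipeline.

Implemented here rather than delegated so that every convention
(tie handling, two-sided definitions, CI scale) is explicit and pinned by
tests against independent oracles:

* ROC/AUC with DeLong variance and the paired DeLong test,
* Youden-index cutoff selection and sensitivity/specificity,
* Fisher's exact test (probability-ordering two-sided convention),
* Wilcoxon rank-sum (exact for small groups, tie-corrected normal otherwise),
* Kaplan–Meier product-limit estimation and the two-group log-rank test.

Only distribution functions (normal, chi-square, hypergeometric) come from
scipy; the statistics themselves are assembled here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

__all__ = [
    "RocResult",
    "SurvivalCurve",
    "DelongComparison",
    "roc_auc",
    "delong_paired_test",
    "youden_cutoff",
    "sens_spec_at_cutoff",
    "fisher_exact",
    "wilcoxon_rank_sum",
    "km_estimate",
    "logrank_test",
]


class DegenerateInputError(ValueError):
    """Raised when the requested statistic is undefined for the input."""


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong inference
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    """ROC curve with midrank AUC and DeLong variance.

    ``curve`` rows are (fpr, tpr, cutoff) with a ``+inf`` sentinel cutoff at
    (0, 0) and ``-inf`` at (1, 1); a score >= cutoff predicts the positive
    class.
    """

    auc: float
    variance: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    curve: np.ndarray  # shape (k, 3): fpr, tpr, cutoff

    @property
    def ci(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    uniq = set(np.unique(labels).tolist())
    if not uniq <= {0, 1, False, True}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(uniq)}")
    return labels.astype(bool)


def _placements(scores: np.ndarray, labels: np.ndarray):
    """Midrank placement values V10 (per positive) and V01 (per negative).

    V10[i] = fraction of negatives scored below positive i (+ half ties);
    its mean is the AUC, likewise 1 - mean(V01).
    """
    pos = scores[labels]
    neg = scores[~labels]
    # pairwise comparison; cohorts here are small enough for the dense form
    diff = pos[:, None] - neg[None, :]
    wins = (diff > 0).astype(float) + 0.5 * (diff == 0)
    v10 = wins.mean(axis=1)
    v01 = 1.0 - wins.mean(axis=0)
    return v10, v01


def roc_auc(scores, labels, ci_level: float = 0.95) -> RocResult:
    """Midrank AUC (ties count one half) with a DeLong normal CI.

    The CI is on the AUC scale, truncated to [0, 1]. Requires both classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("both classes must be present for a ROC")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")

    v10, v01 = _placements(scores, labels)
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if n_pos > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n_neg > 1 else 0.0
    var = s10 / n_pos + s01 / n_neg
    z = float(_sps.norm.ppf(0.5 + ci_level / 2.0))
    half = z * math.sqrt(max(var, 0.0))
    ci_low = max(0.0, auc - half)
    ci_high = min(1.0, auc + half)

    # ROC curve at every observed score plus sentinels
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(~sorted_labels)
    # collapse tied scores to a single operating point
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = tps[distinct] / n_pos
    fpr = fps[distinct] / n_neg
    cutoffs = sorted_scores[distinct]
    curve = np.column_stack(
        [np.r_[0.0, fpr], np.r_[0.0, tpr], np.r_[np.inf, cutoffs]]
    )
    return RocResult(auc, var, ci_low, ci_high, n_pos, n_neg, curve)


@dataclass
class DelongComparison:
    auc_a: float
    auc_b: float
    z: float
    pvalue: float
    evaluable: bool = True
    note: str = ""


def delong_paired_test(scores_a, scores_b, labels) -> DelongComparison:
    """DeLong test for two correlated AUCs measured on the same samples.

    Uses the covariance of midrank placement values. A zero-variance
    difference with unequal AUCs is reported as non-evaluable rather than
    forcing p = 0; identical score vectors give z = 0, p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = _check_binary(labels)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must share length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("both classes must be present")

    v10a, v01a = _placements(a, labels)
    v10b, v01b = _placements(b, labels)
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())

    def _cov(x, y):
        if len(x) < 2:
            return 0.0
        return float(np.cov(x, y, ddof=1)[0, 1])

    var_diff = (
        _cov(v10a, v10a) + _cov(v10b, v10b) - 2 * _cov(v10a, v10b)
    ) / n_pos + (
        _cov(v01a, v01a) + _cov(v01b, v01b) - 2 * _cov(v01a, v01b)
    ) / n_neg

    diff = auc_a - auc_b
    if var_diff <= 0:
        if diff == 0:
            return DelongComparison(auc_a, auc_b, 0.0, 1.0)
        return DelongComparison(
            auc_a, auc_b, math.nan, math.nan, evaluable=False,
            note="zero variance of AUC difference",
        )
    z = diff / math.sqrt(var_diff)
    p = float(2.0 * _sps.norm.sf(abs(z)))
    return DelongComparison(auc_a, auc_b, float(z), min(p, 1.0))


# ---------------------------------------------------------------------------
# Cutoffs and confusion metrics
# ---------------------------------------------------------------------------


def sens_spec_at_cutoff(scores, labels, cutoff: float, direction: str = "ge"):
    """Sensitivity and specificity at a cutoff.

    direction "ge": score >= cutoff predicts positive; "le": score <= cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if direction not in ("ge", "le"):
        raise ValueError("direction must be 'ge' or 'le'")
    if labels.sum() == 0 or (~labels).sum() == 0:
        raise DegenerateInputError("both classes must be present")
    pred = scores >= cutoff if direction == "ge" else scores <= cutoff
    sens = float(pred[labels].mean())
    spec = float((~pred[~labels]).mean())
    return sens, spec


@dataclass
class YoudenCutoff:
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    direction: str = "ge"


def youden_cutoff(scores, labels, direction: str = "ge") -> YoudenCutoff:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidate cutoffs are midpoints between consecutive distinct scores plus
    sentinels beyond the extremes, so the returned cutoff sits strictly
    between classes whenever they separate. Ties in J break toward higher
    specificity; remaining ties toward the more extreme cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if labels.sum() == 0 or (~labels).sum() == 0:
        raise DegenerateInputError("both classes must be present")
    uniq = np.unique(scores)
    if uniq.size == 1:
        mids = np.array([uniq[0]])
    else:
        mids = (uniq[:-1] + uniq[1:]) / 2.0
    span = max(uniq[-1] - uniq[0], 1.0)
    candidates = np.r_[uniq[0] - span, mids, uniq[-1] + span]
    best = None
    for c in candidates:
        sens, spec = sens_spec_at_cutoff(scores, labels, c, direction)
        j = sens + spec - 1.0
        key = (round(j, 12), round(spec, 12))
        if best is None or key > best[0]:
            best = (key, float(c), sens, spec, j)
    _, cut, sens, spec, j = best
    return YoudenCutoff(cut, sens, spec, j, direction)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    p sums hypergeometric probabilities of all tables (with the observed
    margins) that are no more probable than the observed one — the
    probability-ordering convention used by R's ``fisher.test``. Returns
    (p, sample odds ratio); the odds ratio is ``inf`` or ``nan`` for zero
    cells as appropriate.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t_int = t.astype(np.int64)
        if np.any(t_int != t) or np.any(t_int < 0):
            raise ValueError("table entries must be nonnegative integers")
        t = t_int
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0, odds

    rv = _sps.hypergeom(n, c1, r1)  # X = count in cell (0,0)
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    # relative tolerance guards float noise in the pmf ordering
    p = float(probs[probs <= p_obs * (1 + 1e-7)].sum())
    if p > 1.0 - 1e-12:  # accumulated pmf round-off
        p = 1.0
    return p, odds


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return _sps.rankdata(pooled, method="average")


def wilcoxon_rank_sum(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration of rank assignments when both groups have at most
    ``exact_max_n`` observations (valid under ties through midranks);
    otherwise the normal approximation with tie correction and a 0.5
    continuity correction. Returns (rank-sum W of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DegenerateInputError("both groups must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.r_[x, y]
    ranks = _midranks(pooled)
    w = float(ranks[:n1].sum())
    mean_w = n1 * (n1 + n2 + 1) / 2.0

    if n1 <= exact_max_n and n2 <= exact_max_n:
        dev = abs(w - mean_w)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            ws = ranks[list(idx)].sum()
            total += 1
            if abs(ws - mean_w) >= dev - 1e-9:
                count += 1
        return w, count / total

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return w, 1.0
    dev = abs(w - mean_w) - 0.5  # continuity correction
    z = max(dev, 0.0) / math.sqrt(var_w)
    return w, float(min(1.0, 2.0 * _sps.norm.sf(z)))


# ---------------------------------------------------------------------------
# Survival: Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------


@dataclass
class SurvivalCurve:
    """Product-limit estimate evaluated at each distinct event time."""

    event_times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def evaluate(self, t: float) -> float:
        """S(t) with right-continuous steps; S = 1 before the first event."""
        s = 1.0
        for et, sv in zip(self.event_times, self.survival):
            if et <= t:
                s = sv
            else:
                break
        return s


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    Censorings at an event time are counted at risk for that event (the
    standard convention: events precede censorings at tied times).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if np.any(times < 0):
        raise ValueError("survival times must be nonnegative")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("events must be 0/1")
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    at_risk = np.empty(event_times.size, dtype=int)
    n_events = np.empty(event_times.size, dtype=int)
    surv = np.empty(event_times.size, dtype=float)
    s = 1.0
    for k, t in enumerate(event_times):
        r = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        at_risk[k] = r
        n_events[k] = d
        s *= 1.0 - d / r
        surv[k] = s
    return SurvivalCurve(
        event_times, at_risk, n_events, surv,
        censor_times=np.sort(times[events == 0]),
    )


@dataclass
class LogrankResult:
    chi2: float
    pvalue: float
    observed: tuple[float, float]
    expected: tuple[float, float]
    evaluable: bool = True
    note: str = ""


def logrank_test(times, events, group) -> LogrankResult:
    """Two-group Mantel-Haenszel log-rank test (1 df chi-square).

    ``group`` is a binary indicator. Requires both groups present and at
    least one event; an all-tied degenerate table is flagged non-evaluable.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    group = _check_binary(group)
    if group.all() or (~group).all():
        raise DegenerateInputError("log-rank needs two groups")
    if events.sum() == 0:
        return LogrankResult(
            math.nan, math.nan, (0, 0), (0, 0), evaluable=False,
            note="no events",
        )
    event_times = np.unique(times[events == 1])
    o1 = e1 = v = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & group).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    o_total = float(events.sum())
    if v <= 0:
        return LogrankResult(
            math.nan, math.nan, (o1, o_total - o1), (e1, o_total - e1),
            evaluable=False, note="zero log-rank variance",
        )
    chi2 = (o1 - e1) ** 2 / v
    p = float(_sps.chi2.sf(chi2, df=1))
    return LogrankResult(
        float(chi2), p, (float(o1), float(o_total - o1)),
        (float(e1), float(o_total - e1)),
    )
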