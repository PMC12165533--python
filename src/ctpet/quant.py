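"""ctDNA quantification from panel variant calls.

Per-sample, per-timepoint metrics used by the prediction model:

* positivity — a gene mutation is positive when its VAF is at least 0.25%
  (copy-number and structural variants carry no VAF but still count toward
  gene- and sample-level positivity),
* relative ctDNA abundance — max VAF among positive mutations x cfDNA
  concentration in ng/ml (a unitless burden score),
* ctDNA concentration — mean VAF among positive mutations x cfDNA in pg/ml
  divided by 3.3 pg per haploid genome equivalent, giving hGE/ml,
* clearance classes from the pre/post positivity pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

VAF_POSITIVITY_THRESHOLD = 0.0025  # fraction: 0.25%
HAPLOID_GENOME_PG = 3.3
NG_TO_PG = 1000.0

TIMEPOINTS = ("pre", "post")
VARIANT_CLASSES = ("mutation", "CNV", "SV")
CLEARANCE_STATES = (
    "cleared",
    "persistent",
    "newly_detected",
    "consistently_negative",
)


class DataError(ValueError):
    """Raised for invalid or inconsistent input rows."""


@dataclass(frozen=True)
class VariantCall:
    """One somatic alteration observed in a plasma sample.

    ``vaf`` is a fraction in [0, 1], present iff ``vclass == "mutation"``.
    ``region`` optionally carries an exon/intron annotation such as "exon6".
    """

    sample_id: str
    timepoint: str
    gene: str
    chrom: str = "."
    pos: int = 1
    ref: str = "N"
    alt: str = "N"
    vclass: str = "mutation"
    vaf: Optional[float] = None
    region: Optional[str] = None

    def __post_init__(self):
        if self.timepoint not in TIMEPOINTS:
            raise DataError(f"timepoint must be one of {TIMEPOINTS}")
        if self.vclass not in VARIANT_CLASSES:
            raise DataError(f"vclass must be one of {VARIANT_CLASSES}")
        if self.pos < 1:
            raise DataError("pos must be a 1-based coordinate >= 1")
        if self.vclass == "mutation":
            if self.vaf is None or math.isnan(self.vaf):
                raise DataError("mutations must carry a VAF")
            if not 0.0 <= self.vaf <= 1.0:
                raise DataError(f"VAF {self.vaf} outside [0, 1]")
        elif self.vaf is not None and not math.isnan(self.vaf):
            raise DataError("CNV/SV rows must not carry a VAF")


@dataclass
class QuantResult:
    """Derived ctDNA metrics for one sample at one timepoint."""

    sample_id: str
    timepoint: str
    ctdna_positive: bool
    relative_abundance: float
    ctdna_concentration: float
    max_vaf: float
    n_positive_variants: int
    per_gene_status: dict[str, bool] = field(default_factory=dict)

    def gene_positive(self, gene: str) -> bool:
        return self.per_gene_status.get(gene, False)


@dataclass(frozen=True)
class ClearanceStatus:
    sample_id: str
    scope: str  # "sample" or a gene symbol
    status: str

    def __post_init__(self):
        if self.status not in CLEARANCE_STATES:
            raise DataError(f"unknown clearance status {self.status!r}")


def call_positivity(
    variants: Iterable[VariantCall],
    vaf_threshold: float = VAF_POSITIVITY_THRESHOLD,
) -> list[bool]:
    """Per-variant positivity: mutation VAF >= threshold (inclusive).

    CNV/SV rows are positive by presence — they are called events without a
    VAF, so the threshold does not apply to them.
    """
    if not 0.0 < vaf_threshold < 1.0:
        raise ValueError("vaf_threshold must lie in (0, 1)")
    out = []
    for v in variants:
        if v.vclass == "mutation":
            out.append(v.vaf >= vaf_threshold)
        else:
            out.append(True)
    return out


def _positive_mutation_vafs(
    variants: list[VariantCall],
    vaf_threshold: float,
    positive_only: bool,
) -> list[float]:
    vafs = [v.vaf for v in variants if v.vclass == "mutation"]
    if positive_only:
        vafs = [f for f in vafs if f >= vaf_threshold]
    return vafs


def relative_abundance(
    variants: Iterable[VariantCall],
    cfdna_ng_ml: float,
    vaf_threshold: float = VAF_POSITIVITY_THRESHOLD,
    positive_only: bool = True,
) -> float:
    """max VAF x cfDNA (ng/ml); 0 when no mutation passes the threshold.

    ``positive_only=False`` ranges the max over all called mutations
    irrespective of the threshold.
    """
    if cfdna_ng_ml is None or math.isnan(cfdna_ng_ml):
        return math.nan
    if cfdna_ng_ml < 0:
        raise DataError("cfDNA concentration must be nonnegative")
    vafs = _positive_mutation_vafs(list(variants), vaf_threshold, positive_only)
    if not vafs:
        return 0.0
    return max(vafs) * cfdna_ng_ml


def ctdna_concentration(
    variants: Iterable[VariantCall],
    cfdna_pg_ml: float,
    vaf_threshold: float = VAF_POSITIVITY_THRESHOLD,
    positive_only: bool = True,
) -> float:
    """mean VAF x cfDNA (pg/ml) / 3.3 pg, in haploid genome equivalents/ml."""
    if cfdna_pg_ml is None or math.isnan(cfdna_pg_ml):
        return math.nan
    if cfdna_pg_ml < 0:
        raise DataError("cfDNA concentration must be nonnegative")
    vafs = _positive_mutation_vafs(list(variants), vaf_threshold, positive_only)
    if not vafs:
        return 0.0
    mean_vaf = sum(vafs) / len(vafs)
    return mean_vaf * cfdna_pg_ml / HAPLOID_GENOME_PG


def sample_status(
    variants: Iterable[VariantCall],
    cfdna_ng_ml: float = math.nan,
    vaf_threshold: float = VAF_POSITIVITY_THRESHOLD,
    positive_only: bool = True,
    sample_id: Optional[str] = None,
    timepoint: Optional[str] = None,
) -> QuantResult:
    """Aggregate one sample/timepoint's variants into a QuantResult.

    All variants must share one (sample_id, timepoint); for an empty variant
    list the identifiers must be supplied explicitly and the sample is
    ctDNA-negative with zero metrics.
    """
    variants = list(variants)
    ids = {(v.sample_id, v.timepoint) for v in variants}
    if len(ids) > 1:
        raise DataError(f"mixed sample/timepoint in one aggregate: {sorted(ids)}")
    if variants:
        vid, vtp = next(iter(ids))
        if sample_id is not None and sample_id != vid:
            raise DataError("sample_id does not match the variant rows")
        sample_id, timepoint = vid, vtp
    elif sample_id is None or timepoint is None:
        raise DataError("empty variant list needs explicit sample_id/timepoint")

    flags = call_positivity(variants, vaf_threshold)
    positive = [v for v, f in zip(variants, flags) if f]
    per_gene: dict[str, bool] = {}
    for v in positive:
        per_gene[v.gene] = True
    for v in variants:
        per_gene.setdefault(v.gene, False)
    pos_vafs = [v.vaf for v in positive if v.vclass == "mutation"]
    return QuantResult(
        sample_id=sample_id,
        timepoint=timepoint,
        ctdna_positive=len(positive) > 0,
        relative_abundance=relative_abundance(
            variants, cfdna_ng_ml, vaf_threshold, positive_only
        ),
        ctdna_concentration=ctdna_concentration(
            variants,
            cfdna_ng_ml * NG_TO_PG if not math.isnan(cfdna_ng_ml) else math.nan,
            vaf_threshold,
            positive_only,
        ),
        max_vaf=max(pos_vafs) if pos_vafs else 0.0,
        n_positive_variants=len(positive),
        per_gene_status=per_gene,
    )


def clearance_status(
    pre: QuantResult,
    post: QuantResult,
    scope: str = "sample",
) -> ClearanceStatus:
    """Classify the pre/post positivity pair.

    (pos, neg) -> cleared; (pos, pos) -> persistent; (neg, pos) ->
    newly_detected; (neg, neg) -> consistently_negative. ``scope`` is
    "sample" for whole-sample ctDNA status or a gene symbol.
    """
    if pre.sample_id != post.sample_id:
        raise DataError("pre/post sample ids differ")
    if scope == "sample":
        p0, p1 = pre.ctdna_positive, post.ctdna_positive
    else:
        p0, p1 = pre.gene_positive(scope), post.gene_positive(scope)
    status = {
        (True, False): "cleared",
        (True, True): "persistent",
        (False, True): "newly_detected",
        (False, False): "consistently_negative",
    }[(p0, p1)]
    return ClearanceStatus(pre.sample_id, scope, status)


def delta_metric(pre_value: float, post_value: float) -> float:
    """Signed change post - pre; missing inputs propagate as NaN."""
    if pre_value is None or post_value is None:
        return math.nan
    if math.isnan(pre_value) or math.isnan(post_value):
        return math.nan
    return post_value - pre_value


def detection_rate(results: Iterable[QuantResult]) -> float:
    """Percent of samples that are ctDNA-positive (0-100 scale)."""
    results = list(results)
    if not results:
        raise DataError("no samples")
    return 100.0 * sum(r.ctdna_positive for r in results) / len(results)


def gene_prevalence(results: Iterable[QuantResult], gene: str) -> float:
    """Percent of samples with a positive alteration in ``gene``."""
    results = list(results)
    if not results:
        raise DataError("no samples")
    return 100.0 * sum(r.gene_positive(gene) for r in results) / len(results)
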