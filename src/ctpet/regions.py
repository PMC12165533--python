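"""Exon/intron region classification and exon-level pCR predictors.

A transcript model lists a gene's exons as 1-based inclusive genomic
intervals numbered in transcript order (strand-aware: on the minus strand
exon 1 has the highest coordinates). A variant position maps to exactly one
of exonK, intronK (the gap following exon K in transcript order) or
"outside". Exon mutation counts (distinct positive loci within an exon
subset) feed predictors such as the TP53 exon 5-7 score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .quant import DataError, VariantCall, call_positivity
from .stats import roc_auc

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TranscriptModel:
    gene: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # (start, end), transcript order

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ConfigError("strand must be '+' or '-'")
        if not self.exons:
            raise ConfigError("transcript needs at least one exon")
        ivs = sorted((s, e) for s, e in self.exons)
        for (s, e) in ivs:
            if e < s or s < 1:
                raise ConfigError(f"malformed exon interval ({s}, {e})")
        for (_, e0), (s1, _) in zip(ivs, ivs[1:]):
            if s1 <= e0:
                raise ConfigError("exons overlap")
        genomic = [s for s, _ in self.exons]
        expected = sorted(genomic, reverse=self.strand == "-")
        if genomic != expected:
            raise ConfigError(
                "exon order inconsistent with strand (exon 1 must be the "
                "5' end in transcript orientation)"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)


def classify_region(variant: VariantCall, model: TranscriptModel) -> str:
    """Region label for a variant: "exonK", "intronK" or "outside".

    Exon bounds are inclusive on both ends; variants spanning a boundary
    (indels) are assigned by their start coordinate.
    """
    if variant.gene != model.gene:
        raise DataError(
            f"variant gene {variant.gene} does not match model {model.gene}"
        )
    pos = variant.pos
    lo, hi = model.span
    if pos < lo or pos > hi:
        return "outside"
    for k, (s, e) in enumerate(model.exons, start=1):
        if s <= pos <= e:
            return f"exon{k}"
    # strictly between exon k and exon k+1 in transcript order
    for k in range(1, model.n_exons):
        a = model.exons[k - 1]
        b = model.exons[k]
        gap_lo = min(a[1], b[1]) + 1
        gap_hi = max(a[0], b[0]) - 1
        if gap_lo <= pos <= gap_hi:
            return f"intron{k}"
    return "outside"


def region_labels(model: TranscriptModel) -> list[str]:
    """All region labels of a transcript, exons interleaved with introns."""
    out = []
    for k in range(1, model.n_exons + 1):
        out.append(f"exon{k}")
        if k < model.n_exons:
            out.append(f"intron{k}")
    return out


def exon_mutation_count(
    variants: Iterable[VariantCall],
    model: TranscriptModel,
    exon_subset: Sequence[int],
    vaf_threshold: float = 0.0025,
) -> int:
    """Distinct positive mutations (by locus+alt) within an exon subset.

    Counts only mutation-class variants of the model's gene for one sample;
    duplicate calls at the same (chrom, pos, alt) count once.
    """
    subset = set(exon_subset)
    if not subset:
        raise ValueError("exon subset must be nonempty")
    labels = {f"exon{k}" for k in subset}
    variants = [
        v for v in variants if v.gene == model.gene and v.vclass == "mutation"
    ]
    flags = call_positivity(variants, vaf_threshold)
    loci = set()
    for v, pos_flag in zip(variants, flags):
        if pos_flag and classify_region(v, model) in labels:
            loci.add((v.chrom, v.pos, v.alt))
    return len(loci)


def region_frequency_table(
    variants: Iterable[VariantCall],
    model: TranscriptModel,
    pcr_status: dict[str, bool],
    vaf_threshold: float = 0.0025,
) -> pd.DataFrame:
    """Per-region mutated-patient frequency and pCR-discrimination AUC.

    AUC orientation follows the module convention: mutation predicts
    non-pCR, so the positive label is non-pCR and informative regions score
    above 0.5. Regions with a constant status vector are flagged degenerate
    with AUC 0.5.
    """
    patients = sorted(pcr_status)
    if not patients:
        raise DataError("pcr_status is empty")
    non_pcr = [0 if pcr_status[p] else 1 for p in patients]
    if len(set(non_pcr)) < 2:
        raise DataError("both pCR and non-pCR patients are required")

    per_region_status = {
        label: {p: 0 for p in patients} for label in region_labels(model)
    }
    gene_variants = [
        v for v in variants if v.gene == model.gene and v.vclass == "mutation"
    ]
    flags = call_positivity(gene_variants, vaf_threshold)
    for v, pos_flag in zip(gene_variants, flags):
        if not pos_flag or v.sample_id not in per_region_status["exon1"]:
            continue
        label = classify_region(v, model)
        if label != "outside":
            per_region_status[label][v.sample_id] = 1

    rows = []
    for label in region_labels(model):
        status = [per_region_status[label][p] for p in patients]
        n_mut = sum(status)
        degenerate = len(set(status)) < 2
        if degenerate:
            auc = 0.5
        else:
            auc = roc_auc(status, non_pcr).auc
        rows.append(
            {
                "gene": model.gene,
                "region": label,
                "n_mutated": n_mut,
                "frequency": n_mut / len(patients),
                "auc": auc,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
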