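"""Canonical tab-separated interchange formats.

The pipeline consumes post-called, panel-level summaries, so plain TSV with
documented headers is the primary interchange (a minimal VCF reader is
provided for convenience). Coordinates are 1-based inclusive throughout.
Missing values are written as ``NA``; floats are written with ``repr`` so a
write -> read -> write cycle is byte-identical.

Files:

* variants TSV  — one alteration per row (see ``VARIANT_COLUMNS``),
* samples TSV   — one patient per row: cfDNA, PET metrics, pathology,
  surgery flag and survival endpoints (``SAMPLE_COLUMNS``),
* truth TSV     — simulator ground truth,
* PPI edge list — two tab-separated gene columns,
* treatment annotation — (gene, paradigm) rows,
* transcript model — (gene, strand, exon_number, start, end) rows.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .imaging import PetMetrics
from .quant import DataError, VariantCall
from .regions import TranscriptModel

NA = "NA"

VARIANT_COLUMNS = [
    "sample_id", "timepoint", "gene", "chrom", "pos", "ref", "alt",
    "vclass", "vaf", "region",
]

SAMPLE_COLUMNS = [
    "sample_id", "cohort",
    "cfdna_pre", "cfdna_post",
    "suvmax_pre", "suvmean_pre", "mtv_pre", "tlg_pre", "bloodpool_suvmax_pre",
    "suvmax_post", "suvmean_post", "mtv_post", "tlg_post",
    "bloodpool_suvmax_post",
    "viable_area", "regression_area", "necrosis_area",
    "lymph_node_metastasis", "response_label", "surgery_performed",
    "dfs_months", "dfs_event", "os_months", "os_event",
]


class SchemaError(ValueError):
    pass


@dataclass
class SampleRecord:
    """Per-patient clinical and assay record."""

    sample_id: str
    cohort: str = "discovery"
    cfdna_pre: float = math.nan
    cfdna_post: float = math.nan
    suvmax_pre: float = math.nan
    suvmean_pre: float = math.nan
    mtv_pre: float = math.nan
    tlg_pre: float = math.nan
    bloodpool_suvmax_pre: float = math.nan
    suvmax_post: float = math.nan
    suvmean_post: float = math.nan
    mtv_post: float = math.nan
    tlg_post: float = math.nan
    bloodpool_suvmax_post: float = math.nan
    viable_area: float = math.nan
    regression_area: float = math.nan
    necrosis_area: float = math.nan
    lymph_node_metastasis: bool = False
    response_label: Optional[str] = None
    surgery_performed: bool = True
    dfs_months: float = math.nan
    dfs_event: int = 0
    os_months: float = math.nan
    os_event: int = 0

    def __post_init__(self):
        for name in ("dfs_months", "os_months"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise DataError(f"{name} must be nonnegative")
        for name in ("dfs_event", "os_event"):
            if getattr(self, name) not in (0, 1):
                raise DataError(f"{name} must be 0/1")

    def pet_metrics(self, timepoint: str) -> PetMetrics:
        return PetMetrics(
            sample_id=self.sample_id,
            timepoint=timepoint,
            suvmax=getattr(self, f"suvmax_{timepoint}"),
            suvmean=getattr(self, f"suvmean_{timepoint}"),
            mtv=getattr(self, f"mtv_{timepoint}"),
            tlg=getattr(self, f"tlg_{timepoint}"),
            bloodpool_suvmax=getattr(self, f"bloodpool_suvmax_{timepoint}"),
        )


# ---------------------------------------------------------------------------
# low-level cell formatting
# ---------------------------------------------------------------------------


def _fmt(value) -> str:
    if value is None:
        return NA
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        if math.isnan(value):
            return NA
        return repr(value)
    return str(value)


def _parse_float(cell: str, column: str, line: int) -> float:
    if cell == NA or cell == "":
        return math.nan
    try:
        return float(cell)
    except ValueError:
        raise SchemaError(f"line {line}: column {column!r}: not a number: {cell!r}")


def _parse_bool(cell: str, column: str, line: int) -> bool:
    if cell in ("1", "True", "true"):
        return True
    if cell in ("0", "False", "false", NA, ""):
        return False
    raise SchemaError(f"line {line}: column {column!r}: not a boolean: {cell!r}")


def _open_reader(path):
    fh = open(path, newline="")
    reader = csv.reader(fh, delimiter="\t")
    return fh, reader


def _check_header(header, required, path):
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


# ---------------------------------------------------------------------------
# variants TSV
# ---------------------------------------------------------------------------


def write_variants_tsv(variants: Iterable[VariantCall], path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(VARIANT_COLUMNS)
        for v in variants:
            w.writerow([
                v.sample_id, v.timepoint, v.gene, v.chrom, v.pos, v.ref,
                v.alt, v.vclass, _fmt(v.vaf), v.region or NA,
            ])


def read_variants_tsv(path) -> list[VariantCall]:
    """Parse the canonical variants TSV; all row errors reported together."""
    path = Path(path)
    fh, reader = _open_reader(path)
    with fh:
        header = next(reader, None)
        if header is None:
            raise SchemaError(f"{path}: empty file, header expected")
        _check_header(header, VARIANT_COLUMNS, path)
        idx = {c: header.index(c) for c in VARIANT_COLUMNS}
        out: list[VariantCall] = []
        errors: list[str] = []
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                vaf = _parse_float(row[idx["vaf"]], "vaf", line_no)
                region = row[idx["region"]]
                out.append(VariantCall(
                    sample_id=row[idx["sample_id"]],
                    timepoint=row[idx["timepoint"]],
                    gene=row[idx["gene"]],
                    chrom=row[idx["chrom"]],
                    pos=int(row[idx["pos"]]),
                    ref=row[idx["ref"]],
                    alt=row[idx["alt"]],
                    vclass=row[idx["vclass"]],
                    vaf=None if math.isnan(vaf) else vaf,
                    region=None if region in (NA, "") else region,
                ))
            except (DataError, ValueError, IndexError) as exc:
                errors.append(f"line {line_no}: {exc}")
        if errors:
            raise SchemaError(f"{path}: {len(errors)} bad row(s):\n" + "\n".join(errors))
    return out


# ---------------------------------------------------------------------------
# samples TSV
# ---------------------------------------------------------------------------


def write_samples_tsv(samples: Iterable[SampleRecord], path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SAMPLE_COLUMNS)
        for s in samples:
            w.writerow([_fmt(getattr(s, c)) for c in SAMPLE_COLUMNS])


def read_samples_tsv(path) -> list[SampleRecord]:
    path = Path(path)
    fh, reader = _open_reader(path)
    with fh:
        header = next(reader, None)
        if header is None:
            raise SchemaError(f"{path}: empty file, header expected")
        _check_header(header, SAMPLE_COLUMNS, path)
        idx = {c: header.index(c) for c in SAMPLE_COLUMNS}
        out: list[SampleRecord] = []
        errors: list[str] = []
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                kwargs = {}
                for c in SAMPLE_COLUMNS:
                    cell = row[idx[c]]
                    if c in ("sample_id", "cohort"):
                        kwargs[c] = cell
                    elif c == "response_label":
                        kwargs[c] = None if cell in (NA, "") else cell
                    elif c in ("lymph_node_metastasis", "surgery_performed"):
                        kwargs[c] = _parse_bool(cell, c, line_no)
                    elif c in ("dfs_event", "os_event"):
                        kwargs[c] = int(cell) if cell not in (NA, "") else 0
                    else:
                        kwargs[c] = _parse_float(cell, c, line_no)
                out.append(SampleRecord(**kwargs))
            except (DataError, SchemaError, ValueError, IndexError) as exc:
                errors.append(f"line {line_no}: {exc}")
        if errors:
            raise SchemaError(f"{path}: {len(errors)} bad row(s):\n" + "\n".join(errors))
    return out


# ---------------------------------------------------------------------------
# auxiliary tables
# ---------------------------------------------------------------------------


def write_ppi_edges(edges: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for a, b in edges:
            w.writerow([a, b])


def read_ppi_edges(path) -> list[tuple[str, str]]:
    fh, reader = _open_reader(path)
    with fh:
        edges = []
        for line_no, row in enumerate(reader, start=1):
            if not row:
                continue
            if len(row) < 2:
                raise SchemaError(f"{path}: line {line_no}: expected two columns")
            edges.append((row[0], row[1]))
    return edges


def write_treatment_annotation(rows: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "paradigm"])
        for gene, paradigm in rows:
            w.writerow([gene, paradigm])


def read_treatment_annotation(path) -> list[tuple[str, str]]:
    fh, reader = _open_reader(path)
    with fh:
        header = next(reader, None)
        if header is None:
            raise SchemaError(f"{path}: empty file, header expected")
        _check_header(header, ["gene", "paradigm"], path)
        gi, pi = header.index("gene"), header.index("paradigm")
        return [(row[gi], row[pi]) for row in reader if row]


def write_transcript_model(model: TranscriptModel, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "strand", "exon_number", "start", "end"])
        for k, (s, e) in enumerate(model.exons, start=1):
            w.writerow([model.gene, model.strand, k, s, e])


def read_transcript_models(path) -> dict[str, TranscriptModel]:
    """Read one or more transcript models from a BED-like TSV."""
    fh, reader = _open_reader(path)
    with fh:
        header = next(reader, None)
        if header is None:
            raise SchemaError(f"{path}: empty file, header expected")
        required = ["gene", "strand", "exon_number", "start", "end"]
        _check_header(header, required, path)
        idx = {c: header.index(c) for c in required}
        acc: dict[str, dict] = {}
        for row in reader:
            if not row:
                continue
            gene = row[idx["gene"]]
            entry = acc.setdefault(gene, {"strand": row[idx["strand"]], "exons": {}})
            entry["exons"][int(row[idx["exon_number"]])] = (
                int(row[idx["start"]]), int(row[idx["end"]]),
            )
    models = {}
    for gene, entry in acc.items():
        numbers = sorted(entry["exons"])
        if numbers != list(range(1, len(numbers) + 1)):
            raise SchemaError(f"{path}: {gene}: exon numbers must be 1..K")
        models[gene] = TranscriptModel(
            gene=gene,
            strand=entry["strand"],
            exons=tuple(entry["exons"][k] for k in numbers),
        )
    return models


def read_vcf_variants(path, sample_id: str, timepoint: str) -> list[VariantCall]:
    """Minimal single-sample VCF reader; VAF from an AF-style INFO field."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            af = rec.info.get("AF")
            if af is None:
                af = rec.info.get("VAF")
            if isinstance(af, tuple):
                af = af[0]
            if af is None:
                raise SchemaError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks an AF/VAF INFO field"
                )
            gene = rec.info.get("GENE", ".")
            out.append(VariantCall(
                sample_id=sample_id,
                timepoint=timepoint,
                gene=str(gene),
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alts[0] if rec.alts else "N",
                vclass="mutation",
                vaf=float(af),
            ))
    return out
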