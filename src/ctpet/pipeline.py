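"""End-to-end orchestration of the analysis and the survival report.

``run_pipeline`` chains the stages: ctDNA quantification -> response
labeling -> feature matrix -> model (frozen published scorer or a freshly
fitted one) -> risk stratification -> module/hub-gene analysis -> exon
region analysis -> survival stratification, writing one TSV or text report
per stage plus a run manifest. Everything is deterministic given the
config and seed; validation-cohort rows never touch a fit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    SampleRecord,
    read_ppi_edges,
    read_samples_tsv,
    read_transcript_models,
    read_treatment_annotation,
    read_variants_tsv,
)
from .imaging import PetMetrics, metric_table
from .model import (
    PUBLISHED_MODEL,
    ModelSpec,
    classify_risk,
    fit_logistic,
    lasso_select,
    loocv_auc,
    stepwise_aic,
    tertile_stratify,
)
from .modules import (
    assign_treatment_modules,
    build_ppi_modules,
    gene_status_table,
    hub_genes,
    module_auc,
    module_report,
)
from .quant import (
    DataError,
    QuantResult,
    VariantCall,
    clearance_status,
    delta_metric,
    sample_status,
)
from .regions import region_frequency_table
from .response import (
    PathologySpecimen,
    ResponseLabel,
    label_specimen,
    label_unresected,
)
from .stats import DegenerateInputError, logrank_test, km_estimate, roc_auc

logger = logging.getLogger(__name__)

#: candidate predictors mirroring the published variable panel
DEFAULT_CANDIDATE_FEATURES = [
    "ctdna_status_post",
    "relative_abundance_post",
    "ctdna_concentration_post",
    "max_vaf_post",
    "suvmax_post",
    "suvmean_post",
    "mtv_post",
    "tlg_post",
    "suvtbr_post",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------


def quantify_cohort(
    variants: Sequence[VariantCall],
    samples: Sequence[SampleRecord],
    vaf_threshold: float = 0.0025,
    positive_only: bool = True,
) -> list[QuantResult]:
    """Per-sample, per-timepoint ctDNA metrics for the whole cohort."""
    by_key: dict[tuple[str, str], list[VariantCall]] = {}
    for v in variants:
        by_key.setdefault((v.sample_id, v.timepoint), []).append(v)
    out = []
    for s in samples:
        for tp in ("pre", "post"):
            cfdna = getattr(s, f"cfdna_{tp}")
            out.append(sample_status(
                by_key.get((s.sample_id, tp), []),
                cfdna_ng_ml=cfdna,
                vaf_threshold=vaf_threshold,
                positive_only=positive_only,
                sample_id=s.sample_id,
                timepoint=tp,
            ))
    return out


def label_cohort(samples: Sequence[SampleRecord]) -> list[ResponseLabel]:
    """Response labels: precomputed column, pathology scoring, or the
    unresected (non-pCR) convention, in that order of precedence."""
    labels = []
    for s in samples:
        if s.response_label is not None:
            labels.append(ResponseLabel(
                s.sample_id,
                math.nan,
                s.response_label,
                s.response_label == "pCR",
                unresected=not s.surgery_performed,
            ))
        elif not s.surgery_performed:
            labels.append(label_unresected(s.sample_id))
        else:
            labels.append(label_specimen(PathologySpecimen(
                s.sample_id, s.viable_area, s.regression_area,
                s.necrosis_area, s.lymph_node_metastasis,
            )))
    return labels


def build_feature_matrix(
    samples: Sequence[SampleRecord],
    quant_results: Sequence[QuantResult],
    labels: Sequence[ResponseLabel],
    include_deltas: bool = False,
) -> pd.DataFrame:
    """One row per patient with candidate predictors and the pCR outcome."""
    q = {(r.sample_id, r.timepoint): r for r in quant_results}
    lab = {l.sample_id: l for l in labels}
    rows = []
    for s in samples:
        row: dict = {"sample_id": s.sample_id, "cohort": s.cohort}
        for tp in ("pre", "post"):
            qr = q.get((s.sample_id, tp))
            row[f"ctdna_status_{tp}"] = (
                float(qr.ctdna_positive) if qr else math.nan
            )
            row[f"relative_abundance_{tp}"] = (
                qr.relative_abundance if qr else math.nan
            )
            row[f"ctdna_concentration_{tp}"] = (
                qr.ctdna_concentration if qr else math.nan
            )
            row[f"max_vaf_{tp}"] = qr.max_vaf if qr else math.nan
            pet = s.pet_metrics(tp)
            for m in ("suvmax", "suvmean", "mtv", "tlg"):
                row[f"{m}_{tp}"] = getattr(pet, m)
            row[f"suvtbr_{tp}"] = pet.suvtbr
        if include_deltas:
            for m in ("ctdna_concentration", "suvmax", "suvmean", "mtv",
                      "tlg", "suvtbr"):
                row[f"{m}_delta"] = delta_metric(
                    row[f"{m}_pre"], row[f"{m}_post"]
                )
        row["pcr"] = int(lab[s.sample_id].is_pcr)
        rows.append(row)
    return pd.DataFrame(rows)


def survival_report(
    samples: Sequence[SampleRecord],
    risk_groups: Mapping[str, str],
    labels: Sequence[ResponseLabel],
) -> pd.DataFrame:
    """Log-rank stratifications: DFS and OS, each by risk group and by pCR.

    Patients without surgery have no DFS origin and are excluded from the
    DFS analyses (with a logged count); they remain in OS. Strata that are
    single-group or event-free are reported non-evaluable rather than
    failing.
    """
    lab = {l.sample_id: l for l in labels}
    rows = []
    for endpoint in ("dfs", "os"):
        eligible = [
            s for s in samples
            if endpoint == "os" or s.surgery_performed
        ]
        excluded = len(samples) - len(eligible)
        if excluded and endpoint == "dfs":
            logger.info("excluded %d unresected patient(s) from DFS", excluded)
        times = np.array([getattr(s, f"{endpoint}_months") for s in eligible])
        events = np.array([getattr(s, f"{endpoint}_event") for s in eligible])
        strata = {
            "risk": np.array([
                1 if risk_groups.get(s.sample_id) == "high" else 0
                for s in eligible
            ]),
            "pcr": np.array([
                0 if lab[s.sample_id].is_pcr else 1 for s in eligible
            ]),
        }
        for by, group in strata.items():
            row = {
                "endpoint": endpoint.upper(),
                "stratified_by": by,
                "n": len(eligible),
                "n_events": int(events.sum()),
                "n_group1": int(group.sum()),
            }
            try:
                res = logrank_test(times, events, group)
                row.update(
                    chi2=res.chi2, pvalue=res.pvalue, evaluable=res.evaluable,
                    note=res.note,
                )
            except DegenerateInputError as exc:
                row.update(chi2=math.nan, pvalue=math.nan, evaluable=False,
                           note=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)


def km_curves_by_group(
    samples: Sequence[SampleRecord],
    groups: Mapping[str, str],
    endpoint: str = "dfs",
) -> dict:
    """Kaplan-Meier curves per group label for one endpoint."""
    out = {}
    for g in sorted(set(groups.values())):
        members = [
            s for s in samples
            if groups.get(s.sample_id) == g
            and (endpoint == "os" or s.surgery_performed)
        ]
        if not members:
            continue
        times = [getattr(s, f"{endpoint}_months") for s in members]
        events = [getattr(s, f"{endpoint}_event") for s in members]
        out[g] = km_estimate(times, events)
    return out


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    input_digests: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        payload = {
            "package_version": self.version,
            "seed": self.seed,
            "config": self.config,
            "input_digests": self.input_digests,
            "stage_row_counts": self.stage_counts,
        }
        path.write_text(yaml.safe_dump(payload, sort_keys=True))


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the full analysis described by ``config``.

    Config keys: ``variants`` and ``samples`` (canonical TSV paths);
    optional ``ppi_edges``, ``treatment_annotation``, ``transcript_models``
    paths; ``seed``; ``vaf_threshold``; ``model`` with ``mode``
    ("frozen" | "fit") and optional ``candidate_features``. Returns a dict
    of result objects; writes per-stage tables plus ``manifest.yaml`` under
    ``outdir``. A second run with the same config and inputs is
    byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    vaf_threshold = float(config.get("vaf_threshold", 0.0025))
    model_cfg = dict(config.get("model", {"mode": "frozen"}))
    manifest = RunManifest(config=config, seed=seed)
    results: dict = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # annotate with the failing stage
                raise StageError(name, exc) from exc
        return deco

    @stage("read_inputs")
    def _inputs():
        for key in ("variants", "samples", "ppi_edges",
                    "treatment_annotation", "transcript_models", "panel"):
            if key in config:
                manifest.input_digests[key] = _digest(Path(config[key]))
        variants = read_variants_tsv(config["variants"])
        samples = read_samples_tsv(config["samples"])
        results["variants"], results["samples"] = variants, samples
        manifest.stage_counts["variants"] = len(variants)
        manifest.stage_counts["samples"] = len(samples)

    samples = results["samples"]
    variants = results["variants"]

    @stage("quantify")
    def _quantify():
        qr = quantify_cohort(variants, samples, vaf_threshold)
        results["quant"] = qr
        manifest.stage_counts["quant"] = len(qr)
        df = pd.DataFrame([
            {
                "sample_id": r.sample_id, "timepoint": r.timepoint,
                "ctdna_positive": int(r.ctdna_positive),
                "relative_abundance": r.relative_abundance,
                "ctdna_concentration": r.ctdna_concentration,
                "max_vaf": r.max_vaf,
                "n_positive_variants": r.n_positive_variants,
            }
            for r in qr
        ])
        _write_tsv(df, outdir / "quant.tsv")
        by = {(r.sample_id, r.timepoint): r for r in qr}
        clearance = pd.DataFrame([
            {
                "sample_id": s.sample_id,
                "status": clearance_status(
                    by[(s.sample_id, "pre")], by[(s.sample_id, "post")]
                ).status,
            }
            for s in samples
        ])
        _write_tsv(clearance, outdir / "clearance.tsv")

    @stage("label")
    def _label():
        labels = label_cohort(samples)
        results["labels"] = labels
        df = pd.DataFrame([
            {
                "sample_id": l.sample_id, "irrvt_percent": l.irrvt_percent,
                "category": l.category, "is_pcr": int(l.is_pcr),
                "unresected": int(l.unresected),
            }
            for l in labels
        ])
        _write_tsv(df, outdir / "labels.tsv")

    @stage("features")
    def _features():
        fm = build_feature_matrix(samples, results["quant"], results["labels"])
        results["features"] = fm
        manifest.stage_counts["features"] = len(fm)
        _write_tsv(fm, outdir / "features.tsv")
        _write_tsv(
            metric_table(
                [s.pet_metrics(tp) for s in samples for tp in ("pre", "post")]
            ),
            outdir / "pet_metrics.tsv",
        )

    @stage("model")
    def _model():
        fm_all: pd.DataFrame = results["features"]
        discovery = fm_all[fm_all["cohort"] == "discovery"]
        mode = model_cfg.get("mode", "frozen")
        if mode == "frozen":
            spec = PUBLISHED_MODEL
            results["selected"] = list(spec.feature_names)
        elif mode == "fit":
            candidates = [
                c for c in model_cfg.get(
                    "candidate_features", DEFAULT_CANDIDATE_FEATURES
                )
                if discovery[c].notna().all()
            ]
            fit_df = discovery
            selected = lasso_select(fit_df, candidates, seed=seed)
            if not selected:
                selected = candidates
            selected = stepwise_aic(fit_df, selected)
            fit = fit_logistic(fit_df, selected)
            strata_fit = tertile_stratify(fit.spec.score(fit_df))
            spec = ModelSpec(
                feature_names=fit.spec.feature_names,
                coefficients=fit.spec.coefficients,
                intercept=fit.spec.intercept,
                cutoff=strata_fit.boundary,
                low_risk_rule="le",
                separation=fit.spec.separation,
            )
            results["selected"] = selected
            results["loocv"] = loocv_auc(fit_df, selected)
        else:
            raise ValueError(f"unknown model mode {mode!r}")
        results["model_spec"] = spec
        (outdir / "model.txt").write_text(spec.to_text())

        complete = fm_all[[*spec.feature_names]].notna().all(axis=1)
        scored = fm_all[complete].copy()
        dropped = int((~complete).sum())
        if dropped:
            logger.info("dropped %d incomplete case(s) from scoring", dropped)
        scored["score"] = spec.score(scored)
        scored["risk_group"] = [
            classify_risk(s, spec) for s in scored["score"]
        ]
        results["scores"] = scored
        _write_tsv(
            scored[["sample_id", "cohort", "score", "risk_group"]],
            outdir / "risk_groups.tsv",
        )
        # per-cohort discrimination of the score (direction: lower score ...
        # is produced by higher tumor burden under the published signs)
        auc_rows = []
        for cohort, sub in scored.groupby("cohort"):
            if sub["pcr"].nunique() < 2:
                continue
            roc = roc_auc(-sub["score"].to_numpy(), 1 - sub["pcr"].to_numpy())
            auc_rows.append({
                "cohort": cohort, "n": len(sub), "auc": roc.auc,
                "ci_low": roc.ci_low, "ci_high": roc.ci_high,
            })
        results["score_auc"] = pd.DataFrame(auc_rows)
        _write_tsv(results["score_auc"], outdir / "score_auc.tsv")

    @stage("modules")
    def _modules():
        if "ppi_edges" not in config and "treatment_annotation" not in config:
            return
        pcr = {
            l.sample_id: l.is_pcr for l in results["labels"]
        }
        edges = (
            read_ppi_edges(config["ppi_edges"])
            if "ppi_edges" in config else []
        )
        annotation = (
            read_treatment_annotation(config["treatment_annotation"])
            if "treatment_annotation" in config else []
        )
        if "panel" in config:
            panel = sorted(
                line.strip()
                for line in Path(config["panel"]).read_text().splitlines()
                if line.strip()
            )
        else:  # permissive default: every gene any input refers to
            panel = sorted(
                {v.gene for v in variants}
                | {g for e in edges for g in e}
                | {g for g, _ in annotation}
            )
        status = gene_status_table(
            results["quant"], timepoint="post", panel=panel
        )
        mods = []
        if edges:
            mods.extend(build_ppi_modules(edges, panel, seed=seed))
        if annotation:
            mods.extend(assign_treatment_modules(annotation))
        mods = [module_auc(m, status, pcr) for m in mods]
        results["modules"] = mods
        results["hub_genes"] = hub_genes(mods)
        report = module_report(mods)
        _write_tsv(report, outdir / "modules.tsv")
        (outdir / "hub_genes.txt").write_text(
            "\n".join(sorted(results["hub_genes"])) + "\n"
        )

    @stage("regions")
    def _regions():
        if "transcript_models" not in config:
            return
        models = read_transcript_models(config["transcript_models"])
        pcr = {l.sample_id: l.is_pcr for l in results["labels"]}
        tables = []
        for gene in sorted(models):
            tables.append(region_frequency_table(
                variants, models[gene], pcr, vaf_threshold
            ))
        results["regions"] = pd.concat(tables, ignore_index=True)
        _write_tsv(results["regions"], outdir / "regions.tsv")

    @stage("survival")
    def _survival():
        scored = results.get("scores")
        risk = (
            dict(zip(scored["sample_id"], scored["risk_group"]))
            if scored is not None else {}
        )
        rep = survival_report(samples, risk, results["labels"])
        results["survival"] = rep
        _write_tsv(rep, outdir / "survival.tsv")

    manifest.write(outdir / "manifest.yaml")
    summary = {
        "n_patients": len(samples),
        "n_variants": len(variants),
        "hub_genes": sorted(results.get("hub_genes", [])),
        "model_features": list(results["model_spec"].feature_names),
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return results
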