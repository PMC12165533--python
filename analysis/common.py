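"""Shared plumbing for the numbered analysis drivers.

Generates (once) the synthetic discovery and validation cohorts that stand
in for the study's patients, plus the network/annotation/transcript
fixtures, under results/cohort/.
"""

from pathlib import Path

from ctpet.io import (
    read_samples_tsv,
    read_variants_tsv,
    write_ppi_edges,
    write_samples_tsv,
    write_transcript_model,
    write_treatment_annotation,
    write_variants_tsv,
)
from ctpet.simulate import (
    DRIVER_GENE,
    default_panel,
    default_treatment_annotation,
    study_like,
    simulate_cohort,
    simulate_ppi_network,
    synthetic_driver_transcript,
)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
COHORT_DIR = RESULTS / "cohort"

DISCOVERY_N = 68
VALIDATION_N = 55
SEED = 20240317


def ensure_cohort() -> dict:
    """Simulate and persist the cohorts if absent; return the file paths."""
    paths = {
        "variants": COHORT_DIR / "variants.tsv",
        "samples": COHORT_DIR / "samples.tsv",
        "truth": COHORT_DIR / "truth.tsv",
        "ppi_edges": COHORT_DIR / "ppi_edges.tsv",
        "treatment_annotation": COHORT_DIR / "treatment_annotation.tsv",
        "transcript_models": COHORT_DIR / "transcripts.tsv",
        "panel": COHORT_DIR / "panel.txt",
    }
    if all(p.exists() for p in paths.values()):
        return paths
    COHORT_DIR.mkdir(parents=True, exist_ok=True)

    discovery = simulate_cohort(study_like(seed=SEED, n_patients=DISCOVERY_N))
    validation = simulate_cohort(
        study_like(seed=SEED + 1, n_patients=VALIDATION_N)
    )
    for s in validation.samples:
        s.cohort = "validation"
        s.sample_id = s.sample_id.replace("P", "V")
    validation_variants = [
        v.__class__(**{**v.__dict__, "sample_id":
                       v.sample_id.replace("P", "V")})
        for v in validation.variants
    ]
    validation.truth["sample_id"] = validation.truth["sample_id"].str.replace(
        "P", "V"
    )

    write_variants_tsv(
        discovery.variants + validation_variants, paths["variants"]
    )
    write_samples_tsv(
        discovery.samples + validation.samples, paths["samples"]
    )
    import pandas as pd

    pd.concat([discovery.truth, validation.truth]).to_csv(
        paths["truth"], sep="\t", index=False
    )

    panel = default_panel()
    fillers = sorted(g for g in panel if g.startswith("GENE"))
    planted = sorted([DRIVER_GENE] + fillers[:5])
    write_ppi_edges(
        simulate_ppi_network(panel, planted, 0.01, seed=SEED),
        paths["ppi_edges"],
    )
    write_treatment_annotation(
        default_treatment_annotation(), paths["treatment_annotation"]
    )
    write_transcript_model(
        synthetic_driver_transcript(), paths["transcript_models"]
    )
    paths["panel"].write_text("\n".join(panel) + "\n")
    return paths


def load_cohort():
    paths = ensure_cohort()
    return (
        read_variants_tsv(paths["variants"]),
        read_samples_tsv(paths["samples"]),
        paths,
    )
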