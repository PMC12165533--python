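"""Seeded synthetic cohorts with the statistical structure of the study.

The generator emulates a neoadjuvant-immunochemotherapy ESCC cohort profiled
by panel ctDNA sequencing and FDG PET/CT:

* pathological complete response (pCR) drawn Bernoulli(pcr_rate),
* per-gene pre-treatment ctDNA carriage from marginal prevalences
  (TP53-dominated), post-treatment carriage by response-conditional
  retention — pCR patients clear every alteration by default,
* variant allele fractions and cfDNA concentrations lognormal,
* PET metrics lognormal with response-conditional post-treatment means
  (TLG is SUVmean x MTV by construction),
* pathology areas consistent with the drawn response class,
* disease-free and overall survival exponential by latent risk group,
  administratively censored.

Everything is deterministic given the seed. The defaults (``study_like``)
encode the printed cohort facts of the source study: pCR ~= 25%, TP53
prevalence 63% pre-treatment, ctDNA detection ~= 75% pre and ~= 31% post,
and universal clearance in pCR patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io import SampleRecord, write_samples_tsv, write_variants_tsv
from .quant import VariantCall

DRIVER_GENE = "TP53"

#: marginal pre-treatment carriage of the frequently altered non-driver genes
DEFAULT_OTHER_GENE_PREV = {
    "EGFR": 0.07,
    "PIK3CA": 0.07,
    "MET": 0.04,
    "ATR": 0.04,
    "NFE2L2": 0.04,
    "ESR1": 0.04,
    "BRCA2": 0.04,
    "CDKN2A": 0.04,
}

#: (mu, sigma) on the log scale, keyed [metric][timepoint][is_pcr]
DEFAULT_SUV_PARAMS = {
    "suvmean": {
        "pre": {True: (math.log(6.0), 0.35), False: (math.log(6.0), 0.35)},
        "post": {True: (math.log(1.3), 0.30), False: (math.log(3.2), 0.45)},
    },
    "mtv": {
        "pre": {True: (math.log(12.0), 0.50), False: (math.log(12.0), 0.50)},
        "post": {True: (math.log(2.5), 0.50), False: (math.log(6.0), 0.60)},
    },
}


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class CohortSimParams:
    """Generating parameters of a synthetic cohort.

    ``clearance_prob_nonpcr`` defaults to 0.52, which calibrates the
    post-treatment any-gene detection rate to ~= 0.31 given the default
    prevalences (analytically: detection_post = (1 - pcr_rate) *
    (1 - prod_g (1 - (1 - clearance) * prev_g))).
    ``driver_clearance_nonpcr`` optionally overrides the driver gene's
    clearance among non-pCR patients for planted-driver experiments.
    """

    n_patients: int = 68
    pcr_rate: float = 0.25
    tp53_prev_pre: float = 0.63
    other_gene_prev: dict = field(
        default_factory=lambda: dict(DEFAULT_OTHER_GENE_PREV)
    )
    clearance_prob_pcr: float = 1.0
    clearance_prob_nonpcr: float = 0.52
    driver_gene: str = DRIVER_GENE
    driver_clearance_nonpcr: Optional[float] = None
    vaf_lognormal_params: tuple = (math.log(0.02), 1.0)
    cfdna_lognormal_pre: tuple = (math.log(10.0), 0.5)
    cfdna_lognormal_post: tuple = (math.log(8.0), 0.5)
    suv_params_by_response: dict = field(
        default_factory=lambda: {
            m: {tp: dict(v) for tp, v in d.items()}
            for m, d in DEFAULT_SUV_PARAMS.items()
        }
    )
    suvmax_factor_params: tuple = (math.log(2.0), 0.15)
    bloodpool_suv_params: tuple = (2.0, 0.2)
    class_probs: tuple = (0.85, 0.09, 0.06)  # mutation, CNV, SV
    driver_exon_fraction: float = 0.85  # share of driver calls in exons
    nonpcr_class_probs: tuple = (0.36, 0.38, 0.26)  # MPR, pPR, pSD
    ln_metastasis_prob_nonpcr: float = 0.28
    unresected_prob_nonpcr: float = 0.11
    hazard_low: float = 0.008  # DFS events per month, low-risk
    hazard_high: float = 0.035
    os_hazard_scale: float = 0.6
    censor_horizon: float = 36.0  # months
    dropout: bool = False
    dropout_max_months: float = 36.0
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "pcr_rate": self.pcr_rate,
            "tp53_prev_pre": self.tp53_prev_pre,
            "clearance_prob_pcr": self.clearance_prob_pcr,
            "clearance_prob_nonpcr": self.clearance_prob_nonpcr,
            "ln_metastasis_prob_nonpcr": self.ln_metastasis_prob_nonpcr,
            "unresected_prob_nonpcr": self.unresected_prob_nonpcr,
            "driver_exon_fraction": self.driver_exon_fraction,
            **{f"prev[{g}]": p for g, p in self.other_gene_prev.items()},
        }
        if self.driver_clearance_nonpcr is not None:
            probs["driver_clearance_nonpcr"] = self.driver_clearance_nonpcr
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {p}")
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        for name in ("vaf_lognormal_params", "cfdna_lognormal_pre",
                     "cfdna_lognormal_post", "suvmax_factor_params"):
            _, sigma = getattr(self, name)
            if sigma <= 0:
                raise ParameterError(f"{name}: sigma must be positive")
        for metric, byt in self.suv_params_by_response.items():
            for tp, byr in byt.items():
                for resp, (_, sigma) in byr.items():
                    if sigma <= 0:
                        raise ParameterError(
                            f"suv_params[{metric}][{tp}][{resp}]: sigma must be positive"
                        )
        for name in ("hazard_low", "hazard_high"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.censor_horizon <= 0:
            raise ParameterError("censor_horizon must be positive")
        if abs(sum(self.class_probs) - 1) > 1e-9:
            raise ParameterError("class_probs must sum to 1")

    def with_overrides(self, **kwargs) -> "CohortSimParams":
        return replace(self, **kwargs)

    @property
    def gene_prevalences(self) -> dict:
        return {self.driver_gene: self.tp53_prev_pre, **self.other_gene_prev}


def study_like(**overrides) -> CohortSimParams:
    """The default preset encoding the printed cohort facts."""
    return CohortSimParams(**overrides)


def planted_driver(**overrides) -> CohortSimParams:
    """study_like with a stronger driver signal for hub-gene experiments.

    The driver gene persists more often in non-pCR patients (clearance 0.30
    instead of the cohort-wide 0.52), so a module containing it separates
    pCR from non-pCR with AUC ~= 0.72 in expectation while driver-free
    modules stay near 0.5.
    """
    kwargs = {"driver_clearance_nonpcr": 0.30}
    kwargs.update(overrides)
    return CohortSimParams(**kwargs)


@dataclass
class SyntheticCohort:
    variants: list
    samples: list
    truth: pd.DataFrame
    params: CohortSimParams

    def to_tsv(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "variants": outdir / "variants.tsv",
            "samples": outdir / "samples.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_variants_tsv(self.variants, paths["variants"])
        write_samples_tsv(self.samples, paths["samples"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


_BASES = np.array(list("ACGT"))

#: synthetic per-gene loci; the driver occupies 1..12000 so that the bundled
#: synthetic transcript model (see below) can classify its variants
_GENE_CHROM = {DRIVER_GENE: "chr17"}

#: exon layout of the synthetic driver transcript (1-based inclusive);
#: shared with synthetic_driver_transcript so placement and classification
#: agree
_DRIVER_EXONS = tuple((200 + k * 1000, 200 + k * 1000 + 149) for k in range(11))
_DRIVER_INTRONS = tuple(
    (_DRIVER_EXONS[k][1] + 1, _DRIVER_EXONS[k + 1][0] - 1) for k in range(10)
)


def _draw_driver_pos(rng: np.random.Generator, exon_fraction: float) -> int:
    """Driver-gene position: exonic with probability ``exon_fraction``.

    Deep targeted panels enrich coding regions, so most called driver
    mutations fall in exons — which is also the printed finding this
    emulates (exon mutations outnumber intron mutations).
    """
    intervals = (
        _DRIVER_EXONS if rng.random() < exon_fraction else _DRIVER_INTRONS
    )
    lo, hi = intervals[int(rng.integers(0, len(intervals)))]
    return int(rng.integers(lo, hi + 1))


def _draw_vaf(rng: np.random.Generator, mu: float, sigma: float) -> float:
    """Lognormal VAF truncated to (0, 1] by rejection."""
    for _ in range(1000):
        v = float(rng.lognormal(mu, sigma))
        if 0.0 < v <= 1.0:
            return v
    return 1.0


def _draw_variant(
    rng: np.random.Generator,
    params: CohortSimParams,
    sample_id: str,
    timepoint: str,
    gene: str,
    vclass: str,
    pos: int,
) -> VariantCall:
    mu, sigma = params.vaf_lognormal_params
    ref, alt = rng.choice(_BASES, size=2, replace=False)
    return VariantCall(
        sample_id=sample_id,
        timepoint=timepoint,
        gene=gene,
        chrom=_GENE_CHROM.get(gene, "chr1"),
        pos=pos,
        ref=str(ref),
        alt=str(alt),
        vclass=vclass,
        vaf=_draw_vaf(rng, mu, sigma) if vclass == "mutation" else None,
    )


def simulate_cohort(params: CohortSimParams) -> SyntheticCohort:
    """Generate one seeded cohort; deterministic given ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    genes = list(params.gene_prevalences)
    prev = np.array([params.gene_prevalences[g] for g in genes])
    n = params.n_patients

    is_pcr = rng.random(n) < params.pcr_rate
    pre_carriage = rng.random((n, len(genes))) < prev[None, :]

    clearance = np.where(
        is_pcr[:, None], params.clearance_prob_pcr, params.clearance_prob_nonpcr
    ) * np.ones((n, len(genes)))
    if params.driver_clearance_nonpcr is not None:
        j = genes.index(params.driver_gene)
        clearance[~is_pcr, j] = params.driver_clearance_nonpcr
    retained = pre_carriage & (rng.random((n, len(genes))) >= clearance)

    variants: list[VariantCall] = []
    samples: list[SampleRecord] = []
    truth_rows = []
    mu_cf_pre, sg_cf_pre = params.cfdna_lognormal_pre
    mu_cf_post, sg_cf_post = params.cfdna_lognormal_post

    for i in range(n):
        sid = f"P{i + 1:04d}"
        pcr = bool(is_pcr[i])

        # --- variants -----------------------------------------------------
        for j, gene in enumerate(genes):
            if not pre_carriage[i, j]:
                continue
            vclass = ("mutation", "CNV", "SV")[
                rng.choice(3, p=params.class_probs)
            ]
            if gene == params.driver_gene:
                pos = _draw_driver_pos(rng, params.driver_exon_fraction)
            else:
                pos = int(rng.integers(1, 12000))
            variants.append(
                _draw_variant(rng, params, sid, "pre", gene, vclass, pos)
            )
            if retained[i, j]:
                variants.append(
                    _draw_variant(rng, params, sid, "post", gene, vclass, pos)
                )

        # --- cfDNA and PET ------------------------------------------------
        cf_pre = float(rng.lognormal(mu_cf_pre, sg_cf_pre))
        cf_post = float(rng.lognormal(mu_cf_post, sg_cf_post))
        pet = {}
        for tp in ("pre", "post"):
            mu, sigma = params.suv_params_by_response["suvmean"][tp][pcr]
            suvmean = float(rng.lognormal(mu, sigma))
            mu, sigma = params.suv_params_by_response["mtv"][tp][pcr]
            mtv = float(rng.lognormal(mu, sigma))
            fmu, fsg = params.suvmax_factor_params
            suvmax = suvmean * float(rng.lognormal(fmu, fsg))
            bp_mu, bp_sg = params.bloodpool_suv_params
            bloodpool = max(0.5, float(rng.normal(bp_mu, bp_sg)))
            pet[tp] = {
                "suvmean": suvmean,
                "mtv": mtv,
                "suvmax": suvmax,
                "tlg": suvmean * mtv,
                "bloodpool_suvmax": bloodpool,
            }

        # --- pathology ----------------------------------------------------
        unresected = False
        if pcr:
            viable_pct = 0.0
            ln_met = False
        else:
            cls = int(rng.choice(3, p=params.nonpcr_class_probs))
            if cls == 0:  # MPR
                viable_pct = float(rng.uniform(0.5, 10.0))
            elif cls == 1:  # pPR
                viable_pct = float(rng.uniform(10.0, 50.0) + 1e-6)
            else:  # pSD
                viable_pct = float(rng.uniform(50.0, 90.0) + 1e-6)
            ln_met = bool(rng.random() < params.ln_metastasis_prob_nonpcr)
            unresected = bool(rng.random() < params.unresected_prob_nonpcr)
        necrosis_pct = float(rng.uniform(0.0, min(20.0, 100.0 - viable_pct)))
        regression_pct = 100.0 - viable_pct - necrosis_pct

        # --- survival -----------------------------------------------------
        risk = "low" if pcr else "high"
        hz = params.hazard_low if risk == "low" else params.hazard_high
        dfs_t = float(rng.exponential(1.0 / hz))
        os_t = float(rng.exponential(1.0 / (hz * params.os_hazard_scale)))
        horizon = params.censor_horizon
        if params.dropout:
            horizon = min(
                horizon, float(rng.uniform(0.0, params.dropout_max_months))
            )
        dfs_months, dfs_event = min(dfs_t, horizon), int(dfs_t <= horizon)
        os_months, os_event = min(os_t, horizon), int(os_t <= horizon)

        samples.append(SampleRecord(
            sample_id=sid,
            cohort="discovery",
            cfdna_pre=cf_pre,
            cfdna_post=cf_post,
            suvmax_pre=pet["pre"]["suvmax"],
            suvmean_pre=pet["pre"]["suvmean"],
            mtv_pre=pet["pre"]["mtv"],
            tlg_pre=pet["pre"]["tlg"],
            bloodpool_suvmax_pre=pet["pre"]["bloodpool_suvmax"],
            suvmax_post=pet["post"]["suvmax"],
            suvmean_post=pet["post"]["suvmean"],
            mtv_post=pet["post"]["mtv"],
            tlg_post=pet["post"]["tlg"],
            bloodpool_suvmax_post=pet["post"]["bloodpool_suvmax"],
            viable_area=viable_pct,
            regression_area=regression_pct,
            necrosis_area=necrosis_pct,
            lymph_node_metastasis=ln_met,
            surgery_performed=not unresected,
            dfs_months=dfs_months,
            dfs_event=dfs_event,
            os_months=os_months,
            os_event=os_event,
        ))
        j_drv = genes.index(params.driver_gene)
        truth_rows.append({
            "sample_id": sid,
            "is_pcr": pcr,
            "risk_group": risk,
            "driver_pre": bool(pre_carriage[i, j_drv]),
            "driver_post": bool(retained[i, j_drv]),
        })

    truth = pd.DataFrame(truth_rows)
    # invariant: pCR patients with full clearance carry no post-NICT variant
    if params.clearance_prob_pcr == 1.0:
        pcr_ids = set(truth.loc[truth.is_pcr, "sample_id"])
        assert not any(
            v.sample_id in pcr_ids and v.timepoint == "post" for v in variants
        )
    return SyntheticCohort(variants, samples, truth, params)


# ---------------------------------------------------------------------------
# PPI network fixture
# ---------------------------------------------------------------------------


def simulate_ppi_network(
    panel_genes,
    planted_module,
    background_edge_prob: float = 0.01,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Planted-clique interaction network over a gene panel.

    The planted module becomes a clique; every other unordered gene pair is
    an edge independently with ``background_edge_prob``. Deterministic given
    the seed and the sorted gene order.
    """
    panel = sorted(set(panel_genes))
    planted = sorted(set(planted_module))
    if not set(planted) <= set(panel):
        raise ParameterError("planted module must be a subset of the panel")
    if len(planted) < 3:
        raise ParameterError("planted module needs at least 3 genes "
                             "(the minimum module size)")
    if not 0.0 <= background_edge_prob <= 1.0:
        raise ParameterError("background_edge_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    planted_set = set(planted)
    edges = []
    for i, a in enumerate(panel):
        for b in panel[i + 1:]:
            if a in planted_set and b in planted_set:
                edges.append((a, b))
            elif rng.random() < background_edge_prob:
                edges.append((a, b))
    return edges


# ---------------------------------------------------------------------------
# feature-level cohorts with planted logistic effects
# ---------------------------------------------------------------------------

def synthetic_driver_transcript(n_exons: int = 11, strand: str = "+"):
    """A synthetic transcript model for the driver gene (test fixture).

    Eleven 150-bp exons spaced 1 kb apart on arbitrary coordinates inside
    the simulator's 1..12000 gene locus; it is NOT the true TP53 transcript
    — exon numbering is relative to this model only.
    """
    from .regions import TranscriptModel

    exons = list(_DRIVER_EXONS[:n_exons])
    if strand == "-":
        exons = exons[::-1]
    return TranscriptModel(gene=DRIVER_GENE, strand=strand, exons=tuple(exons))


def default_treatment_annotation() -> list[tuple[str, str]]:
    """Synthetic (gene, paradigm) table over the default panel.

    Groups the default genes by the treatment paradigm their alterations
    are most associated with; the driver gene is annotated to both the
    immunotherapy and chemotherapy paradigms (its alterations bear on both),
    so hub convergence intersects one interaction-derived and two
    treatment-derived modules. A study would supply its own table.
    """
    return [
        (DRIVER_GENE, "immunotherapy"),
        ("NFE2L2", "immunotherapy"),
        ("ATR", "immunotherapy"),
        (DRIVER_GENE, "chemotherapy"),
        ("BRCA2", "chemotherapy"),
        ("MET", "chemotherapy"),
        ("EGFR", "targeted"),
        ("PIK3CA", "targeted"),
        ("MET", "targeted"),
        ("ESR1", "targeted"),
        ("CDKN2A", "targeted"),
    ]


def default_panel(n_filler: int = 24) -> list[str]:
    """Default gene panel: the simulated genes plus unaltered filler genes."""
    fillers = [f"GENE{i + 1:03d}" for i in range(n_filler)]
    return sorted(set(DEFAULT_OTHER_GENE_PREV) | {DRIVER_GENE} | set(fillers))


DEFAULT_PLANTED_BETA = {"suvmean_post": -1.0, "ctdna_concentration_post": -0.01}


def simulate_feature_cohort(
    n: int,
    beta: Optional[dict] = None,
    intercept: float = 4.0,
    n_noise: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Patient-level feature matrix with a known logistic outcome model.

    Planted features (default: post-treatment SUVmean with log-odds slope
    -1.0 per SUV and ctDNA concentration with -0.01 per hGE/ml) are drawn
    lognormal on realistic scales; ``n_noise`` standard-normal noise columns
    are independent of the outcome. pCR ~ Bernoulli(expit(intercept +
    x . beta)). Used for selection-consistency, parameter-recovery, and
    null-calibration experiments.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    beta = dict(DEFAULT_PLANTED_BETA) if beta is None else dict(beta)
    rng = np.random.default_rng(seed)
    cols = {
        "suvmean_post": rng.lognormal(math.log(3.0), 0.5, n),
        "ctdna_concentration_post": rng.lognormal(math.log(60.0), 1.0, n),
    }
    for k in range(1, n_noise + 1):
        cols[f"noise{k}"] = rng.normal(0.0, 1.0, n)
    df = pd.DataFrame(cols)
    for name in beta:
        if name not in df.columns:
            raise ParameterError(f"beta refers to unknown feature {name!r}")
    lin = intercept + sum(b * df[name].to_numpy() for name, b in beta.items())
    prob = 1.0 / (1.0 + np.exp(-lin))
    df.insert(0, "sample_id", [f"P{i + 1:05d}" for i in range(n)])
    df["pcr"] = (rng.random(n) < prob).astype(int)
    return df
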