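"""Gene-module construction and hub-gene convergence.

The panel's genes are clustered two ways: communities of a protein-protein
interaction network (greedy modularity, size-bounded to [3, 500] with
recursive splitting of oversized communities) and treatment-paradigm
annotations (one module per paradigm; a gene may serve several paradigms).
Each module's post-treatment any-mutation status is scored as a pCR
discriminator (orientation: mutation predicts non-pCR, so informative
modules exceed AUC 0.5), and the hub genes are the intersection of every
module clearing the AUC threshold.

Community detection here replaces an external enrichment service used in
the original analysis workflow; module *identities* therefore depend on the
supplied network, while the convergence logic does not.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .quant import QuantResult
from .stats import roc_auc

logger = logging.getLogger(__name__)

MIN_MODULE_SIZE = 3
MAX_MODULE_SIZE = 500
HUB_AUC_THRESHOLD = 0.65


class ConfigError(ValueError):
    pass


@dataclass
class GeneModule:
    module_id: str
    source: str  # "ppi" or "treatment"
    genes: frozenset
    auc: Optional[float] = None
    degenerate: bool = False

    def qualifies(self, threshold: float = HUB_AUC_THRESHOLD) -> bool:
        return self.auc is not None and self.auc > threshold


def build_ppi_modules(
    edges: Iterable[tuple[str, str]],
    panel: Sequence[str],
    min_size: int = MIN_MODULE_SIZE,
    max_size: int = MAX_MODULE_SIZE,
    seed: int = 0,
    resolution: float = 0.5,
) -> list[GeneModule]:
    """Size-bounded modularity communities of the panel PPI graph.

    Louvain communities at resolution 0.5: plain modularity (resolution 1)
    exhibits the pendant pathology on panel-sized graphs — a hub-gene
    clique member with a single outside neighbor is split off as a pair —
    while the lower resolution keeps densely connected gene sets together.
    Edges touching genes outside the panel are dropped with a warning.
    Communities smaller than ``min_size`` are discarded; larger than
    ``max_size`` are split by re-clustering the induced subgraph at full
    resolution. Deterministic given the seed and input ordering. Module
    ids P1.. are assigned by decreasing size, then lexicographic gene
    order.
    """
    panel_set = set(panel)
    g = nx.Graph()
    dropped = 0
    for a, b in edges:
        if a in panel_set and b in panel_set:
            g.add_edge(a, b)
        else:
            dropped += 1
    if dropped:
        logger.warning("dropped %d edge(s) outside the panel", dropped)
    if g.number_of_edges() == 0:
        warnings.warn("empty panel-restricted PPI graph; no modules",
                      stacklevel=2)
        return []

    def _communities(subgraph, gamma) -> list[set]:
        if subgraph.number_of_edges() == 0:
            return [set(c) for c in nx.connected_components(subgraph)]
        return [
            set(c)
            for c in nx.community.louvain_communities(
                subgraph, resolution=gamma, seed=seed
            )
        ]

    def _split(members: set) -> list[set]:
        if len(members) <= max_size:
            return [members]
        sub = g.subgraph(members)
        parts = _communities(sub, 1.0)
        if len(parts) <= 1:  # indivisible: hard-split by sorted order
            ordered = sorted(members)
            return [
                set(ordered[i:i + max_size])
                for i in range(0, len(ordered), max_size)
            ]
        out = []
        for p in parts:
            out.extend(_split(p))
        return out

    final: list[set] = []
    for community in _communities(g, resolution):
        final.extend(_split(community))
    final = [c for c in final if len(c) >= min_size]
    final.sort(key=lambda c: (-len(c), tuple(sorted(c))))
    return [
        GeneModule(f"P{i + 1}", "ppi", frozenset(c))
        for i, c in enumerate(final)
    ]


def assign_treatment_modules(
    annotation: Iterable[tuple[str, str]],
    panel: Optional[Sequence[str]] = None,
) -> list[GeneModule]:
    """One module per treatment paradigm, in order of first appearance.

    Duplicate (gene, paradigm) rows deduplicate with a warning; a gene
    annotated to several paradigms appears in each. Annotated genes outside
    the panel (when a panel is given) are a configuration error.
    """
    seen = set()
    order: list[str] = []
    members: dict[str, set] = {}
    dupes = 0
    for gene, paradigm in annotation:
        if panel is not None and gene not in set(panel):
            raise ConfigError(f"annotated gene {gene!r} not in the panel")
        if (gene, paradigm) in seen:
            dupes += 1
            continue
        seen.add((gene, paradigm))
        if paradigm not in members:
            members[paradigm] = set()
            order.append(paradigm)
        members[paradigm].add(gene)
    if dupes:
        warnings.warn(f"deduplicated {dupes} repeated annotation row(s)",
                      stacklevel=2)
    return [
        GeneModule(f"T{i + 1}", "treatment", frozenset(members[p]))
        for i, p in enumerate(order)
    ]


def gene_status_table(
    results: Iterable[QuantResult],
    timepoint: str = "post",
    panel: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Patients x genes boolean positivity table at one timepoint.

    With ``panel`` given, the columns are exactly the panel's genes (genes
    never altered in the cohort appear as all-negative columns).
    """
    rows = {}
    genes = set()
    for r in results:
        if r.timepoint != timepoint:
            continue
        rows[r.sample_id] = dict(r.per_gene_status)
        genes.update(r.per_gene_status)
    columns = sorted(set(panel)) if panel is not None else sorted(genes)
    df = pd.DataFrame(False, index=sorted(rows), columns=columns)
    for sample_id, status in rows.items():
        for gene, flag in status.items():
            if gene in df.columns:
                df.loc[sample_id, gene] = bool(flag)
    return df


def module_status(
    module: GeneModule,
    gene_status: pd.DataFrame,
    mode: str = "binary",
) -> pd.Series:
    """Per-patient module signal: any-positive (binary) or positive count."""
    unknown = module.genes - set(gene_status.columns)
    present = sorted(module.genes & set(gene_status.columns))
    if not present:
        raise ConfigError(
            f"module {module.module_id} has no gene in the status table "
            f"(unknown: {sorted(unknown)})"
        )
    sub = gene_status[present]
    if mode == "binary":
        return sub.any(axis=1).astype(int)
    if mode == "count":
        return sub.sum(axis=1).astype(int)
    raise ConfigError("mode must be 'binary' or 'count'")


def module_auc(
    module: GeneModule,
    gene_status: pd.DataFrame,
    pcr_status: Mapping[str, bool],
    mode: str = "binary",
) -> GeneModule:
    """Score a module's discrimination of pCR; returns an updated module.

    The positive label is non-pCR and the score is the module status, so a
    module whose mutations mark residual disease scores above 0.5. Constant
    status vectors get AUC 0.5 with the degenerate flag.
    """
    status = module_status(module, gene_status, mode)
    patients = [p for p in status.index if p in pcr_status]
    scores = status.loc[patients].to_numpy(dtype=float)
    non_pcr = [0 if pcr_status[p] else 1 for p in patients]
    if len(set(non_pcr)) < 2:
        raise ValueError("both pCR and non-pCR patients are required")
    if len(set(scores.tolist())) < 2:
        module.auc = 0.5
        module.degenerate = True
        return module
    module.auc = roc_auc(scores, non_pcr).auc
    module.degenerate = False
    return module


def hub_genes(
    modules: Sequence[GeneModule],
    auc_threshold: float = HUB_AUC_THRESHOLD,
) -> frozenset:
    """Intersection of the gene sets of every qualifying module.

    A module qualifies when its AUC strictly exceeds the threshold. When
    both module systems (PPI and treatment) are represented in the input,
    at least one qualifying module from each system is required; otherwise
    the plain intersection of whatever qualifies is returned with a note.
    Empty if nothing qualifies.
    """
    scored = [m for m in modules if m.auc is not None]
    qualifying = [m for m in scored if m.qualifies(auc_threshold)]
    if not qualifying:
        return frozenset()
    systems_present = {m.source for m in scored}
    systems_qualifying = {m.source for m in qualifying}
    if len(systems_present) > 1 and systems_qualifying != systems_present:
        logger.info(
            "qualifying modules come from %s only; using plain intersection",
            sorted(systems_qualifying),
        )
    hub = set(qualifying[0].genes)
    for m in qualifying[1:]:
        hub &= m.genes
    return frozenset(hub)


def module_report(modules: Sequence[GeneModule],
                  auc_threshold: float = HUB_AUC_THRESHOLD) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "module_id": m.module_id,
            "source": m.source,
            "size": len(m.genes),
            "auc": m.auc,
            "qualifies": m.qualifies(auc_threshold),
            "genes": ",".join(sorted(m.genes)),
        }
        for m in modules
    ])
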