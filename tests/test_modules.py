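"""Gene modules: PPI communities, treatment annotation, hub convergence."""

import numpy as np
import pandas as pd
import pytest

from ctpet.modules import (
    ConfigError,
    GeneModule,
    assign_treatment_modules,
    build_ppi_modules,
    gene_status_table,
    hub_genes,
    module_auc,
    module_status,
)
from ctpet.quant import sample_status
from ctpet.simulate import simulate_ppi_network
from conftest import make_variant


class TestPpiModules:
    def test_single_triangle_is_one_module(self):
        edges = [("A", "B"), ("B", "C"), ("A", "C")]
        mods = build_ppi_modules(edges, ["A", "B", "C", "D"])
        assert len(mods) == 1
        assert mods[0].genes == frozenset("ABC")

    def test_size_two_components_excluded(self):
        edges = [("A", "B"), ("C", "D")]
        assert build_ppi_modules(edges, list("ABCD")) == []

    def test_empty_graph_warns_and_returns_nothing(self):
        with pytest.warns(UserWarning, match="empty"):
            assert build_ppi_modules([], ["A", "B"]) == []

    def test_off_panel_edges_dropped(self, caplog):
        edges = [("A", "B"), ("B", "C"), ("A", "C"), ("A", "Z")]
        with caplog.at_level("WARNING"):
            mods = build_ppi_modules(edges, ["A", "B", "C"])
        assert mods[0].genes == frozenset("ABC")

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_clique_recovered_in_sparse_background(self, seed):
        panel = [f"G{i:02d}" for i in range(24)]
        planted = set(panel[:6])
        edges = simulate_ppi_network(panel, planted, 0.01, seed)
        mods = build_ppi_modules(edges, panel, seed=seed)
        assert any(planted <= m.genes for m in mods)

    def test_oversized_communities_split_within_bounds(self):
        # two 5-cliques joined by one bridge edge, max_size 5 forces a split
        left = [f"L{i}" for i in range(5)]
        right = [f"R{i}" for i in range(5)]
        edges = [(a, b) for i, a in enumerate(left) for b in left[i + 1:]]
        edges += [(a, b) for i, a in enumerate(right) for b in right[i + 1:]]
        edges.append((left[0], right[0]))
        mods = build_ppi_modules(edges, left + right, min_size=3, max_size=5)
        assert mods and all(3 <= len(m.genes) <= 5 for m in mods)

    def test_ppi_modules_are_disjoint(self, rng):
        panel = [f"G{i:02d}" for i in range(30)]
        edges = simulate_ppi_network(panel, set(panel[:5]), 0.08, 3)
        mods = build_ppi_modules(edges, panel)
        seen = set()
        for m in mods:
            assert not (m.genes & seen)
            seen |= m.genes


class TestTreatmentModules:
    def test_modules_mirror_annotation(self):
        ann = [("A", "immuno"), ("B", "immuno"), ("C", "chemo"),
               ("D", "target"), ("E", "target")]
        mods = assign_treatment_modules(ann)
        assert [m.module_id for m in mods] == ["T1", "T2", "T3"]
        assert mods[0].genes == frozenset("AB")
        assert mods[1].genes == frozenset("C")

    def test_empty_annotation_gives_empty_list(self):
        assert assign_treatment_modules([]) == []

    def test_multi_paradigm_gene_in_both_modules(self):
        ann = [("A", "immuno"), ("A", "chemo"), ("B", "chemo")]
        mods = assign_treatment_modules(ann)
        assert mods[0].genes == frozenset("A")
        assert mods[1].genes == frozenset("AB")

    def test_duplicate_rows_deduplicated_with_warning(self):
        ann = [("A", "immuno"), ("A", "immuno")]
        with pytest.warns(UserWarning, match="dedup"):
            mods = assign_treatment_modules(ann)
        assert mods[0].genes == frozenset("A")

    def test_off_panel_annotation_rejected(self):
        with pytest.raises(ConfigError):
            assign_treatment_modules([("Z", "immuno")], panel=["A", "B"])


def status_frame(rows):
    return pd.DataFrame(rows).astype(bool)


class TestModuleStatus:
    def test_any_positive_gene_fires_binary_and_count(self):
        status = status_frame({"TP53": [True], "NFE2L2": [False]})
        module = GeneModule("T1", "treatment", frozenset({"TP53", "NFE2L2"}))
        assert module_status(module, status, "binary").iloc[0] == 1
        assert module_status(module, status, "count").iloc[0] == 1

    def test_no_positive_gene_is_zero(self):
        status = status_frame({"TP53": [False], "NFE2L2": [False]})
        module = GeneModule("T1", "treatment", frozenset({"TP53", "NFE2L2"}))
        assert module_status(module, status).iloc[0] == 0

    def test_two_positives_count_two_binary_one(self):
        status = status_frame({"TP53": [True], "NFE2L2": [True]})
        module = GeneModule("T1", "treatment", frozenset({"TP53", "NFE2L2"}))
        assert module_status(module, status, "binary").iloc[0] == 1
        assert module_status(module, status, "count").iloc[0] == 2

    def test_module_without_known_genes_rejected(self):
        status = status_frame({"TP53": [True]})
        module = GeneModule("T1", "treatment", frozenset({"XYZ"}))
        with pytest.raises(ConfigError):
            module_status(module, status)


class TestModuleAuc:
    def test_perfect_complement_scores_one(self):
        pcr = {f"S{i}": i < 5 for i in range(10)}
        status = status_frame({
            "TP53": [not pcr[f"S{i}"] for i in range(10)],
        })
        status.index = [f"S{i}" for i in range(10)]
        module = GeneModule("T1", "treatment", frozenset({"TP53"}))
        assert module_auc(module, status, pcr).auc == 1.0

    def test_binary_auc_equals_mean_sens_spec_by_direct_count(self, rng):
        n = 20
        ids = [f"S{i}" for i in range(n)]
        pcr = {s: bool(rng.integers(0, 2)) for s in ids}
        if len(set(pcr.values())) < 2:
            pcr[ids[0]] = not pcr[ids[1]]
        flags = rng.integers(0, 2, n).astype(bool)
        if len(set(flags.tolist())) < 2:
            flags[0] = not flags[1]
        status = pd.DataFrame({"TP53": flags}, index=ids)
        module = GeneModule("T1", "treatment", frozenset({"TP53"}))
        auc = module_auc(module, status, pcr).auc
        non_pcr = [s for s in ids if not pcr[s]]
        pcr_pos = [s for s in ids if pcr[s]]
        sens = np.mean([status.loc[s, "TP53"] for s in non_pcr])
        spec = np.mean([not status.loc[s, "TP53"] for s in pcr_pos])
        assert auc == pytest.approx((sens + spec) / 2, abs=1e-12)

    def test_constant_status_degenerate_half(self):
        pcr = {"S0": True, "S1": False}
        status = pd.DataFrame({"TP53": [False, False]}, index=["S0", "S1"])
        module = GeneModule("T1", "treatment", frozenset({"TP53"}))
        scored = module_auc(module, status, pcr)
        assert scored.auc == 0.5 and scored.degenerate

    def test_independent_status_near_half_at_large_n(self, rng):
        n = 2000
        ids = [f"S{i}" for i in range(n)]
        pcr = {s: bool(rng.random() < 0.3) for s in ids}
        status = pd.DataFrame(
            {"TP53": rng.random(n) < 0.4}, index=ids
        )
        module = GeneModule("T1", "treatment", frozenset({"TP53"}))
        assert module_auc(module, status, pcr).auc == pytest.approx(
            0.5, abs=0.05
        )


class TestHubGenes:
    def _mods(self):
        return [
            GeneModule("P4", "ppi", frozenset({"TP53", "A"}), auc=0.72),
            GeneModule("P1", "ppi", frozenset({"X", "Y", "Z"}), auc=0.52),
            GeneModule("T4", "treatment", frozenset({"TP53", "B"}), auc=0.70),
            GeneModule("T5", "treatment", frozenset({"TP53", "C"}), auc=0.68),
            GeneModule("T1", "treatment", frozenset({"D", "E"}), auc=0.55),
        ]

    def test_intersection_of_qualifying_modules(self):
        assert hub_genes(self._mods()) == frozenset({"TP53"})

    def test_no_qualifying_module_gives_empty_set(self):
        mods = self._mods()
        for m in mods:
            m.auc = 0.5
        assert hub_genes(mods) == frozenset()

    def test_single_qualifying_module_returns_its_genes(self):
        mods = [
            GeneModule("P1", "ppi", frozenset({"A", "B", "C"}), auc=0.8),
            GeneModule("P2", "ppi", frozenset({"D", "E", "F"}), auc=0.5),
        ]
        assert hub_genes(mods) == frozenset({"A", "B", "C"})

    def test_threshold_sweep_follows_intersection_semantics(self):
        """Hub sets along a threshold sweep are intersections over the
        qualifying modules: unchanged while the qualifying set is
        unchanged, superset when a module drops out of the intersection,
        empty once nothing qualifies."""
        mods = self._mods()
        by_threshold = {
            t: hub_genes(mods, t) for t in (0.65, 0.69, 0.71, 0.73)
        }
        assert by_threshold[0.65] == frozenset({"TP53"})
        assert by_threshold[0.69] == frozenset({"TP53"})
        # only P4 qualifies: its whole gene set is the (trivial) intersection
        assert by_threshold[0.71] == frozenset({"TP53", "A"})
        assert by_threshold[0.73] == frozenset()

    def test_strictly_above_threshold_required(self):
        mods = [GeneModule("P1", "ppi", frozenset({"A", "B", "C"}), auc=0.65)]
        assert hub_genes(mods, 0.65) == frozenset()


class TestGeneStatusTable:
    def test_includes_patients_without_variants(self):
        results = [
            sample_status([make_variant(sample_id="S1")], sample_id="S1",
                          timepoint="post"),
            sample_status([], sample_id="S2", timepoint="post"),
        ]
        table = gene_status_table(results, "post", panel=["TP53", "EGFR"])
        assert list(table.index) == ["S1", "S2"]
        assert bool(table.loc["S1", "TP53"]) and not table.loc["S2", "TP53"]
        assert not table["EGFR"].any()
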