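"""Ontology compression, differential edges, coordination, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dualgi as dg


def _sym_frame(rng, labels):
    m = rng.normal(0, 1, (len(labels), len(labels)))
    m = (m + m.T) / 2
    return pd.DataFrame(m, index=labels, columns=labels)


@pytest.fixture()
def gene_matrix():
    rng = np.random.default_rng(0)
    return _sym_frame(rng, [f"g{i}" for i in range(5)])


class TestCompression:
    def test_singleton_clusters_reproduce_gene_level(self, gene_matrix):
        clusters = pd.Series(
            {g: f"c{i}" for i, g in enumerate(gene_matrix.index)}
        )
        om = dg.compress_to_ontology(gene_matrix, clusters)
        relabeled = om.scores.copy()
        relabeled.index = [om.members[c][0] for c in om.scores.index]
        relabeled.columns = relabeled.index
        assert np.allclose(relabeled, gene_matrix.loc[relabeled.index, relabeled.index])

    def test_hand_computed_two_and_three_gene_clusters(self, gene_matrix):
        clusters = pd.Series(
            {"g0": "A", "g1": "A", "g2": "B", "g3": "B", "g4": "B"}
        )
        om = dg.compress_to_ontology(gene_matrix, clusters)
        # off-diagonal cell: mean of the 2x3 cross block
        cross = gene_matrix.loc[["g0", "g1"], ["g2", "g3", "g4"]].to_numpy()
        assert om.scores.at["A", "B"] == pytest.approx(cross.mean(), abs=1e-12)
        # diagonal: intra-cluster pairs, self cells excluded
        assert om.scores.at["A", "A"] == pytest.approx(
            gene_matrix.at["g0", "g1"], abs=1e-12
        )
        intra_b = [
            gene_matrix.at[i, j]
            for i, j in [("g2", "g3"), ("g2", "g4"), ("g3", "g4")]
        ]
        assert om.scores.at["B", "B"] == pytest.approx(np.mean(intra_b), abs=1e-12)

    def test_masked_pairs_omitted_from_the_mean(self, gene_matrix):
        gene_matrix.at["g0", "g2"] = gene_matrix.at["g2", "g0"] = np.nan
        clusters = pd.Series(
            {"g0": "A", "g1": "A", "g2": "B", "g3": "B", "g4": "B"}
        )
        om = dg.compress_to_ontology(gene_matrix, clusters)
        kept = gene_matrix.loc[["g0", "g1"], ["g2", "g3", "g4"]].to_numpy()
        assert om.scores.at["A", "B"] == pytest.approx(np.nanmean(kept), abs=1e-12)

    def test_unassigned_gene_rejected(self, gene_matrix):
        with pytest.raises(ValueError, match="without a cluster"):
            dg.compress_to_ontology(gene_matrix, pd.Series({"g0": "A"}))

    def test_reduced_variance_vs_gene_level(self, planted_screen):
        """Compressing a simulated map averages away gene-level noise."""
        _, _, _, res = planted_screen
        m = res.gene_gi["reference"]
        genes = list(m.targeting)
        clusters = pd.Series(
            {g: f"c{i // 6}" for i, g in enumerate(genes)}
        )
        om = dg.compress_to_ontology(m, clusters)
        iu = np.triu_indices(len(om.scores), k=1)
        comp_sd = np.nanstd(om.scores.to_numpy()[iu])
        gu = np.triu_indices(len(genes), k=1)
        gene_sd = np.nanstd(m.interaction_scores.to_numpy()[gu])
        assert comp_sd < gene_sd


class TestDifferential:
    def _oms(self):
        rng = np.random.default_rng(1)
        labels = ["c1", "c2", "c3"]
        ref = _sym_frame(rng, labels) * 0.1
        env = ref.copy()
        env.at["c1", "c2"] = env.at["c2", "c1"] = 3.0   # gained
        ref.at["c1", "c3"] = ref.at["c3", "c1"] = -3.0  # lost
        members = {c: [c] for c in labels}
        return (
            dg.OntologyMatrix(env, members, "env"),
            dg.OntologyMatrix(ref, members, "ref"),
        )

    def test_identical_matrices_give_no_edges(self):
        _, ref = self._oms()
        out = dg.ontology_differential(ref, ref, threshold=1.0)
        assert out.gained == [] and out.lost == []
        assert np.allclose(out.diff, 0)

    def test_gained_and_lost_edges_identified(self):
        env, ref = self._oms()
        out = dg.ontology_differential(env, ref, threshold=1.0)
        assert out.gained == [("c1", "c2")]
        assert out.lost == [("c1", "c3")]

    def test_antisymmetry_under_swap(self):
        env, ref = self._oms()
        fwd = dg.ontology_differential(env, ref, threshold=1.0)
        rev = dg.ontology_differential(ref, env, threshold=1.0)
        assert np.allclose(fwd.diff, -rev.diff)
        assert set(fwd.gained) == set(rev.lost)

    def test_cluster_set_mismatch_rejected(self):
        env, _ = self._oms()
        other = dg.OntologyMatrix(
            pd.DataFrame(0.0, index=["x"], columns=["x"]), {"x": ["x"]}, "r"
        )
        with pytest.raises(ValueError, match="cluster sets"):
            dg.ontology_differential(env, other, threshold=1.0)


class TestCoordination:
    def test_identical_profiles_give_r_one_and_self_excluded(self):
        rng = np.random.default_rng(2)
        labels = [f"c{i}" for i in range(6)]
        m = _sym_frame(rng, labels)
        m.loc["c1"] = m.loc["c0"]
        m["c1"] = m["c0"]
        m.at["c1", "c1"] = m.at["c0", "c0"]
        om = dg.OntologyMatrix(m, {c: [c] for c in labels}, "ref")
        prof = dg.coordination_profile("c0", {"ref": om})
        assert "c0" not in prof.index
        assert prof.at["c1", "ref"] == pytest.approx(1.0, abs=1e-9)

    def test_condition_specific_partner_shift(self, planted_screen):
        """A module's top correlate changes between conditions when its
        interactions are rewired."""
        _, _, _, res = planted_screen
        genes = list(res.gene_gi["reference"].targeting)
        clusters = pd.Series({g: f"c{i // 5}" for i, g in enumerate(genes)})
        maps = {
            cond: dg.compress_to_ontology(res.gene_gi[cond], clusters)
            for cond in res.conditions
        }
        prof = dg.coordination_profile("c0", maps)
        assert set(prof.columns) == set(res.conditions)
        assert prof.notna().all().all()


class TestPPIEnrichment:
    def _matrix(self, seed=3, n=16):
        rng = np.random.default_rng(seed)
        labels = [f"g{i}" for i in range(n)]
        scores = _sym_frame(rng, labels)
        return dg.GIMatrix(
            level="gene", condition="ref", channel="gamma",
            scores=scores, n_obs=scores.notna().astype(int),
            is_ntc=pd.Series(False, index=labels),
        )

    def test_constant_escores_give_unit_enrichment(self):
        m = self._matrix()
        genes = list(m.scores.index)
        ppi = dg.PPITable(
            {
                tuple(sorted((a, b))): 0.5
                for i, a in enumerate(genes)
                for b in genes[i + 1 :]
            }
        )
        out = dg.ppi_enrichment(m, ppi, n_bins=5)
        assert np.allclose(out.table["enrichment"], 1.0)
        assert np.isnan(out.p_value) or out.p_value > 0.9

    def test_planted_overlap_enriches_top_bin(self):
        m = self._matrix(seed=4)
        pairs = m.pairs_long().sort_values("score", key=abs)
        strong = pairs.tail(20)
        ppi = dg.PPITable(
            {tuple(sorted((a, b))): 0.9 for a, b in zip(strong.entity_a, strong.entity_b)}
        )
        out = dg.ppi_enrichment(m, ppi, n_bins=5)
        tab = out.table.sort_values("mean_abs_score")
        assert tab.iloc[-1]["enrichment"] > 1.5
        assert tab.iloc[-1]["enrichment"] > tab.iloc[0]["enrichment"]
        assert out.p_value < 0.01

    def test_bin_without_ppi_scores_zero(self):
        m = self._matrix(seed=5)
        pairs = m.pairs_long().sort_values("score", key=abs)
        strong = pairs.tail(10)  # only strongest pairs have known PPIs
        ppi = dg.PPITable(
            {tuple(sorted((a, b))): 0.8 for a, b in zip(strong.entity_a, strong.entity_b)}
        )
        out = dg.ppi_enrichment(m, ppi, n_bins=4)
        tab = out.table.sort_values("mean_abs_score")
        assert tab.iloc[0]["mean_escore"] == 0.0  # absent PPIs count as 0

    def test_no_coverage_rejected(self):
        m = self._matrix()
        with pytest.raises(ValueError, match="covers no pair"):
            dg.ppi_enrichment(m, dg.PPITable({("x", "y"): 0.5}))

    def test_tsv_round_trip(self, tmp_path):
        ppi = dg.PPITable({("a", "b"): 0.3, ("a", "c"): 0.9})
        ppi.write_tsv(tmp_path / "ppi.tsv")
        back = dg.PPITable.read_tsv(tmp_path / "ppi.tsv")
        assert back.scores == ppi.scores
        assert back.escore("b", "a") == 0.3  # order-insensitive lookup
        assert back.escore("b", "c") == 0.0


class TestIterativeEnrichment:
    @pytest.fixture()
    def gsc(self):
        universe = frozenset(f"u{i}" for i in range(200))
        sets = {
            "term_big": frozenset(f"u{i}" for i in range(20)),
            "term_small": frozenset(f"u{i}" for i in range(20, 30)),
            "term_other": frozenset(f"u{i}" for i in range(100, 140)),
        }
        return dg.GeneSetCollection(sets=sets, universe=universe)

    def test_exact_term_hit_then_empty(self, gsc):
        hits = set(gsc.sets["term_small"])
        out = dg.iterative_enrichment(hits, gsc, n_iter=10)
        assert out.iloc[0]["term"] == "term_small"
        assert len(out) == 1  # second iteration saw an empty hit list

    def test_two_planted_terms_recovered_in_order_and_disjoint(self, gsc):
        hits = set(gsc.sets["term_big"]) | set(gsc.sets["term_small"])
        out = dg.iterative_enrichment(hits, gsc, n_iter=10)
        assert list(out["term"][:2]) == ["term_big", "term_small"]
        assert out.iloc[0]["significant"] and out.iloc[1]["significant"]
        removed = [set(r) for r in out["genes_removed"]]
        for i in range(len(removed)):
            for j in range(i + 1, len(removed)):
                assert removed[i].isdisjoint(removed[j])

    def test_random_hits_not_significant(self, gsc):
        rng = np.random.default_rng(6)
        hits = set(rng.choice(sorted(gsc.universe), size=25, replace=False))
        out = dg.iterative_enrichment(hits, gsc, n_iter=10)
        assert not out["significant"].any()

    def test_hypergeometric_matches_fisher_exact(self, gsc):
        """Cross-check the upper-tail hypergeometric p against Fisher's
        exact test on the same 2x2 table."""
        hits = set(gsc.sets["term_small"]) | {f"u{i}" for i in range(30, 45)}
        out = dg.iterative_enrichment(hits, gsc, n_iter=1)
        k = out.iloc[0]["n_overlap"]
        term = gsc.sets[out.iloc[0]["term"]]
        table = [
            [k, len(term) - k],
            [len(hits) - k, len(gsc.universe) - len(term) - len(hits) + k],
        ]
        _, p_fisher = stats.fisher_exact(table, alternative="greater")
        assert out.iloc[0]["p_value"] == pytest.approx(p_fisher, rel=1e-9)

    def test_gmt_round_trip(self, tmp_path, gsc):
        gsc.write_gmt(tmp_path / "sets.gmt")
        back = dg.GeneSetCollection.read_gmt(
            tmp_path / "sets.gmt", universe=gsc.universe
        )
        assert back.sets == gsc.sets
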