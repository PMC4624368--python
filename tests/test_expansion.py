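"""Recruitment, class labeling, and closest-published-relative scoring."""

import networkx as nx
import numpy as np
import pytest

from seqsimnet.config import PipelineConfig
from seqsimnet.expansion import (
    classify_nodes,
    cpr_identity,
    divergence_summary,
    expand_families,
    recruit_round,
)
from seqsimnet.records import SequenceRecord
from seqsimnet.similarity import LocalAligner, SimilarityHit
from seqsimnet.simulate import random_protein
from ._oracles import bfs_distances


def _env(seq_id, residues, sample="aquatic"):
    return SequenceRecord(seq_id, residues, origin="Environment", sample_id=sample)


def _pub(seq_id, residues, origin="Bacteria"):
    return SequenceRecord(seq_id, residues, origin=origin)


@pytest.fixture(scope="module")
def aligner():
    return LocalAligner(min_score=40)


class TestRecruitment:
    def test_identical_env_orf_recruited(self, aligner):
        rng = np.random.default_rng(2)
        seq = random_protein(80, rng)
        recruited, hits = recruit_round([_pub("seed", seq)], [_env("e", seq)], aligner)
        assert recruited == {"e"}
        assert hits[0].pident == 100.0

    def test_no_hit_above_floor_yields_empty(self, aligner):
        rng = np.random.default_rng(4)
        seed = _pub("seed", random_protein(60, rng))
        env = _env("e", random_protein(60, rng))
        recruited, _ = recruit_round([seed], [env], aligner)
        assert recruited == set()

    def test_empty_env_db(self, aligner):
        recruited, hits = recruit_round([_pub("seed", "MKVLITGAGSGIG")], [], aligner)
        assert recruited == set() and hits == []

    def test_hit_cap_limits_per_seed(self):
        hits = [
            SimilarityHit("seed", f"e{i}", 90.0, 50, qend=50, send=50,
                          evalue=1e-20, bitscore=100.0 - i)
            for i in range(5)
        ]
        seeds = [_pub("seed", "A" * 50)]
        env = [_env(f"e{i}", "A" * 50) for i in range(5)]
        cfg = PipelineConfig(recruit_hit_cap=2)
        recruited, _ = recruit_round(seeds, env, hits, cfg)
        assert recruited == {"e0", "e1"}


class TestExpandFamilies:
    """Two-tier planted family: the class-2-like clade is reachable only
    through the round-1 recruits."""

    def test_second_round_reaches_second_tier(self, default_dataset):
        truth = default_dataset.truth
        nuclei = [default_dataset.proteins[i] for i in truth.ids_with_class("nucleus")
                  if not i.startswith("x")]
        env = [s for s in default_dataset.proteins if s.is_environmental]
        engine = LocalAligner(min_score=40)

        one_round = expand_families(nuclei, env, engine, PipelineConfig(recruitment_rounds=1))
        two_rounds = expand_families(nuclei, env, engine, PipelineConfig(recruitment_rounds=2))

        c1 = set(truth.ids_with_class("class1"))
        c2 = set(truth.ids_with_class("class2"))
        r1 = set(one_round.recruited_round)
        r2 = set(two_rounds.recruited_round)
        # round 1 reaches the directly connected clades but not the second tier
        assert c1 <= r1
        assert not (c2 & r1)
        assert c2 <= r2
        # monotone recruitment
        assert r1 <= r2
        assert all(two_rounds.recruited_round[i] == 2 for i in c2)

    def test_unrelated_env_db_recruits_nothing(self, aligner):
        rng = np.random.default_rng(6)
        nuclei = [_pub("seed", random_protein(100, rng))]
        env = [_env(f"e{i}", random_protein(100, rng)) for i in range(5)]
        expanded = expand_families(nuclei, env, aligner)
        assert expanded.recruited_round == {}
        assert [s.id for s in expanded.sequences] == ["seed"]


class TestClassifyNodes:
    def _path_net(self):
        g = nx.path_graph(["n", "e1", "e2", "e3"])
        return g

    def test_path_distances(self):
        labels = classify_nodes(self._path_net(), ["n"])
        assert labels == {"n": "nucleus", "e1": "class1", "e2": "class2", "e3": "distal"}

    def test_nucleus_adjacency_wins(self):
        g = nx.Graph([("n", "e1"), ("e1", "e"), ("n", "e")])
        labels = classify_nodes(g, ["n"])
        assert labels["e"] == "class1"

    def test_disconnected_node_is_distal(self):
        g = self._path_net()
        g.add_node("lonely")
        assert classify_nodes(g, ["n"])["lonely"] == "distal"

    def test_matches_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            g = nx.gnp_random_graph(30, 0.08, seed=int(rng.integers(1 << 30)))
            nuclei = [v for v in g.nodes if rng.random() < 0.15]
            labels = classify_nodes(g, nuclei)
            dist = bfs_distances(list(g.nodes), list(g.edges), nuclei)
            for v in g.nodes:
                if v in nuclei:
                    assert labels[v] == "nucleus"
                else:
                    expected = {1: "class1", 2: "class2"}.get(dist[v], "distal")
                    assert labels[v] == expected

    def test_class2_invariant(self, default_result):
        """Every class-2 node has a class-1 neighbour and no nucleus neighbour."""
        net = default_result.exploratory_net
        labels = default_result.class_labels
        for node, lab in labels.items():
            if lab != "class2":
                continue
            neighbour_labels = {labels[v] for v in net[node]}
            assert "class1" in neighbour_labels
            assert "nucleus" not in neighbour_labels


class TestCPR:
    def test_identical_published_scores_hundred(self, aligner):
        rng = np.random.default_rng(8)
        seq = random_protein(80, rng)
        (rec,) = cpr_identity([_env("e", seq)], [_pub("p", seq)], aligner)
        assert rec.cpr_identity == pytest.approx(100.0)
        assert rec.best_published_id == "p"

    def test_max_over_hits(self):
        hits = [
            SimilarityHit("e", "p1", 80.0, 90, qend=90, send=90, evalue=1e-30, bitscore=100),
            SimilarityHit("e", "p2", 55.3, 100, qend=100, send=100, evalue=1e-30, bitscore=80),
        ]
        env = [_env("e", "A" * 100)]
        pubs = [_pub("p1", "A" * 100), _pub("p2", "A" * 100)]
        (rec,) = cpr_identity(env, pubs, hits)
        # 80.0 * 90/100 = 72.0 beats 55.3
        assert rec.cpr_identity == pytest.approx(72.0)
        assert rec.best_published_id == "p1"

    def test_tie_breaks_by_bitscore_then_id(self):
        base = dict(pident=80.0, aln_len=100, qend=100, send=100, evalue=1e-30)
        hits = [
            SimilarityHit("e", "p2", bitscore=90.0, **base),
            SimilarityHit("e", "p1", bitscore=90.0, **base),
            SimilarityHit("e", "p3", bitscore=99.0, **base),
        ]
        env = [_env("e", "A" * 100)]
        pubs = [_pub(p, "A" * 100) for p in ("p1", "p2", "p3")]
        (rec,) = cpr_identity(env, pubs, hits)
        # equal adjusted identity everywhere: higher bitscore wins
        assert rec.best_published_id == "p3"
        (rec,) = cpr_identity(env, pubs[:2], hits[:2])
        # bitscore also tied: lexicographically smaller id wins
        assert rec.best_published_id == "p1"

    def test_no_hit_recorded_explicitly(self, aligner):
        rng = np.random.default_rng(10)
        (rec,) = cpr_identity([_env("e", random_protein(60, rng))],
                              [_pub("p", random_protein(60, rng))], aligner)
        assert not rec.has_cpr
        assert rec.cpr_identity is None

    def test_planted_divergent_clade_scores_below_cutoff(self, default_dataset, default_result):
        truth = default_dataset.truth.by_id()
        for rec in default_result.cpr_records:
            row = truth[rec.env_id]
            if row.clade in ("c1div", "c2div") and rec.has_cpr:
                assert rec.cpr_identity < 60.0

    def test_class1_can_be_divergent(self, default_result):
        """Being directly connected to a nucleus does not put a sequence
        above the divergence cutoff: the planted class-1 clade is both
        class 1 and < 60 % CPR identity."""
        labels = default_result.class_labels
        divergent_class1 = [
            r for r in default_result.cpr_records
            if labels.get(r.env_id) == "class1" and r.has_cpr and r.cpr_identity < 60
        ]
        assert divergent_class1


class TestDivergenceSummary:
    def _recs(self, values, stratum="gut"):
        from seqsimnet.expansion import CPRRecord

        return [CPRRecord(f"e{i}", "p", v, stratum) for i, v in enumerate(values)]

    def test_bin_proportions(self):
        df = divergence_summary(self._recs([95, 97, 50, 40]), [0, 60, 95, 100])
        row = df.loc["gut"]
        assert row["[0,60)"] == pytest.approx(0.5)
        assert row["[60,95)"] == 0.0
        assert row["[95,100]"] == pytest.approx(0.5)

    def test_single_record(self):
        df = divergence_summary(self._recs([72.0]), [0, 60, 95, 100])
        assert df.loc["gut", "[60,95)"] == 1.0

    def test_no_cpr_counted_separately(self):
        from seqsimnet.expansion import CPRRecord

        recs = self._recs([50.0]) + [CPRRecord("x", None, None, "gut")]
        df = divergence_summary(recs, [0, 60, 100])
        assert df.loc["gut", "no_cpr"] == 1
        assert df.loc["gut", "[0,60)"] == 1.0

    def test_bad_bins_rejected(self):
        with pytest.raises(ValueError):
            divergence_summary(self._recs([50.0]), [60, 0])
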