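"""CDR3 homology graph, neighbor enrichment and motif clusters."""

import itertools

import numpy as np
import pytest

import repseq as rs
from repseq.simulate import generate_baseline

from conftest import make_meta


def random_cdr3s(n, rng, lengths=(8, 9, 10)):
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    out = set()
    while len(out) < n:
        ln = int(rng.choice(lengths))
        out.add("".join(alphabet[int(i)] for i in rng.integers(0, 20, ln)))
    return out


class TestGraph:
    def test_single_mismatch_edge(self):
        g = rs.build_cdr3_graph({"CASSL", "CASSF"})
        assert g.edges == {frozenset({"CASSL", "CASSF"})}

    def test_length_difference_is_not_an_edge(self):
        g = rs.build_cdr3_graph({"CASSL", "CASS"})
        assert g.edges == set()

    def test_two_mismatches_not_connected(self):
        g = rs.build_cdr3_graph({"CASSL", "CAWWL"})
        assert g.edges == set()

    def test_no_self_edges_and_equal_length_endpoints(self):
        rng = np.random.default_rng(0)
        g = rs.build_cdr3_graph(random_cdr3s(300, rng))
        for e in g.edges:
            a, b = tuple(e)
            assert a != b and len(a) == len(b)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(1)
        seqs = sorted(random_cdr3s(500, rng, lengths=(6, 7)))
        g = rs.build_cdr3_graph(seqs)
        oracle = set()
        for a, b in itertools.combinations(seqs, 2):
            if len(a) == len(b) and sum(x != y for x, y in zip(a, b)) == 1:
                oracle.add(frozenset({a, b}))
        assert g.edges == oracle


class TestEnrichment:
    def test_no_neighbors_never_selected(self, model):
        baseline = [c.cdr3_aa for c in
                    generate_baseline(model, 2000, np.random.default_rng(0))]
        sample = {"CWWWWWWWWWWF", "CYYYYYYYYYYF"}  # isolated sequences
        recs = rs.neighbor_enrichment(sample, baseline)
        assert all(not r.selected and r.observed_neighbors == 0 for r in recs)

    def test_empty_baseline_is_error(self):
        with pytest.raises(ValueError):
            rs.neighbor_enrichment({"CASSF"}, [])

    def test_baseline_smaller_than_sample_is_error(self):
        with pytest.raises(ValueError):
            rs.neighbor_enrichment({"CASSF", "CASSL", "CASSY"}, ["CAF"])

    def test_null_level_control(self, model):
        """Samples drawn from the baseline distribution itself are selected
        at no more than the nominal rate after correction."""
        baseline = [c.cdr3_aa for c in
                    generate_baseline(model, 10000, np.random.default_rng(10))]
        rng = np.random.default_rng(11)
        for _ in range(5):
            sample = {c.cdr3_aa for c in generate_baseline(model, 1000, rng)}
            recs = rs.neighbor_enrichment(sample, baseline, alpha=0.05)
            assert sum(r.selected for r in recs) / len(recs) <= 0.05

    def test_planted_cluster_recovered(self, model):
        """A dense one-mismatch neighborhood stands out against the null."""
        rng = np.random.default_rng(12)
        consensus = "CAILNVGDRGF"
        planted = {consensus}
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        for pos in range(2, 10):
            for alt in alphabet[:4]:
                if alt != consensus[pos]:
                    planted.add(consensus[:pos] + alt + consensus[pos + 1:])
        planted = set(sorted(planted)[:30])
        background = {c.cdr3_aa for c in generate_baseline(model, 5000, rng)}
        baseline = [c.cdr3_aa for c in generate_baseline(model, 50000, rng)]
        recs = rs.neighbor_enrichment(planted | background, baseline)
        selected = {r.cdr3_aa for r in recs if r.selected}
        assert len(planted & selected) / len(planted) >= 0.9


class TestExtractClusters:
    def test_empty_selection_gives_no_clusters(self):
        g = rs.build_cdr3_graph({"CASSL", "CASSF"})
        assert rs.extract_clusters(g, set()) == []

    def test_chain_is_one_cluster(self):
        g = rs.build_cdr3_graph({"CASSL", "CASSF", "CASWF"})
        clusters = rs.extract_clusters(g, {"CASSL", "CASSF", "CASWF"})
        assert len(clusters) == 1 and len(clusters[0]) == 3

    def test_singletons_discarded(self):
        g = rs.build_cdr3_graph({"CASSL", "CASSF", "CWWWWWWF"})
        clusters = rs.extract_clusters(g, {"CASSL", "CASSF", "CWWWWWWF"})
        assert len(clusters) == 1

    def test_different_lengths_never_merge(self):
        a = {"CASSF", "CASSL", "CASSY"}
        b = {"CAWWWWF", "CAWWWWL"}
        g = rs.build_cdr3_graph(a | b)
        clusters = rs.extract_clusters(g, a | b)
        assert len(clusters) == 2
        assert all(len({len(m) for m in c.members}) == 1 for c in clusters)

    def test_deterministic_ids_by_size_then_member(self):
        a = {"CASSF", "CASSL", "CASSY"}
        b = {"CAWWWWF", "CAWWWWL"}
        g = rs.build_cdr3_graph(a | b)
        clusters = rs.extract_clusters(g, a | b)
        assert clusters[0].members == frozenset(a)  # larger first
        assert clusters[0].cluster_id == 1

    def test_unknown_selected_sequence_is_error(self):
        g = rs.build_cdr3_graph({"CASSL"})
        with pytest.raises(ValueError):
            rs.extract_clusters(g, {"CXXXX"})


class TestFrequencyMatrixAndPWM:
    def _mini_cohort(self):
        from repseq.simulate import back_translate
        rng = np.random.default_rng(5)
        members = ["CASSF", "CASSL"]
        reps = []
        for i, has_motif in enumerate([True, False]):
            clones = [rs.Clonotype(back_translate("CWWYF", rng), "CWWYF",
                                   "TRAV1", "TRAJ1", count=6)]
            if has_motif:
                clones += [rs.Clonotype(back_translate(m, rng), m, "TRAV2",
                                        "TRAJ2", count=2) for m in members]
            meta = make_meta(sample_id=f"s{i}", mouse=f"control_m{i + 1}")
            reps.append(rs.Repertoire.build(meta, clones))
        cohort = rs.Cohort(repertoires=reps)
        cluster = rs.CDR3Cluster(cluster_id=1, members=frozenset(members))
        return cohort, cluster

    def test_frequencies_summed_and_absent_is_zero(self):
        cohort, cluster = self._mini_cohort()
        mat = rs.cluster_sample_frequencies([cluster], cohort)
        assert mat.loc[1, "s0"] == pytest.approx(0.4)
        assert mat.loc[1, "s1"] == 0.0
        assert ((mat.to_numpy() >= 0) & (mat.to_numpy() <= 1)).all()
        assert (mat.sum(axis=0) <= 1.0 + 1e-9).all()

    def test_challenge_specific_cluster_differs_by_group(self, demo_cohort):
        truth = demo_cohort.ground_truth["challenge_motifs"][("LLC", "eTreg")]
        cluster = rs.CDR3Cluster(cluster_id=1, members=frozenset(truth))
        share = rs.cluster_share_in_subsets(cluster, demo_cohort)
        sub = share[(share.tissue == "lung") & (share.subset == "eTreg")]
        from scipy import stats as sps
        match = sub[sub.challenge == "LLC"].frequency
        rest = sub[sub.challenge != "LLC"].frequency
        t, p = sps.ttest_ind(match, rest, equal_var=False)
        assert t > 0 and p < 0.01

    def test_pwm_one_hot_for_single_sequence(self):
        cluster = rs.CDR3Cluster(cluster_id=1, members=frozenset({"CASSF"}))
        with pytest.raises(ValueError):
            rs.cluster_pwm(rs.CDR3Cluster(cluster_id=2, members=frozenset()))
        cluster = rs.cluster_pwm(cluster)
        assert cluster.consensus == "CASSF"
        assert np.allclose(cluster.pwm.sum(axis=1), 1.0)
        assert (cluster.pwm.to_numpy().max(axis=1) == 1.0).all()

    def test_pwm_even_split_at_variable_position(self):
        cluster = rs.CDR3Cluster(cluster_id=1, members=frozenset({"CASSF", "CASWF"}))
        cluster = rs.cluster_pwm(cluster)  # equal weights without a cohort
        assert cluster.pwm.loc[3, "S"] == pytest.approx(0.5)
        assert cluster.pwm.loc[3, "W"] == pytest.approx(0.5)
        assert np.allclose(cluster.pwm.sum(axis=1), 1.0, atol=1e-9)

    def test_matrix_ordering_preserves_values(self, demo_cohort):
        truths = demo_cohort.ground_truth["challenge_motifs"]
        clusters = [rs.CDR3Cluster(cluster_id=i + 1, members=frozenset(v))
                    for i, v in enumerate(truths.values())]
        raw = rs.cluster_sample_frequencies(clusters, demo_cohort)
        ordered = rs.cluster_frequency_matrix(clusters, demo_cohort)
        assert sorted(ordered.index) == sorted(raw.index)
        assert np.isclose(ordered.to_numpy().sum(), raw.to_numpy().sum())
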