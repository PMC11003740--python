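"""F2 overlap, top-N selection, MDS and dendrograms."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import repseq as rs

from conftest import make_meta, make_repertoire


def rep_from_freqs(freqs, v="TRAV1", j="TRAJ1", scale=1000, sample_id="s"):
    """Repertoire with named amino-acid clonotypes at given frequencies."""
    from repseq.simulate import back_translate
    rng = np.random.default_rng(0)
    clones = []
    for name, f in freqs.items():
        clones.append(rs.Clonotype(back_translate(name, rng), name, v, j,
                                   count=int(round(f * scale))))
    return rs.Repertoire.build(make_meta(sample_id=sample_id), clones)


class TestF2:
    def test_identity_is_one(self):
        rep = make_repertoire([9, 5, 1])
        assert math.isclose(rs.f2_overlap(rep, rep, "aa"), 1.0, abs_tol=1e-12)
        assert math.isclose(rs.f2_overlap(rep, rep, "nt"), 1.0, abs_tol=1e-12)

    def test_disjoint_is_zero(self):
        a = rep_from_freqs({"CAAAF": 0.5, "CAACF": 0.5})
        b = rep_from_freqs({"CWWWF": 0.5, "CWWYF": 0.5})
        assert rs.f2_overlap(a, b, "aa") == 0.0

    def test_hand_evaluated_partial_overlap(self):
        a = rep_from_freqs({"CAAAF": 0.5, "CAYYF": 0.5})
        b = rep_from_freqs({"CAAAF": 0.2, "CAZZF".replace("Z", "W"): 0.8})
        assert math.isclose(rs.f2_overlap(a, b, "aa"), math.sqrt(0.1), abs_tol=1e-9)

    def test_v_segment_must_match_at_aa_level(self):
        a = rep_from_freqs({"CAAAF": 1.0}, v="TRAV1")
        b = rep_from_freqs({"CAAAF": 1.0}, v="TRAV2")
        assert rs.f2_overlap(a, b, "aa") == 0.0

    def test_empty_is_error(self):
        a = make_repertoire([1])
        b = make_repertoire([1])
        b.clonotypes = []
        with pytest.raises(ValueError):
            rs.f2_overlap(a, b, "aa")

    @settings(max_examples=40, deadline=None)
    @given(ca=st.lists(st.integers(1, 20), min_size=1, max_size=20),
           cb=st.lists(st.integers(1, 20), min_size=1, max_size=20))
    def test_symmetry_and_brute_force_oracle(self, ca, cb):
        """F2 equals the all-pairs double loop over matched keys, and is
        symmetric to 1e-12, on arbitrary small repertoires."""
        a, b = make_repertoire(ca), make_repertoire(cb)
        f_ab = rs.f2_overlap(a, b, "aa")
        f_ba = rs.f2_overlap(b, a, "aa")
        assert abs(f_ab - f_ba) < 1e-12
        brute = 0.0
        for x in a.clonotypes:
            for y in b.clonotypes:
                if (x.v_segment, x.cdr3_aa) == (y.v_segment, y.cdr3_aa):
                    brute += math.sqrt(x.frequency * y.frequency)
        assert abs(f_ab - brute) < 1e-9
        assert 0.0 <= f_ab <= 1.0 + 1e-12


class TestTopN:
    def test_fewer_than_n_returns_all(self):
        rep = make_repertoire([5, 4, 3, 2, 1])
        out = rs.top_n_clonotypes(rep, 10, np.random.default_rng(0))
        assert len(out) == 5

    def test_strict_ordering_deterministic(self):
        rep = make_repertoire([9, 5, 1])
        for seed in range(5):
            out = rs.top_n_clonotypes(rep, 2, np.random.default_rng(seed))
            assert sorted(c.count for c in out) == [5, 9]

    def test_ties_broken_by_shuffle(self):
        rep = make_repertoire([10, 10, 10])
        picks = set()
        for seed in range(30):
            out = rs.top_n_clonotypes(rep, 2, np.random.default_rng(seed))
            assert len(out) == 2
            picks.add(frozenset(c.cdr3_nt for c in out))
        assert len(picks) > 1  # different seeds pick different tied pairs

    def test_frequencies_renormalized(self):
        rep = make_repertoire([6, 3, 1])
        out = rs.top_n_clonotypes(rep, 2, np.random.default_rng(0))
        assert math.isclose(sum(c.frequency for c in out), 1.0, abs_tol=1e-12)


class TestPairwiseOverlap:
    def test_small_samples_excluded(self):
        big = [make_repertoire([2] * 800, make_meta(sample_id=f"b{i}",
                                                    mouse=f"control_m{i + 1}"))
               for i in range(2)]
        small = make_repertoire([2] * 600, make_meta(sample_id="small",
                                                     mouse="control_m3"))
        m = rs.pairwise_overlap(big + [small], n=100, min_clonotypes=700,
                                rng=np.random.default_rng(0))
        assert m.excluded == ["small"]
        assert m.sample_ids == ["b0", "b1"]

    def test_identical_samples_give_unit_matrix(self):
        reps = [make_repertoire([5, 4, 3], make_meta(sample_id=f"s{i}",
                                                     mouse=f"control_m{i + 1}"))
                for i in range(3)]
        m = rs.pairwise_overlap(reps, n=10, min_clonotypes=1,
                                rng=np.random.default_rng(0))
        assert np.allclose(m.f2, 1.0)

    def test_too_few_eligible_is_error(self):
        reps = [make_repertoire([3, 2])]
        with pytest.raises(ValueError):
            rs.pairwise_overlap(reps, n=10, min_clonotypes=1)

    def test_within_challenge_exceeds_between(self, demo_cohort):
        lung = [r for r in demo_cohort.filter(tissue="lung", subset="eTreg")
                if r.meta.challenge != "control"]
        m = rs.pairwise_overlap(lung, n=300, match_level="aa", min_clonotypes=50,
                                rng=np.random.default_rng(0))
        chal = {r.meta.sample_id: r.meta.challenge for r in lung}
        within, between = [], []
        for i, j in itertools.combinations(range(len(m.sample_ids)), 2):
            same = chal[m.sample_ids[i]] == chal[m.sample_ids[j]]
            (within if same else between).append(m.f2[i, j])
        assert np.mean(within) > 5 * np.mean(between)


class TestDistanceAndMDS:
    def test_distance_transform(self):
        m = rs.OverlapMatrix(["a", "b"], np.array([[1.0, 0.25], [0.25, 1.0]]),
                             "aa", 10)
        d = rs.overlap_to_distance(m)
        assert d[0, 0] == 0.0 and d[0, 1] == 0.75

    def test_equilateral_triangle(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = rs.mds_embedding(d, dims=2)
        emb = np.sqrt(((res.coords[:, None] - res.coords[None]) ** 2).sum(-1))
        iu = np.triu_indices(3, 1)
        assert np.allclose(emb[iu], emb[iu][0], atol=1e-8)
        assert res.stress < 1e-6

    def test_two_cluster_separation(self):
        from sklearn.metrics import silhouette_score
        n = 10
        d = np.full((n, n), 0.9)
        labels = np.array([0] * 5 + [1] * 5)
        for i in range(n):
            for j in range(n):
                if labels[i] == labels[j]:
                    d[i, j] = 0.1
        np.fill_diagonal(d, 0)
        res = rs.mds_embedding(d, dims=2)
        assert silhouette_score(res.coords, labels) > 0.5

    def test_excess_dims_is_error(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            rs.mds_embedding(d, dims=3)

    def test_asymmetric_input_is_error(self):
        d = np.array([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError):
            rs.mds_embedding(d, dims=1)

    def test_smacof_matches_geometry(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = rs.mds_embedding(d, dims=2, seed=0, method="smacof")
        assert res.stress < 0.05


class TestDendrogram:
    def test_two_sample_cherry(self):
        d = np.array([[0.0, 0.4], [0.4, 0.0]])
        nwk = rs.hierarchical_dendrogram(d, ["a", "b"])
        assert nwk in ("(a:0.2,b:0.2);", "(b:0.2,a:0.2);")

    def test_identical_samples_zero_branches(self):
        d = np.zeros((3, 3))
        nwk = rs.hierarchical_dendrogram(d, ["a", "b", "c"])
        assert ":0" in nwk and "0.5" not in nwk

    def test_leaf_set_preserved(self, demo_cohort):
        lung = demo_cohort.filter(tissue="lung", subset="eTreg")
        m = rs.pairwise_overlap(lung, n=300, min_clonotypes=50,
                                rng=np.random.default_rng(0))
        nwk = rs.hierarchical_dendrogram(rs.overlap_to_distance(m), m.sample_ids)
        import io
        from Bio import Phylo
        tree = Phylo.read(io.StringIO(nwk), "newick")
        leaves = {t.name for t in tree.get_terminals()}
        assert leaves == set(m.sample_ids)

    def test_same_challenge_samples_cluster_together(self, demo_cohort):
        from sklearn.metrics import adjusted_rand_score
        lung = [r for r in demo_cohort.filter(tissue="lung", subset="eTreg")
                if r.meta.challenge != "control"]
        m = rs.pairwise_overlap(lung, n=300, min_clonotypes=50,
                                rng=np.random.default_rng(0))
        d = rs.overlap_to_distance(m)
        chal = {r.meta.sample_id: r.meta.challenge for r in lung}
        truth = [chal[s] for s in m.sample_ids]
        labels = rs.cut_clusters(d, len(set(truth)))
        assert adjusted_rand_score(truth, labels) >= 0.8
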