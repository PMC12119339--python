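import itertools

import numpy as np
import pytest

from coopselex import (Motif, align_motifs, consensus_score_differential,
                       core_flank_divergence, discovery_curve, dominating_set,
                       gapped_kmer_similarity, jensen_shannon_divergence,
                       linear_lower_bound, sqrt_extrapolate, sqrt_model)
from coopselex.motif_analytics import (_gap_configs, _vector_inner,
                                       is_dominating, similarity_matrix,
                                       top_kmer_set, ward_cluster_counts)
from coopselex.selex_sim import consensus_motif, heterogeneous_motif


class TestGappedKmerSimilarity:
    def test_identical_motifs_score_one(self):
        m = heterogeneous_motif("ACGTTAGCAA", [0.8] * 10)
        assert gapped_kmer_similarity(m, m) == pytest.approx(1.0)

    def test_reverse_complement_scores_one(self):
        m = heterogeneous_motif("ACGTTAGCAA", [0.8] * 10)
        assert gapped_kmer_similarity(m, m.reverse_complement()) == \
            pytest.approx(1.0, abs=1e-9)

    def test_disjoint_consensus_motifs_score_near_zero(self):
        a = consensus_motif("AAAAAAAAAA", 0.97)
        c = consensus_motif("CCCCCCCCCC", 0.97)
        assert gapped_kmer_similarity(a, c) < 0.01

    def test_symmetry(self, rng):
        a = Motif(rng.uniform(0.1, 5, size=(4, 8)))
        b = Motif(rng.uniform(0.1, 5, size=(4, 11)))
        assert gapped_kmer_similarity(a, b) == \
            pytest.approx(gapped_kmer_similarity(b, a), rel=1e-9)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(10):
            a = Motif(rng.uniform(0.1, 5, size=(4, rng.integers(6, 12))))
            b = Motif(rng.uniform(0.1, 5, size=(4, rng.integers(6, 12))))
            assert 0.0 <= gapped_kmer_similarity(a, b) <= 1.0

    def test_inner_product_matches_explicit_vector_enumeration(self, rng):
        # small k: enumerate the expected gapped k-mer count vectors
        # explicitly and compare inner products with the factorised form
        k, max_gap = 2, 1
        fa = Motif(rng.uniform(0.1, 5, size=(4, 4))).frequencies
        fb = Motif(rng.uniform(0.1, 5, size=(4, 4))).frequencies

        def explicit_vector(freq):
            vec = {}
            for positions in _gap_configs(k, max_gap):
                span = positions[-1] + 1
                L = freq.shape[1]
                for o in range(L - span + 1):
                    for word in itertools.product(range(4), repeat=k):
                        key = (positions, word)
                        p = 1.0
                        for digit, pos in zip(word, positions):
                            p *= freq[digit, o + pos]
                        vec[key] = vec.get(key, 0.0) + p
            return vec

        va, vb = explicit_vector(fa), explicit_vector(fb)
        explicit = sum(va[kk] * vb.get(kk, 0.0) for kk in va)
        assert _vector_inner(fa, fb, k, max_gap) == \
            pytest.approx(explicit, rel=1e-9)


class TestJSD:
    def test_orthogonal_distributions_give_one_bit(self):
        assert jensen_shannon_divergence([1, 0, 0, 0], [0, 1, 0, 0]) == \
            pytest.approx(1.0)

    def test_identical_distributions_give_zero(self):
        assert jensen_shannon_divergence([0.3, 0.3, 0.2, 0.2],
                                         [0.3, 0.3, 0.2, 0.2]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(4))
            q = rng.dirichlet(np.ones(4))
            d = jensen_shannon_divergence(p, q)
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(jensen_shannon_divergence(q, p))


class TestAlignMotifs:
    def test_recovers_padding_offset(self):
        mono = heterogeneous_motif("TGACTCAT", [0.9] * 8)
        pad = np.full((4, 3), 2.5)
        comp = Motif(np.concatenate([pad, mono.counts, pad], axis=1))
        aln = align_motifs(mono, comp)
        assert aln.offset == 3
        assert aln.orientation == "same"

    def test_detects_revcomp_embedding(self):
        mono = heterogeneous_motif("TGACTCAT", [0.9] * 8)
        pad = np.full((4, 2), 2.5)
        comp = Motif(np.concatenate(
            [pad, mono.reverse_complement().counts, pad], axis=1))
        aln = align_motifs(mono, comp)
        assert aln.orientation == "revcomp"
        assert aln.offset == 2

    def test_no_alignment_raises(self):
        a = consensus_motif("ACGT", 0.9)
        b = consensus_motif("ACG", 0.9)
        with pytest.raises(ValueError):
            align_motifs(a, b, min_overlap=5)


class TestCoreFlankDivergence:
    def _triplet(self, core_override=None):
        """composite = [monoA left | core | monoB right] with the monomers
        overlapping the central core."""
        a = heterogeneous_motif("TTGACG", [0.9] * 6)
        b = heterogeneous_motif("CATAGC", [0.9] * 6)
        core = a.counts[:, 4:] if core_override is None else core_override
        comp_counts = np.concatenate(
            [a.counts[:, :4], core, b.counts[:, 2:]], axis=1)
        return Motif(comp_counts), a, b

    def test_identical_overlap_not_distinct(self):
        comp, a, b = self._triplet()
        rep = core_flank_divergence(comp, a, b)
        assert rep.analysable

    def test_orthogonal_columns_distinct_by_jsd(self):
        comp = heterogeneous_motif("AAAATTTTGGGG", [0.95] * 12)
        a = heterogeneous_motif("AAAACCCC", [0.95] * 8)
        b = heterogeneous_motif("CCCCGGGG", [0.95] * 8)
        rep = core_flank_divergence(comp, a, b)
        if rep.analysable:
            assert rep.distinct_by_jsd

    def test_single_column_jsd_closed_form(self):
        # one fully-concentrated column vs another base: JSD = 1 bit
        assert jensen_shannon_divergence([1, 0, 0, 0], [0, 0, 1, 0]) == 1.0

    def test_jaccard_matches_exhaustive_enumeration(self, rng):
        freq = Motif(rng.uniform(0.1, 5, size=(4, 6))).frequencies
        selected = top_kmer_set(freq, 0.9)
        scores = {}
        for word in itertools.product(range(4), repeat=6):
            p = 1.0
            for j, digit in enumerate(word):
                p *= freq[digit, j]
            idx = 0
            for digit in word:
                idx = idx * 4 + digit
            scores[idx] = p
        mx = max(scores.values())
        oracle = {i for i, s in scores.items() if s >= 0.9 * mx}
        assert set(selected.tolist()) == oracle


class TestConsensusScoreDifferential:
    def test_verbatim_containment_equalises_scores(self):
        mono = heterogeneous_motif("TGACTC", [0.85] * 6)
        comp = Motif(np.concatenate(
            [np.full((4, 3), 2.5), mono.counts, np.full((4, 3), 2.5)],
            axis=1))
        own, on_comp = consensus_score_differential(mono, comp)
        assert on_comp == pytest.approx(own, abs=1e-9)

    def test_uniform_monomer_has_zero_differential(self):
        mono = Motif(np.full((4, 5), 3.0))
        comp = heterogeneous_motif("ACGTACGTAC", [0.9] * 10)
        own, on_comp = consensus_score_differential(mono, comp)
        assert own == pytest.approx(on_comp, abs=1e-9)

    def test_mismatches_cost_logodds_penalties(self):
        # target shares no base with the monomer consensus on either strand
        mono = heterogeneous_motif("AAAA", [0.85] * 4)
        own, on_comp = consensus_score_differential(
            mono, heterogeneous_motif("CCCC", [0.85] * 4))
        assert own > on_comp


class TestDominatingSet:
    def test_edgeless_graph_needs_every_node(self):
        nodes, mode = dominating_set(np.zeros((5, 5), dtype=bool))
        assert nodes == [0, 1, 2, 3, 4]
        assert mode == "ilp"

    def test_star_graph_needs_only_hub(self):
        n = 6
        adj = np.zeros((n, n), dtype=bool)
        adj[0, 1:] = adj[1:, 0] = True
        nodes, _ = dominating_set(adj)
        assert nodes == [0]

    def test_ilp_matches_brute_force_minimum(self, rng):
        for trial in range(15):
            n = int(rng.integers(4, 11))
            adj = rng.random((n, n)) < 0.3
            adj = adj | adj.T
            np.fill_diagonal(adj, False)
            nodes, mode = dominating_set(adj)
            assert mode == "ilp"
            assert is_dominating(adj, nodes)
            best = next(
                size for size in range(1, n + 1)
                if any(is_dominating(adj, c)
                       for c in itertools.combinations(range(n), size)))
            assert len(nodes) == best

    def test_greedy_fallback_is_valid(self, rng):
        n = 30
        adj = rng.random((n, n)) < 0.2
        adj = adj | adj.T
        np.fill_diagonal(adj, False)
        nodes, mode = dominating_set(adj, ilp_max_nodes=10)
        assert mode == "greedy"
        assert is_dominating(adj, nodes)


class TestSaturation:
    def test_exact_sqrt_curve_recovered(self):
        N = np.arange(1, 200, 7)
        curve = np.column_stack([N, 2.0 * np.sqrt(N)])
        fit = sqrt_extrapolate(curve, 500)
        assert fit.A == pytest.approx(2.0, abs=1e-6)
        assert fit.B == pytest.approx(0.0, abs=1e-6)
        assert fit.estimate_total_clusters == pytest.approx(
            2.0 * np.sqrt(500), rel=1e-6)

    def test_discovery_curve_monotone_and_extrapolation_covers_total(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            n_clusters = 40
            pair_to_cluster = {i: int(r.integers(n_clusters))
                               for i in range(300)}
            curve = discovery_curve(pair_to_cluster, n_subsamples=40,
                                    seed=seed)
            # monotone up to subsampling noise (independent draws per N)
            assert (np.diff(curve[:, 1]) >= -0.5).all()
            assert curve[-1, 1] > curve[0, 1]
            fit = sqrt_extrapolate(curve, 300)
            observed = len(set(pair_to_cluster.values()))
            assert fit.estimate_total_clusters >= observed * 0.9

    def test_linear_lower_bound_exact_on_line(self):
        N = np.array([10.0, 50.0, 100.0])
        curve = np.column_stack([N, 3.0 * N + 1.0])
        assert linear_lower_bound(curve, 200, anchor_N=10) == \
            pytest.approx(601.0)

    def test_ntotal_must_cover_curve(self):
        curve = np.array([[10.0, 5.0], [100.0, 20.0]])
        with pytest.raises(ValueError):
            sqrt_extrapolate(curve, 50)

    def test_ward_cluster_counts_monotone(self, rng):
        motifs = [Motif(rng.uniform(0.1, 5, size=(4, 8))) for _ in range(12)]
        S = similarity_matrix(motifs, k=6)
        counts = ward_cluster_counts(S, thresholds=[0.1, 0.5, 1.0, 2.0])
        vals = [counts[t] for t in sorted(counts)]
        assert vals == sorted(vals, reverse=True)
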