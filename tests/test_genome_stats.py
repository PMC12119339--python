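import math

import numpy as np
import pytest

from coopselex import (ConservationTrack, Motif, RegionSet, bh_adjust,
                       conserved_match_test, gmm_conservation_threshold,
                       halfsite_correlation, holm_adjust, make_control_motifs,
                       region_enrichment, revcomp, scan_motif,
                       spacing_conservation)
from coopselex.genome_stats import (Match, MatchSet, pair_spacing_counts,
                                    select_top_nonoverlapping)
from coopselex.selex_sim import consensus_motif, heterogeneous_motif


def _random_genome(length, seed, chrom="chr1"):
    rng = np.random.default_rng(seed)
    return {chrom: "".join(rng.choice(list("ACGT"), size=length))}


class TestScanMotif:
    def test_exact_match_found_on_both_strands(self):
        motif = consensus_motif("TTGACA", 0.97, name="m")
        site = "TTGACA"
        seq = "GGGGCCCGGCC" + site + "GGCCGGGCCG" + revcomp(site) + "CCCGGGCC"
        matches = scan_motif({"chr1": seq}, motif, target_matches=None)
        found = {(m.start, m.strand) for m in matches}
        assert (11, "+") in found
        assert (27, "-") in found

    def test_matches_brute_force_window_scorer(self):
        genome = _random_genome(3000, seed=1)
        motif = heterogeneous_motif("TGACGT", [0.8] * 6, name="m")
        matches = scan_motif(genome, motif, target_matches=None, min_score=1.0)
        lo = motif.log_odds(np.full(4, 0.25))
        seq = genome["chr1"]
        oracle = set()
        for strand, mat in (("+", lo), ("-", lo[::-1, ::-1])):
            for i in range(len(seq) - 5):
                s = sum(mat["ACGT".index(seq[i + j]), j] for j in range(6))
                if s >= 1.0:
                    oracle.add((i, strand, round(s, 9)))
        got = {(m.start, m.strand, round(m.score, 9)) for m in matches}
        # the scan uses the genome's own base composition by default; force
        # uniform for comparability
        matches_u = scan_motif(genome, motif, target_matches=None,
                               min_score=1.0, background=np.full(4, 0.25))
        got = {(m.start, m.strand, round(m.score, 9)) for m in matches_u}
        assert got == oracle

    def test_threshold_raised_to_hit_target_count(self):
        genome = _random_genome(20000, seed=2)
        motif = consensus_motif("ACG", 0.9, name="m")
        matches = scan_motif(genome, motif, target_matches=50, min_score=0.1)
        assert len(matches) >= 50
        assert matches.score_threshold >= 0.1
        full = scan_motif(genome, motif, target_matches=None, min_score=0.1)
        assert len(full) > len(matches)

    def test_fallback_returns_all_floor_matches(self, caplog):
        genome = _random_genome(500, seed=3)
        motif = consensus_motif("TTGACAAC", 0.97, name="rare")
        matches = scan_motif(genome, motif, target_matches=300000)
        assert len(matches) < 300000  # all floor-passing windows returned

    def test_empty_sequences_rejected(self):
        with pytest.raises(ValueError):
            scan_motif({}, consensus_motif("ACGT"))


class TestRegionEnrichment:
    def _matchset(self, positions, width=4, chrom="chr1"):
        ms = [Match(chrom, p, p + width, "+", 5.0, "m") for p in positions]
        return MatchSet(ms, score_threshold=0.0)

    def test_match_everywhere_gives_zero_fold_change(self):
        universe = RegionSet([("chr1", i * 10, i * 10 + 5) for i in range(20)])
        subset = RegionSet(universe.intervals[:5])
        matches = self._matchset([i * 10 for i in range(20)])
        res = region_enrichment(matches, subset, universe)
        assert res.k == res.n and res.m == res.N
        assert res.log2_fold_change == 0.0
        assert res.p_value == 1.0

    def test_exact_hypergeometric_enumeration(self):
        # N=20, n=5, m=8, k=5: upper tail by explicit combinatorics
        universe = RegionSet([("chr1", i * 10, i * 10 + 5) for i in range(20)])
        subset = RegionSet(universe.intervals[:5])
        hit_regions = list(range(5)) + [10, 11, 12]  # m = 8, k = 5
        matches = self._matchset([i * 10 for i in hit_regions])
        res = region_enrichment(matches, subset, universe)
        assert (res.k, res.n, res.m, res.N) == (5, 5, 8, 20)
        p_exact = sum(
            math.comb(8, k) * math.comb(12, 5 - k) for k in range(5, 6)
        ) / math.comb(20, 5)
        assert res.p_value == pytest.approx(p_exact, rel=1e-12)
        assert res.direction == "enrichment"

    def test_equal_rates_give_zero_log2fc(self):
        universe = RegionSet([("chr1", i * 10, i * 10 + 5) for i in range(10)])
        subset = RegionSet(universe.intervals[:5])
        matches = self._matchset([0, 50])  # one hit in subset, one outside
        res = region_enrichment(matches, subset, universe)
        assert res.log2_fold_change == 0.0
        assert res.p_value == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            region_enrichment(self._matchset([0]), RegionSet([]), RegionSet([]))


class TestControlMotifs:
    def test_length10_yields_15_controls_before_filtering(self, rng):
        motif = Motif(rng.uniform(0.5, 9, size=(4, 10)), name="m")
        ctrl = make_control_motifs(motif, similarity_fn=lambda a, b: 0.0)
        assert len(ctrl.controls) == 15
        splits = {prov[0] for _, prov in ctrl.controls}
        assert splits == {3, 4, 5, 6, 7}

    def test_controls_preserve_length_and_content(self, rng):
        motif = Motif(rng.uniform(0.5, 9, size=(4, 9)), name="m")
        ctrl = make_control_motifs(motif, similarity_fn=lambda a, b: 0.0)
        for c, _ in ctrl.controls:
            assert c.length == motif.length
            assert np.allclose(np.sort(c.counts.sum(axis=0)),
                               np.sort(motif.counts.sum(axis=0)))

    def test_degenerate_uniform_motif_controls_excluded(self):
        motif = Motif(np.full((4, 10), 5.0), name="uniform")
        ctrl = make_control_motifs(motif, exclude_above=0.1)
        # every recombination of a uniform motif is the uniform motif itself:
        # after deduplication one control remains and it is excluded as
        # identical to the original
        assert len(ctrl.controls) == 0
        assert len(ctrl.excluded) == 1
        assert ctrl.n_duplicates == 14

    def test_palindromic_motif_duplicates_removed(self):
        # ATATAT is self-complementary and shift-repetitive: several
        # recombinations coincide (e.g. right+left at splits 2 and 4 both
        # reproduce the original)
        motif = Motif(consensus_motif("ATATAT", 0.8).counts, name="pal")
        ctrl = make_control_motifs(motif, similarity_fn=lambda a, b: 0.0)
        assert ctrl.n_duplicates > 0
        assert len(ctrl.controls) + ctrl.n_duplicates == 9

    def test_too_short_motif_gives_empty_set(self):
        ctrl = make_control_motifs(consensus_motif("ACGT", 0.8))
        assert ctrl.controls == [] and ctrl.excluded == []


class TestGMMThreshold:
    def test_balanced_gaussian_mixture_split_near_midpoint(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 1000),
                                 rng.normal(5, 1, 1000)])
        res = gmm_conservation_threshold(scores, seed=0)
        assert not res.degenerate
        assert 2.0 <= res.threshold <= 3.0

    def test_constant_scores_fall_back_to_median(self):
        res = gmm_conservation_threshold([1.5] * 30)
        assert res.degenerate
        assert res.threshold == 1.5

    def test_threshold_stable_across_seeds(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 1000),
                                 rng.normal(5, 1, 1000)])
        thresholds = [gmm_conservation_threshold(scores, seed=s).threshold
                      for s in range(10)]
        assert max(thresholds) - min(thresholds) < 0.05

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            gmm_conservation_threshold([1.0] * 10)


def _track_from_array(scores, chrom="chr1"):
    return ConservationTrack({chrom: dict(enumerate(scores))})


def _spaced_matches(n, width, start=0, step=None, strand="+", score=5.0,
                    name="m", chrom="chr1"):
    step = step or (width + 2)
    return [Match(chrom, start + i * step, start + i * step + width, strand,
                  score, name) for i in range(n)]


class TestTopNonoverlapping:
    def test_greedy_keeps_highest_scoring_disjoint_matches(self):
        a = Match("chr1", 0, 10, "+", 9.0, "m")
        b = Match("chr1", 5, 15, "+", 8.0, "m")   # overlaps a: dropped
        c = Match("chr1", 20, 30, "-", 7.0, "m")
        kept = select_top_nonoverlapping([b, a, c], 10)
        assert kept == [a, c]


class TestConservedMatchTest:
    def test_constructed_separation_is_significant(self, rng):
        width = 8
        true_m = _spaced_matches(300, width, start=0)
        ctrl_m = _spaced_matches(300, width, start=5000, name="ctrl")
        scores = np.zeros(10000)
        for m in true_m:
            scores[m.start:m.end] = 3.0
        for m in ctrl_m:
            scores[m.start:m.end] = -1.0
        track = _track_from_array(scores)
        res = conserved_match_test(MatchSet(true_m, 0.0), MatchSet(ctrl_m, 0.0),
                                   track, top_n=600, threshold=1.0)
        assert res.p_value < 1e-6
        assert res.fold_change > 5

    def test_no_conserved_true_matches_gives_unit_p(self):
        width = 8
        true_m = _spaced_matches(50, width, start=0, score=1.0)
        ctrl_m = _spaced_matches(50, width, start=2000, score=9.0, name="c")
        scores = np.zeros(4000)
        for m in ctrl_m:
            scores[m.start:m.end] = 3.0
        track = _track_from_array(scores)
        res = conserved_match_test(MatchSet(true_m, 0.0), MatchSet(ctrl_m, 0.0),
                                   track, top_n=100, threshold=1.0)
        assert res.k == 0
        assert res.fold_change == 0.0
        assert res.p_value == 1.0


class TestMultipleTesting:
    def test_holm_dominates_raw_and_is_monotone(self, rng):
        p = rng.uniform(0, 1, 25)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_bh_classic_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.9])
        q = bh_adjust(p)
        assert q[0] == pytest.approx(0.04)
        assert q[3] == pytest.approx(0.9)


class TestHalfsiteCorrelation:
    def _matches_with_shared_state(self, rng, n=200, width=10, dependent=True):
        matches = _spaced_matches(n, width)
        scores = np.zeros(n * (width + 2))
        for m in matches:
            if dependent:
                state = rng.random() < 0.5
                level = 2.5 if state else 0.0
                scores[m.start:m.end] = level + rng.normal(0, 0.3, width)
            else:
                scores[m.start:m.end] = rng.normal(0, 1.0, width)
        return matches, _track_from_array(scores)

    def test_planted_shared_state_detected(self, rng):
        matches, track = self._matches_with_shared_state(rng, dependent=True)
        ctrl, track_c = self._matches_with_shared_state(rng, dependent=False)
        # merge the two tracks onto disjoint coordinates
        ctrl = [Match("chrC", m.start, m.end, m.strand, m.score, "c")
                for m in ctrl]
        track.scores["chrC"] = track_c.scores["chr1"]
        res = halfsite_correlation(matches, track, half_split=5,
                                   control_matches=ctrl)
        assert res.significant

    def test_independent_noise_rarely_significant(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            matches, track = self._matches_with_shared_state(
                rng, dependent=False)
            ctrl, track_c = self._matches_with_shared_state(
                rng, dependent=False)
            ctrl = [Match("chrC", m.start, m.end, m.strand, m.score, "c")
                    for m in ctrl]
            track.scores["chrC"] = track_c.scores["chr1"]
            res = halfsite_correlation(matches, track, half_split=5,
                                       control_matches=ctrl)
            hits += res.significant
        assert hits <= 2

    def test_half_split_must_be_interior(self, rng):
        matches, track = self._matches_with_shared_state(rng)
        with pytest.raises(ValueError):
            halfsite_correlation(matches, track, half_split=0,
                                 control_matches=matches)


class TestSpacingConservation:
    def test_pair_counts_match_brute_force(self, rng):
        width = 6
        a_matches = [Match("chr1", int(p), int(p) + width,
                           rng.choice(["+", "-"]), 5.0, "a")
                     for p in rng.choice(5000, size=80, replace=False)]
        b_matches = [Match("chr1", int(p), int(p) + width,
                           rng.choice(["+", "-"]), 5.0, "b")
                     for p in rng.choice(5000, size=80, replace=False)]
        table = pair_spacing_counts(MatchSet(a_matches, 0.0),
                                    MatchSet(b_matches, 0.0), max_gap=30)
        oracle = {}
        for a in a_matches:
            for b in b_matches:
                gap = b.start - a.end
                if 0 <= gap < 30:
                    key = (gap, ("F" if a.strand == "+" else "R") +
                           ("F" if b.strand == "+" else "R"))
                    oracle[key] = oracle.get(key, 0) + 1
        assert table == oracle

    def test_uniform_low_scores_give_zero_conserved_pairs(self):
        a = _spaced_matches(20, 6, start=0, step=40, name="a")
        b = _spaced_matches(20, 6, start=10, step=40, name="b")
        track = _track_from_array(np.zeros(1000))
        table = pair_spacing_counts(MatchSet(a, 0.0), MatchSet(b, 0.0),
                                    track, thresholds=(1.0, 1.0))
        assert table == {}

    def test_planted_conserved_gap_is_significant(self, rng):
        width = 6
        gap = 5
        a, b, scores = [], [], np.zeros(20000)
        pos = 0
        for i in range(60):
            a.append(Match("chr1", pos, pos + width, "+", 5.0, "a"))
            b.append(Match("chr1", pos + width + gap,
                           pos + 2 * width + gap, "+", 5.0, "b"))
            scores[pos:pos + 2 * width + gap] = 3.0  # conserved pair
            pos += 50
        track = _track_from_array(scores)
        # the empirical p floor is 1/(n_null+1); FDR 0.01 over ~30 gap cells
        # needs a few thousand null pairings
        controls = []
        for seed in range(4000):
            r = np.random.default_rng(seed)
            ctrl_b = [Match("chr1", int(p), int(p) + width, "+", 5.0, "cb")
                      for p in sorted(r.choice(19000, 60, replace=False))]
            controls.append((MatchSet(a, 0.0), MatchSet(ctrl_b, 0.0),
                             (1.0, 1.0)))
        report = spacing_conservation(MatchSet(a, 0.0), MatchSet(b, 0.0),
                                      track, (1.0, 1.0), controls)
        assert (gap, "FF") in report.significant
        assert not any(cell != (gap, "FF") for cell in report.significant)

    def test_empty_match_sets_rejected(self):
        with pytest.raises(ValueError):
            spacing_conservation(MatchSet([], 0.0), MatchSet([], 0.0),
                                 _track_from_array(np.zeros(10)), (0, 0), [])
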