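"""Composite-motif discovery: relative-affinity comparison of pair vs
single-TF selections, IUPAC seed refinement and multinomial PWM construction.

A 10-mer is a composite candidate when its relative affinity in the TF-pair
(CAP-SELEX) library ranks in the top half of that library AND exceeds 1.5x
the better of its two single-TF (HT-SELEX) relative affinities — i.e. the
pair binds sequences that neither TF alone prefers.  Candidates are reduced
to seeds by Hamming-distance-1 dominance, refined into degenerate IUPAC
seeds from the flanking base composition of seed-matching reads, and turned
into position count matrices with the multinomial model: the column at
position i counts reads that match the seed everywhere except position i
(which is left free), so the interrogated base never contributes to the
alignment and seed bias is eliminated.  Column totals therefore differ
between positions by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .selex_io import DNA, IUPAC, IUPAC_INV, Motif, ReadPool
from .kmer_engine import (AffinityTable, MarkovBackground, count_kmers,
                          decode_kmer, encode_kmer, hamming_distance,
                          relative_affinity)

logger = logging.getLogger("coopselex")

DEFAULT_MIN_SEED_COUNT = 50   # refinement floor: seed must match this often
MAX_SEED_LENGTH = 24


@dataclass
class CompositeCandidate:
    tenmer: str
    ka_cap: float
    ka_ht_best: float
    rank_cap: float   # fraction of observed CAP k-mers with higher K_a; 0 = top

    @property
    def ratio(self) -> float:
        return self.ka_cap / self.ka_ht_best


@dataclass
class IUPACSeed:
    symbols: str
    multinomial_level: int = 1

    def __post_init__(self) -> None:
        if len(self.symbols) < 4:
            raise ValueError("seed shorter than 4")
        bad = [c for c in self.symbols if c not in IUPAC]
        if bad:
            raise ValueError(f"non-IUPAC symbols {bad}")
        n_informative = sum(1 for c in self.symbols if c != "N")
        if n_informative * 2 < len(self.symbols):
            raise ValueError("more than half of the seed is N")

    def __len__(self) -> int:
        return len(self.symbols)

    def allowed_sets(self) -> list[frozenset]:
        return [frozenset(IUPAC[c]) for c in self.symbols]


# ---------------------------------------------------------------------------
# Candidate selection and seeds
# ---------------------------------------------------------------------------

def composite_candidates(aff_cap: AffinityTable, aff_ht1: AffinityTable,
                         aff_ht2: AffinityTable, rank_frac: float = 0.5,
                         ratio_min: float = 1.5,
                         max_candidates: int | None = 500) -> list[CompositeCandidate]:
    """10-mers in the top ``rank_frac`` of the CAP table whose CAP affinity is
    at least ``ratio_min`` times the better single-TF affinity.

    The percentile rank is computed over k-mers with nonzero CAP counts only
    (zero-count k-mers would dominate the denominator at small read counts).
    Returned sorted by CAP affinity, descending; ``max_candidates`` caps the
    list (seed selection is quadratic in its length, and seeds always come
    from the top of the affinity ranking).
    """
    if not (aff_cap.k == aff_ht1.k == aff_ht2.k):
        raise ValueError("affinity tables have mismatched k")
    observed = np.nonzero(aff_cap.counts_array)[0]
    if len(observed) == 0:
        return []
    ka = aff_cap.ka_array[observed]
    order = np.argsort(-ka, kind="stable")
    n = len(observed)
    n_top = int(np.floor(rank_frac * n))
    top_idx = observed[order[:n_top]]
    ht_best = np.maximum(aff_ht1.ka_array[top_idx], aff_ht2.ka_array[top_idx])
    ka_top = aff_cap.ka_array[top_idx]
    passing = np.nonzero(ka_top >= ratio_min * ht_best)[0]
    out = [CompositeCandidate(tenmer=decode_kmer(int(top_idx[i]), aff_cap.k),
                              ka_cap=float(ka_top[i]),
                              ka_ht_best=float(ht_best[i]),
                              rank_cap=int(i) / n)
           for i in passing]
    if max_candidates is not None and len(out) > max_candidates:
        out = out[:max_candidates]
    return out


def select_seeds(candidates: list[CompositeCandidate]) -> list[CompositeCandidate]:
    """Candidates not dominated by a higher-affinity candidate within Hamming
    distance 1 (ties broken lexicographically).  Order-independent."""
    if not candidates:
        raise ValueError("empty candidate list")
    seeds = []
    for cand in candidates:
        dominated = False
        for other in candidates:
            if other is cand:
                continue
            if hamming_distance(cand.tenmer, other.tenmer) == 1:
                if (other.ka_cap > cand.ka_cap or
                        (other.ka_cap == cand.ka_cap and
                         other.tenmer < cand.tenmer)):
                    dominated = True
                    break
        if not dominated:
            seeds.append(cand)
    seeds.sort(key=lambda c: (-c.ka_cap, c.tenmer))
    return seeds


# ---------------------------------------------------------------------------
# Seed matching machinery
# ---------------------------------------------------------------------------

def _allowed_matrix(seed_sets: list[frozenset]) -> np.ndarray:
    """(L, 4) boolean: is base b allowed at seed position j."""
    L = len(seed_sets)
    allowed = np.zeros((L, 4), dtype=bool)
    for j, s in enumerate(seed_sets):
        for c in s:
            allowed[j, DNA.index(c)] = True
    return allowed


def _window_mismatches(codes: np.ndarray, allowed: np.ndarray) -> np.ndarray:
    """(n, W) count of seed-disallowed bases per window."""
    L = allowed.shape[0]
    n, Lr = codes.shape
    W = Lr - L + 1
    if W < 1:
        raise ValueError("reads shorter than the seed")
    M = np.zeros((n, W), dtype=np.int16)
    not_allowed = ~allowed
    for j in range(L):
        M += not_allowed[j][codes[:, j:j + W]]
    return M


def _both_strand_codes(pool: ReadPool) -> list[np.ndarray]:
    codes = pool.encoded()
    return [codes, (3 - codes)[:, ::-1]]  # forward, reverse complement


def count_seed_matches(pool: ReadPool, seed, weights=None) -> float:
    """Strand-combined count of exact (IUPAC) seed matches in the pool."""
    seed = _as_seed(seed)
    allowed = _allowed_matrix(seed.allowed_sets())
    total = 0.0
    for codes in _both_strand_codes(pool):
        M = _window_mismatches(codes, allowed)
        hits = (M == 0)
        if weights is None:
            total += hits.sum()
        else:
            total += (hits.sum(axis=1) * np.asarray(weights)).sum()
    return float(total)


def _as_seed(seed) -> IUPACSeed:
    if isinstance(seed, IUPACSeed):
        return seed
    return IUPACSeed(str(seed), multinomial_level=1 if len(str(seed)) <= 10 else 2)


def _position_class_counts(pool: ReadPool, seed: IUPACSeed,
                           weights=None) -> np.ndarray:
    """(4, L) multinomial class counts: counts[b, i] = windows matching the
    seed at every position except i (with one extra mismatch allowed anywhere
    else at multinomial level 2) carrying base b at position i."""
    allowed = _allowed_matrix(seed.allowed_sets())
    budget = 1 if seed.multinomial_level == 2 else 0
    L = allowed.shape[0]
    counts = np.zeros((4, L))
    for codes in _both_strand_codes(pool):
        M = _window_mismatches(codes, allowed)
        n, W = M.shape
        w_read = np.ones(n) if weights is None else np.asarray(weights, float)
        # windows with M mismatches contribute to class(i, base_i) whenever
        # the mismatches outside i number <= budget, i.e. M - mm_i <= budget
        sel = np.nonzero(M <= budget + 1)
        for ri, wi in zip(*sel):
            m = int(M[ri, wi])
            window = codes[ri, wi:wi + L]
            wt = w_read[ri]
            if m <= budget:
                counts[window, np.arange(L)] += wt
            else:  # m == budget + 1: only at mismatched positions
                mism = np.nonzero(~allowed[np.arange(L), window])[0]
                counts[window[mism], mism] += wt
    return counts


# ---------------------------------------------------------------------------
# Seed refinement
# ---------------------------------------------------------------------------

def _degenerate_symbol(freqs: np.ndarray) -> str:
    """IUPAC symbol for a base-frequency vector per the redundancy rule:
    top base if its frequency >= 0.5; otherwise N, unless the 2nd/3rd (or
    3rd/4th) frequency ratio exceeds 2, in which case the code for the two
    (or three) most frequent bases."""
    order = np.argsort(-freqs, kind="stable")
    f = freqs[order]
    if f[0] >= 0.5:
        return DNA[order[0]]
    if f[2] > 0 and f[1] / f[2] > 2 or (f[1] > 0 and f[2] == 0):
        return IUPAC_INV[frozenset(DNA[i] for i in order[:2])]
    if f[3] > 0 and f[2] / f[3] > 2 or (f[2] > 0 and f[3] == 0):
        return IUPAC_INV[frozenset(DNA[i] for i in order[:3])]
    return "N"


def _flank_distribution(pool: ReadPool, seed: IUPACSeed, side: str,
                        weights=None):
    """Weighted base counts one position 5' (side='left') or 3'
    (side='right') of seed matches, in match orientation, plus the Kish
    effective sample size of the contributing matches.  Returns
    (counts, ess); counts is None when no match has that flank."""
    allowed = _allowed_matrix(seed.allowed_sets())
    L = allowed.shape[0]
    dist = np.zeros(4)
    w_sum = w_sq = 0.0
    for codes in _both_strand_codes(pool):
        M = _window_mismatches(codes, allowed)
        n, W = M.shape
        w_read = np.ones(n) if weights is None else np.asarray(weights, float)
        for ri, wi in zip(*np.nonzero(M == 0)):
            pos = wi - 1 if side == "left" else wi + L
            if 0 <= pos < codes.shape[1]:
                w = w_read[ri]
                dist[codes[ri, pos]] += w
                w_sum += w
                w_sq += w * w
    if w_sum <= 0:
        return None, 0.0
    return dist, w_sum * w_sum / w_sq


def refine_seed(pool: ReadPool, seed: str, weights=None,
                min_count: int = DEFAULT_MIN_SEED_COUNT) -> IUPACSeed:
    """Refine a concrete seed into a degenerate IUPAC seed.

    The seed is extended outward while the ratio between the most and least
    frequent bases at the flanking position (over seed-matching reads)
    exceeds 2; positions where the most frequent base falls below 0.5 receive
    a degenerate symbol (N, or the 2-3-base code when the second/third
    frequency ratio exceeds 2).  The multinomial level becomes 2 when the
    final seed is longer than 10 bp.
    """
    current = _as_seed(seed)
    current = IUPACSeed(current.symbols, multinomial_level=1)
    n_matches = count_seed_matches(pool, current, weights)
    if n_matches < min_count:
        raise ValueError(
            f"seed {seed!r} matches only {n_matches:.0f} times (< {min_count})")

    for side in ("left", "right"):
        while len(current) < MAX_SEED_LENGTH:
            dist, ess = _flank_distribution(pool, current, side, weights)
            # the flank rule needs enough *effective* matches: heavily
            # duplicated reads must not masquerade as independent evidence
            if dist is None or ess < min_count:
                break
            freqs = dist / dist.sum()
            fmax, fmin = freqs.max(), freqs.min()
            if fmin > 0 and fmax / fmin <= 2:
                break
            sym = _degenerate_symbol(freqs)
            symbols = sym + current.symbols if side == "left" \
                else current.symbols + sym
            try:
                current = IUPACSeed(symbols, multinomial_level=1)
            except ValueError:   # would become too degenerate: stop extending
                break

    # redundancy pass over all positions using the multinomial distributions
    class_counts = _position_class_counts(pool, current, weights)
    freqs = class_counts / np.maximum(class_counts.sum(axis=0), 1e-12)
    symbols = list(current.symbols)
    for i in range(len(symbols)):
        if freqs[:, i].max() < 0.5:
            symbols[i] = _degenerate_symbol(freqs[:, i])
    final = "".join(symbols)
    level = 2 if len(final) > 10 else 1
    try:
        return IUPACSeed(final, multinomial_level=level)
    except ValueError:
        logger.warning("refined seed too degenerate; keeping %s", current.symbols)
        return IUPACSeed(current.symbols,
                         multinomial_level=2 if len(current) > 10 else 1)


# ---------------------------------------------------------------------------
# Multinomial PCM
# ---------------------------------------------------------------------------

def _pattern_expectation(background: MarkovBackground,
                         allowed_sets: list[frozenset],
                         budget: int) -> float:
    """P(a background window falls in the class defined by ``allowed_sets``
    with at most ``budget`` disallowed positions), by DP over the chain."""
    m = background.order
    L = len(allowed_sets)
    allowed = _allowed_matrix(allowed_sets)
    if L <= m:
        raise ValueError("pattern shorter than the background order + 1")
    # initial states: all assignments of the first m bases
    states = {}  # (context_id, mismatches) -> prob
    for ctx in range(4 ** m):
        mism = 0
        ok = True
        for j in range(m):
            b = (ctx >> (2 * (m - 1 - j))) & 3
            if not allowed[j, b]:
                mism += 1
                if mism > budget:
                    ok = False
                    break
        if ok:
            key = (ctx, mism)
            states[key] = states.get(key, 0.0) + float(background.initial[ctx])
    for j in range(m, L):
        nxt: dict = {}
        for (ctx, mism), p in states.items():
            for b in range(4):
                nm = mism + (0 if allowed[j, b] else 1)
                if nm > budget:
                    continue
                nctx = ((ctx << 2) | b) & (4 ** m - 1) if m > 0 else 0
                tp = p * float(background.transitions[ctx, b])
                key = (nctx, nm)
                nxt[key] = nxt.get(key, 0.0) + tp
        states = nxt
    return float(sum(states.values()))


def multinomial_pcm(pool: ReadPool, seed, background: MarkovBackground | None = None,
                    weights=None, min_matches: int = DEFAULT_MIN_SEED_COUNT,
                    name: str = "") -> Motif:
    """Build a position count matrix from a pool with the multinomial model.

    Column i holds the (background-corrected) counts of windows matching the
    seed with position i free; at multinomial level 2 one extra mismatch is
    allowed elsewhere.  Reads are scanned on both strands.  Background
    correction subtracts the count expected under the cycle-0 Markov model
    for the same sequence class, floors at 0, and adds a pseudocount of 1.
    """
    seed = _as_seed(seed)
    n_exact = count_seed_matches(pool, seed, weights)
    if n_exact < min_matches:
        raise ValueError(
            f"seed {seed.symbols!r} matches only {n_exact:.0f} times "
            f"(< {min_matches})")
    counts = _position_class_counts(pool, seed, weights)
    L = len(seed)
    if background is not None:
        n_windows = pool.n_reads if weights is None else float(np.sum(weights))
        n_windows *= 2 * (pool.read_length - L + 1)
        budget = 1 if seed.multinomial_level == 2 else 0
        sets = seed.allowed_sets()
        expected = np.zeros_like(counts)
        for i in range(L):
            for b, base in enumerate(DNA):
                class_sets = list(sets)
                class_sets[i] = frozenset(base)
                expected[b, i] = n_windows * _pattern_expectation(
                    background, class_sets, budget)
        counts = np.maximum(counts - expected, 0.0)
    counts += 1.0
    zero_cols = np.nonzero(counts.sum(axis=0) <= 4.0)[0]
    if len(zero_cols):
        logger.warning("multinomial_pcm: columns %s have no matches beyond "
                       "pseudocounts", zero_cols.tolist())
    return Motif(counts, name=name or f"pcm-{seed.symbols}", seed=seed.symbols,
                 multinomial_level=seed.multinomial_level)


# ---------------------------------------------------------------------------
# End-to-end orchestration
# ---------------------------------------------------------------------------

def motif_from_pair(cap_pool: ReadPool, aff_ht1: AffinityTable,
                    aff_ht2: AffinityTable, background: MarkovBackground,
                    k: int = 10, rank_frac: float = 0.5, ratio_min: float = 1.5,
                    min_seed_count: int = DEFAULT_MIN_SEED_COUNT,
                    monomer_consensi: tuple[str, str] | None = None,
                    weights=None, max_seeds: int = 5,
                    name_prefix: str = "pair") -> list[Motif]:
    """Full composite-motif pipeline on a selected CAP cycle.

    Orchestrates candidate detection, Hamming-dominance seed selection, seed
    refinement and multinomial PCM construction.  Motifs are ranked primary,
    secondary, ... by their strand-combined seed match counts.  Returns an
    empty list when no 10-mer passes the candidate rules.
    """
    stats = count_kmers(cap_pool, k, weights=weights)
    aff_cap = relative_affinity(stats, background,
                                r=max(cap_pool.cycle, 1))
    candidates = composite_candidates(aff_cap, aff_ht1, aff_ht2,
                                      rank_frac=rank_frac, ratio_min=ratio_min)
    if not candidates:
        return []
    seeds = select_seeds(candidates)[:max_seeds]
    motifs = []
    for cand in seeds:
        try:
            refined = refine_seed(cap_pool, cand.tenmer, weights=weights,
                                  min_count=min_seed_count)
            motif = multinomial_pcm(cap_pool, refined, background=background,
                                    weights=weights, min_matches=min_seed_count)
        except ValueError as exc:
            logger.info("seed %s skipped: %s", cand.tenmer, exc)
            continue
        n_matches = count_seed_matches(cap_pool, refined, weights)
        motif.motif_class = _classify(motif, monomer_consensi)
        motifs.append((n_matches, motif))
    motifs.sort(key=lambda t: -t[0])
    ranks = ["primary", "secondary", "tertiary"]
    out = []
    for i, (n_matches, motif) in enumerate(motifs):
        rank = ranks[i] if i < len(ranks) else f"rank{i + 1}"
        motif.name = f"{name_prefix}-{rank}"
        out.append(motif)
    return out


def _classify(motif: Motif, monomer_consensi) -> str:
    """Heuristic class: 'spacing' when the motif consensus contains both
    monomer consensus strings (either strand) — i.e. it is a concatenation of
    the individual motifs — else 'composite'."""
    if monomer_consensi is None:
        return "composite"
    from .selex_io import revcomp
    consensus = motif.consensus
    found = []
    for mono in monomer_consensi:
        found.append(mono in consensus or revcomp(mono) in consensus)
    return "spacing" if all(found) else "composite"
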