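"""Positional mutual information between paired 4-mer sets: detection of
spacing and orientation preferences of cooperatively bound TF pairs.

Each TF is represented by a characteristic 8-mer (a locally maximal enriched
8-mer from its single-TF experiment).  The 8-mer and its reverse complement
are partitioned into an indexed set of ten 4-mers; for a TF pair, 4-mers of
the two sets are paired in a "forward" and an "inverse" orientation, and for
every non-overlapping pair of read positions the mutual information

    MI(pos1, pos2) = sum over 4-mer pairs of
        P(4merA at pos1 & 4merB at pos2)
        * log2( P(joint) / (P_pos1(4merA) * P_pos2(4merB)) )

is summed over the surviving 4-mer pairs.  Cooperative binding at a preferred
spacing concentrates the top MI cells onto a few (pos2-pos1, pairing) groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .selex_io import ReadPool, revcomp
from .kmer_engine import window_codes, encode_kmer

logger = logging.getLogger("coopselex")

MIN_SEPARATION = 4  # 4-mers must not overlap: pos2 - pos1 >= 4

PAIRINGS = ("forward", "inverse")


@dataclass(frozen=True)
class FourMerSet:
    """The indexed ten 4-mers of an 8-mer and its reverse complement.

    Index 1..5 are the forward windows at offsets 0..4; index 6..10 are the
    reverse-complement windows, index 6 being the reverse complement of 4-mer
    number 5 and index 10 the reverse complement of 4-mer number 1.
    """

    source_8mer: str
    fourmers: tuple  # fourmers[j-1] is the 4-mer with index j, j = 1..10

    def fourmer(self, index: int) -> str:
        return self.fourmers[index - 1]

    def unique(self) -> set[str]:
        return set(self.fourmers)


def build_4mer_sets(eightmer: str) -> FourMerSet:
    if len(eightmer) != 8 or any(c not in "ACGT" for c in eightmer):
        raise ValueError(f"need an ACGT 8-mer, got {eightmer!r}")
    forward = [eightmer[j:j + 4] for j in range(5)]          # indexes 1..5
    reverse = [revcomp(forward[5 - j]) for j in range(1, 6)]  # indexes 6..10
    return FourMerSet(eightmer, tuple(forward + reverse))


def pair_4mer_sets(set_a: FourMerSet, set_b: FourMerSet):
    """Pair the two indexed sets in forward and inverse orientation.

    Forward pairs index j with j; inverse pairs j with 5+j (j<=5) or j-5
    (j>5).  Any 4-mer present in both sets removes every pair containing it
    (such 4-mers carry single-TF signal).  Returns
    ``{"forward": [...], "inverse": [...]}, excluded`` where each pair is a
    (4merA, 4merB) tuple.
    """
    shared = set_a.unique() & set_b.unique()
    pairs = {"forward": [], "inverse": []}
    for j in range(1, 11):
        a = set_a.fourmer(j)
        b = set_b.fourmer(j)
        if a not in shared and b not in shared:
            pairs["forward"].append((a, b))
        j_inv = 5 + j if j <= 5 else j - 5
        b_inv = set_b.fourmer(j_inv)
        if a not in shared and b_inv not in shared:
            pairs["inverse"].append((a, b_inv))
    return pairs, sorted(shared)


@dataclass
class MIMatrix:
    """MI values over non-overlapping position pairs for both pairings.

    ``values[pairing]`` is a (W, W) array over 4-mer start positions, with
    NaN at invalid cells (pos2 - pos1 < 4).  For 40-bp reads each pairing has
    exactly 561 valid cells.
    """

    values: dict[str, np.ndarray]
    n_reads: int
    excluded_4mers: list[str] = field(default_factory=list)

    @property
    def n_positions(self) -> int:
        return self.values[PAIRINGS[0]].shape[0]

    def valid_mask(self) -> np.ndarray:
        W = self.n_positions
        p1, p2 = np.meshgrid(np.arange(W), np.arange(W), indexing="ij")
        return p2 - p1 >= MIN_SEPARATION

    @property
    def n_position_pairs(self) -> int:
        """Valid (pos1, pos2) cells per pairing."""
        return int(self.valid_mask().sum())

    def cells(self):
        """Iterate (pos1, pos2, pairing, MI) over valid cells."""
        mask = self.valid_mask()
        for pairing in PAIRINGS:
            vals = self.values[pairing]
            for p1, p2 in zip(*np.nonzero(mask)):
                yield int(p1), int(p2), pairing, float(vals[p1, p2])


def _occupancy(pool_codes_w: np.ndarray, fourmers) -> dict[str, np.ndarray]:
    """Boolean (n_reads, W) occupancy matrix per distinct 4-mer."""
    return {fm: pool_codes_w == encode_kmer(fm) for fm in set(fourmers)}


def positional_mi(pool: ReadPool, set_a: FourMerSet, set_b: FourMerSet,
                  weights: np.ndarray | None = None) -> MIMatrix:
    """Compute the MI matrix of a selected pool for one pair of 4-mer sets.

    ``weights`` gives per-read multiplicities for pools stored as unique
    reads (the MI is identical to expanding the reads).
    """
    if pool.read_length < 12:
        raise ValueError("read length must be >= 12 (two 4-mers plus gap)")
    pairs, excluded = pair_4mer_sets(set_a, set_b)
    if not pairs["forward"] and not pairs["inverse"]:
        raise ValueError("no surviving 4-mer pairs (identical sets?)")
    if pool.n_reads < 100:
        logger.warning("positional_mi: only %d reads; MI estimates are noisy",
                       pool.n_reads)
    ids = window_codes(pool.encoded(), 4)
    n = pool.n_reads if weights is None else float(np.sum(weights))
    all_fms = {a for ps in pairs.values() for a, _ in ps} | \
              {b for ps in pairs.values() for _, b in ps}
    occ = {fm: (ids == encode_kmer(fm)).astype(np.float64) for fm in all_fms}
    if weights is not None:
        w = np.asarray(weights, dtype=np.float64)[:, None]
        occ_w = {fm: m * w for fm, m in occ.items()}
    else:
        occ_w = occ
    marg = {fm: occ_w[fm].sum(axis=0) / n for fm in all_fms}  # per-position

    W = ids.shape[1]
    mask = np.triu(np.ones((W, W), dtype=bool), k=MIN_SEPARATION)
    values = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for pairing in PAIRINGS:
            mi = np.zeros((W, W))
            for a, b in pairs[pairing]:
                joint = occ_w[a].T @ occ[b] / n   # (W, W) joint probabilities
                denom = np.outer(marg[a], marg[b])
                term = joint * np.log2(joint / denom)
                term[joint == 0] = 0.0            # 0 * log(0/x) := 0
                term[denom == 0] = 0.0
                mi += term
            mi[~mask] = np.nan
            values[pairing] = mi
    return MIMatrix(values=values, n_reads=int(n), excluded_4mers=excluded)


@dataclass
class InteractionCall:
    """Outcome of the top-5% concentration rule on an MI matrix."""

    is_interacting: bool
    top_pairs: list          # (pos1, pos2, pairing, MI), top cells per pairing
    groups: list             # distinct (offset, pairing) combinations
    preferred: tuple | None  # modal (offset, pairing)
    top_frac: float
    max_groups: int


def call_interaction(mi: MIMatrix, top_frac: float = 0.05,
                     max_groups: int = 6) -> InteractionCall:
    """Rank MI cells and call an interaction when the top cells concentrate
    onto fewer than ``max_groups`` distinct (offset = pos2 - pos1, pairing)
    groups.

    Ranking and the concentration test are done within each pairing
    separately (top 5% of 561 cells = 28 cells per pairing for 40-bp reads);
    an interaction is called when either pairing's top cells concentrate.
    A cooperative arrangement registers in exactly one pairing — the other
    pairing carries only noise spread over many offsets — so pooling both
    pairings' top cells into one group count would mask every real signal.
    ``top_pairs`` is the union of both pairings' top cells (56 for 40-bp
    reads); ``groups`` are the distinct (offset, pairing) combinations of the
    calling pairing (of the more concentrated pairing when neither calls).
    Top cells with MI <= 0 disqualify a pairing: a degenerate
    (zero-information) matrix carries no spacing signal.
    """
    mask = mi.valid_mask()
    top: list[tuple] = []
    per_pairing: dict[str, dict] = {}
    for pairing in PAIRINGS:
        vals = mi.values[pairing]
        cells = [(float(vals[p1, p2]), int(p1), int(p2))
                 for p1, p2 in zip(*np.nonzero(mask))]
        cells.sort(key=lambda t: (-t[0], t[1], t[2]))
        n_top = math.floor(top_frac * len(cells))
        top_cells = [(p1, p2, pairing, v) for v, p1, p2 in cells[:n_top]]
        top.extend(top_cells)
        groups = sorted({(p2 - p1, pairing) for p1, p2, pairing, _ in top_cells})
        degenerate = any(v <= 0 for _, _, _, v in top_cells)
        per_pairing[pairing] = {
            "cells": top_cells, "groups": groups,
            "calls": (not degenerate) and len(groups) < max_groups,
        }
    def _group_stats(cells):
        stats: dict[tuple, list] = {}
        for p1, p2, pairing, v in cells:
            g = (p2 - p1, pairing)
            entry = stats.setdefault(g, [0, 0.0, -np.inf])
            entry[0] += 1
            entry[1] += max(v, 0.0)
            entry[2] = max(entry[2], v)
        return stats

    for pairing in PAIRINGS:
        per_pairing[pairing]["stats"] = _group_stats(per_pairing[pairing]["cells"])

    def _concentration(pairing):
        stats = per_pairing[pairing]["stats"]
        if not stats:
            return (0, 0.0)
        g = max(stats.values(), key=lambda e: (e[0], e[1]))
        return (g[0], g[1])

    calling = [p for p in PAIRINGS if per_pairing[p]["calls"]]
    if calling:
        best_pairing = min(calling,
                           key=lambda p: len(per_pairing[p]["groups"]))
    else:
        # no pairing concentrates under the strict rule: report the pairing
        # whose top cells agree most on one (offset, pairing) group, so
        # `preferred` tracks the dominant arrangement rather than the single
        # noisiest cell
        best_pairing = max(PAIRINGS, key=_concentration)
    is_interacting = bool(calling)
    groups = per_pairing[best_pairing]["groups"]

    preferred = None
    stats = per_pairing[best_pairing]["stats"]
    if stats:
        # modal group; ties by higher summed MI, smaller offset, forward first
        preferred = min(
            stats,
            key=lambda g: (-stats[g][0], -stats[g][1], g[0],
                           PAIRINGS.index(g[1])))
    return InteractionCall(is_interacting=is_interacting, top_pairs=top,
                           groups=groups, preferred=preferred,
                           top_frac=top_frac, max_groups=max_groups)


def spacing_profile(calls_and_matrices) -> dict[int, float]:
    """Average MI by 8-mer gap across interacting TF pairs.

    Input is a list of (InteractionCall, MIMatrix).  For each interacting
    pair, valid cells of both pairings are grouped by offset = pos2 - pos1
    and averaged; profiles are then averaged across pairs.  Offsets are
    reported as gaps between the characteristic 8-mers, gap = offset - 8
    (negative gaps mean overlapping 8-mers and are retained).
    """
    profiles: list[dict[int, float]] = []
    for call, mi in calls_and_matrices:
        if not call.is_interacting:
            continue
        mask = mi.valid_mask()
        per_offset: dict[int, list] = {}
        for pairing in PAIRINGS:
            vals = mi.values[pairing]
            for p1, p2 in zip(*np.nonzero(mask)):
                per_offset.setdefault(int(p2 - p1), []).append(vals[p1, p2])
        profiles.append({off - 8: float(np.mean(v))
                         for off, v in per_offset.items()})
    if not profiles:
        raise ValueError("no interacting calls to profile")
    gaps = sorted({g for p in profiles for g in p})
    return {g: float(np.mean([p[g] for p in profiles if g in p])) for g in gaps}


# ---------------------------------------------------------------------------
# 6-mer spacing tables (used by the genomic spacing-conservation analysis)
# ---------------------------------------------------------------------------

ORIENTATIONS = ("FF", "FR", "RF", "RR")


def _find_all(read: str, kmer: str) -> list[int]:
    hits, start = [], read.find(kmer)
    while start != -1:
        hits.append(start)
        start = read.find(kmer, start + 1)
    return hits


def _occurrences(read: str, sixmer: str) -> list[tuple[int, str]]:
    """(position, strand) occurrences; palindromes recorded as forward only."""
    rc = revcomp(sixmer)
    occ = [(p, "F") for p in _find_all(read, sixmer)]
    if rc != sixmer:
        occ.extend((p, "R") for p in _find_all(read, rc))
    return occ


def sixmer_spacing_table(pool: ReadPool, sixmer_a: str, sixmer_b: str,
                         max_gap: int = 30,
                         weights: np.ndarray | None = None) -> dict:
    """Counts of co-occurrences of two 6-mers by (gap, orientation).

    For every read, every ordered pair of an A occurrence followed by a B
    occurrence with gap = start_B - (start_A + 6) in [0, max_gap) is counted
    under the orientation label (strand_A, strand_B) in {FF, FR, RF, RR}.
    Palindromic 6-mers are recorded in the forward orientation.
    """
    for s in (sixmer_a, sixmer_b):
        if len(s) != 6 or any(c not in "ACGT" for c in s):
            raise ValueError(f"need an ACGT 6-mer, got {s!r}")
    table: dict[tuple[int, str], int] = {}
    if weights is None:
        weights = np.ones(pool.n_reads, dtype=int)
    for read, w in zip(pool.reads, weights):
        occ_a = _occurrences(read, sixmer_a)
        occ_b = _occurrences(read, sixmer_b)
        for pa, sa in occ_a:
            for pb, sb in occ_b:
                gap = pb - (pa + 6)
                if 0 <= gap < max_gap:
                    key = (gap, sa + sb)
                    table[key] = table.get(key, 0) + int(w)
    return table


def preferred_spacing(table: dict) -> tuple[int, str]:
    """Modal (gap, orientation) of a 6-mer spacing table."""
    if not table:
        raise ValueError("empty spacing table")
    return min(table, key=lambda k: (-table[k], k[0], ORIENTATIONS.index(k[1])))
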