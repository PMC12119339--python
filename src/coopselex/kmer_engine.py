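"""k-mer counting, Markov background modelling and relative-affinity
estimation — the shared numerical substrate of the toolkit.

k-mers are indexed densely: a k-mer maps to an integer in [0, 4**k) with
A,C,G,T -> 0..3 and the first base most significant.  Count tables are numpy
arrays over that index space, which keeps 10-mer tables (4**10 ~ 1e6 entries)
tractable; a dict-style view is available for small k.

The relative affinity of a k-mer is estimated from its frequency in a
selected cycle r relative to the expectation under a Markov background fitted
to the cycle-0 (input) library:

    K_a(k) = ((F_k^r / F_ref^r) / (P0(k) / P0(ref)))**(1/r)

with the reference k-mer being the most abundant k-mer of the selected pool,
so K_a(ref) == 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .selex_io import DNA, ReadPool, revcomp

MAX_K = 12  # memory guard: 4**12 = 16.7M entries


def encode_kmer(kmer: str) -> int:
    code = 0
    for c in kmer:
        code = (code << 2) | DNA.index(c)
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(DNA[code & 3])
        code >>= 2
    return "".join(reversed(out))


def window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer ids of all length-k windows of an (n, L) encoded read matrix."""
    n, L = codes.shape
    if k > L:
        raise ValueError(f"k={k} exceeds read length {L}")
    ids = np.zeros((n, L - k + 1), dtype=np.int64)
    acc = np.zeros(n, dtype=np.int64)
    # rolling polynomial evaluation over base-4 digits
    for j in range(k):
        acc = acc * 4 + codes[:, j]
    ids[:, 0] = acc
    mask = np.int64(4 ** (k - 1))
    for start in range(1, L - k + 1):
        acc = (acc - codes[:, start - 1] * mask) * 4 + codes[:, start + k - 1]
        ids[:, start] = acc
    return ids


def revcomp_codes(ids: np.ndarray, k: int) -> np.ndarray:
    """Vectorised reverse complement of dense k-mer ids."""
    out = np.zeros_like(ids)
    x = ids.copy()
    for _ in range(k):
        out = (out << 2) | (3 - (x & 3))
        x >>= 2
    return out


@dataclass
class KmerStats:
    """Exhaustive overlapping-window k-mer counts of one pool."""

    k: int
    counts_array: np.ndarray  # shape (4**k,), int64
    total_positions: int      # windows scanned (x2 if both strands)
    cycle: int
    both_strands: bool = False
    weights_note: str = ""

    @property
    def counts(self) -> dict[str, int]:
        """Sparse dict view (nonzero entries only); intended for small k."""
        nz = np.nonzero(self.counts_array)[0]
        return {decode_kmer(int(i), self.k): int(self.counts_array[i]) for i in nz}

    def count(self, kmer: str) -> int:
        return int(self.counts_array[encode_kmer(kmer)])

    @property
    def total(self) -> int:
        return int(self.counts_array.sum())


def count_kmers(pool: ReadPool, k: int, both_strands: bool = False,
                weights: np.ndarray | None = None) -> KmerStats:
    """Count every overlapping k-mer window of every read.

    With ``both_strands`` each window contributes its sequence and its reverse
    complement.  ``weights`` multiplies each read's contribution (used for
    pools represented as unique reads plus multiplicities).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > MAX_K:
        raise ValueError(f"k={k} exceeds the k<={MAX_K} memory guard")
    codes = pool.encoded()
    ids = window_codes(codes, k)
    if weights is None:
        flat = ids.ravel()
        counts = np.bincount(flat, minlength=4 ** k)
        if both_strands:
            counts += np.bincount(revcomp_codes(flat, k), minlength=4 ** k)
        total = ids.size * (2 if both_strands else 1)
    else:
        weights = np.asarray(weights, dtype=np.float64)
        w = np.repeat(weights, ids.shape[1])
        counts = np.bincount(ids.ravel(), weights=w, minlength=4 ** k)
        if both_strands:
            counts += np.bincount(revcomp_codes(ids.ravel(), k), weights=w,
                                  minlength=4 ** k)
        total = float(w.sum()) * (2 if both_strands else 1)
    return KmerStats(k=k, counts_array=counts, total_positions=total,
                     cycle=pool.cycle, both_strands=both_strands)


# ---------------------------------------------------------------------------
# Markov background
# ---------------------------------------------------------------------------

@dataclass
class MarkovBackground:
    """Order-m Markov chain over DNA fitted to a cycle-0 library.

    ``initial`` is the distribution over m-mers (estimated from all windows,
    i.e. assuming stationarity); ``transitions`` maps a context id in
    [0, 4**m) to P(base | context).  Both are add-one pseudocounted so every
    probability is positive.
    """

    order: int
    initial: np.ndarray       # shape (4**order,)
    transitions: np.ndarray   # shape (4**order, 4)
    pseudocount: float = 1.0

    def expected_frequency(self, kmer: str) -> float:
        """P0(kmer): probability of observing the k-mer at a fixed position."""
        return float(self.expected_frequency_codes(
            np.array([encode_kmer(kmer)]), len(kmer))[0])

    def expected_frequency_codes(self, ids: np.ndarray, k: int) -> np.ndarray:
        """Vectorised P0 over dense k-mer ids."""
        ids = np.asarray(ids, dtype=np.int64)
        m = self.order
        if k <= m:
            # marginalise the m-mer initial distribution over the suffix
            shift = 2 * (m - k)
            probs = np.zeros(len(ids))
            init = self.initial.reshape(4 ** k, -1).sum(axis=1) if m > k \
                else self.initial
            return init[ids] if m >= k else probs
        # leading m-mer
        lead = ids >> (2 * (k - m))
        p = self.initial[lead].copy() if m > 0 else np.ones(len(ids))
        ctx = lead
        for j in range(m, k):
            base = (ids >> (2 * (k - j - 1))) & 3
            p *= self.transitions[ctx, base]
            ctx = ((ctx << 2) | base) & (4 ** m - 1) if m > 0 else ctx
        return p

    def sample(self, n_reads: int, length: int, rng: np.random.Generator) -> ReadPool:
        """Draw i.i.d. reads from the chain (used by the simulator)."""
        m = self.order
        codes = np.zeros((n_reads, length), dtype=np.int64)
        if m > 0:
            lead = rng.choice(4 ** m, size=n_reads, p=self.initial)
            for j in range(m - 1, -1, -1):
                codes[:, m - 1 - j] = (lead >> (2 * j)) & 3
            ctx = lead
            start = m
        else:
            ctx = np.zeros(n_reads, dtype=np.int64)
            start = 0
        u = rng.random((n_reads, length))
        cum = np.cumsum(self.transitions, axis=1)
        for j in range(start, length):
            codes[:, j] = (u[:, j:j + 1] > cum[ctx]).sum(axis=1)
            if m > 0:
                ctx = ((ctx << 2) | codes[:, j]) & (4 ** m - 1)
        reads = ["".join(DNA[c] for c in row) for row in codes]
        return ReadPool(reads, cycle=0, label="markov-sample")


def fit_markov_background(pool0: ReadPool, order: int = 5,
                          pseudocount: float = 1.0) -> MarkovBackground:
    """Maximum-likelihood transition frequencies with add-one pseudocount.

    Fitted to a cycle-0 (input) pool; the initial m-mer distribution is taken
    from all m-mer windows, not just read starts (stationarity assumption).
    """
    if order >= pool0.read_length:
        raise ValueError("order must be smaller than the read length")
    if order < 0:
        raise ValueError("order must be >= 0")
    if order > 0:
        mstats = count_kmers(pool0, order)
        init = mstats.counts_array.astype(float) + pseudocount
        init /= init.sum()
    else:
        init = np.ones(1)
    m1 = count_kmers(pool0, order + 1)
    trans_counts = m1.counts_array.astype(float).reshape(4 ** order, 4) + pseudocount
    trans = trans_counts / trans_counts.sum(axis=1, keepdims=True)
    return MarkovBackground(order=order, initial=init, transitions=trans,
                            pseudocount=pseudocount)


def uniform_background(order: int = 0) -> MarkovBackground:
    return MarkovBackground(order=order,
                            initial=np.full(4 ** order, 4.0 ** -order),
                            transitions=np.full((4 ** order, 4), 0.25))


# ---------------------------------------------------------------------------
# Relative affinity
# ---------------------------------------------------------------------------

@dataclass
class AffinityTable:
    """Per-k-mer relative affinities K_a with K_a(ref) == 1."""

    k: int
    ka_array: np.ndarray          # shape (4**k,)
    ref_kmer: str
    r: int
    counts_array: np.ndarray = field(repr=False)  # raw selected-cycle counts

    @property
    def K_a(self) -> dict[str, float]:
        """Dict view over k-mers observed in the selected pool."""
        nz = np.nonzero(self.counts_array)[0]
        return {decode_kmer(int(i), self.k): float(self.ka_array[i]) for i in nz}

    def get(self, kmer: str) -> float:
        return float(self.ka_array[encode_kmer(kmer)])

    @property
    def kd_array(self) -> np.ndarray:
        return 1.0 / self.ka_array


def relative_affinity(stats_r: KmerStats, background: MarkovBackground,
                      r: int | None = None,
                      pseudocount: float = 0.5) -> AffinityTable:
    """Estimate K_a for every k-mer from selected-cycle counts.

    A count pseudocount (default 0.5, Jeffreys-like) is added to every k-mer
    before frequency computation so zero-count k-mers get a finite small K_a.
    The reference k-mer is the one with the maximal raw count (ties broken
    lexicographically, i.e. by smallest dense index).
    """
    if r is None:
        r = stats_r.cycle
    if r < 1:
        raise ValueError("selected cycle r must be >= 1")
    counts = stats_r.counts_array
    if counts.sum() == 0:
        raise ValueError("empty k-mer statistics")
    k = stats_r.k
    ref_idx = int(np.argmax(counts))  # argmax returns first (lexicographic) max
    freqs = (counts + pseudocount) / (counts.sum() + pseudocount * len(counts))
    p0 = background.expected_frequency_codes(np.arange(len(counts)), k)
    ratio = (freqs / freqs[ref_idx]) / (p0 / p0[ref_idx])
    ka = ratio ** (1.0 / r)
    ka[ref_idx] = 1.0
    return AffinityTable(k=k, ka_array=ka, ref_kmer=decode_kmer(ref_idx, k),
                         r=r, counts_array=counts)


# ---------------------------------------------------------------------------
# k-mer distances and local maxima
# ---------------------------------------------------------------------------

def hamming_distance(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def huddinge_distance(a: str, b: str) -> int:
    """Minimum over ungapped offsets and strands of (mismatching aligned
    positions + unaligned positions of the longer k-mer).

    Equivalently max(len(a), len(b)) minus the best number of matching
    aligned positions over all offsets of b and revcomp(b) against a.
    """
    if not a or not b:
        raise ValueError("empty k-mer")
    la, lb = len(a), len(b)
    longest = max(la, lb)
    best = 0
    for bb in (b, revcomp(b)):
        for off in range(-(lb - 1), la):
            matches = 0
            for j in range(lb):
                i = off + j
                if 0 <= i < la and a[i] == bb[j]:
                    matches += 1
            best = max(best, matches)
    return longest - best


def _huddinge1_neighbours(kmer: str) -> set[str]:
    """All k-mers at Huddinge distance exactly <=1 from ``kmer`` (same k).

    Distance-1 neighbours of an 8-mer are single substitutions and single-base
    shifts, on either strand; any |offset| >= 2 alignment gives distance >= 2.
    """
    out: set[str] = set()
    for base_seq in (kmer, revcomp(kmer)):
        for i in range(len(base_seq)):
            for c in DNA:
                out.add(base_seq[:i] + c + base_seq[i + 1:])
        for c in DNA:
            out.add(c + base_seq[:-1])  # shift right
            out.add(base_seq[1:] + c)   # shift left
    out.discard(kmer)
    out.discard(revcomp(kmer))
    return out


def local_maxima_8mers(stats_sel: KmerStats, background: MarkovBackground,
                       min_fold: float = 5.0) -> list[str]:
    """8-mers enriched more than ``min_fold`` (strict) over the Markov
    expectation AND more enriched than every 8-mer at Huddinge distance 1.

    Returned sorted by fold enrichment, descending.
    """
    k = stats_sel.k
    counts = stats_sel.counts_array
    total = counts.sum()
    p0 = background.expected_frequency_codes(np.arange(len(counts)), k)
    enrich = (counts / total) / p0
    candidates = np.nonzero(enrich > min_fold)[0]
    result = []
    for idx in candidates:
        kmer = decode_kmer(int(idx), k)
        e = enrich[idx]
        if all(e > enrich[encode_kmer(nb)] for nb in _huddinge1_neighbours(kmer)):
            result.append((float(e), kmer))
    result.sort(key=lambda t: (-t[0], t[1]))
    return [kmer for _, kmer in result]


def export_kmer_table(stats: KmerStats, path,
                      affinity: AffinityTable | None = None,
                      min_count: int = 1) -> None:
    """Tab-separated table (kmer, count, frequency[, K_a])."""
    total = stats.total
    with open(path, "w") as fh:
        header = "kmer\tcount\tfrequency" + ("\tK_a" if affinity else "")
        fh.write(header + "\n")
        for idx in np.nonzero(stats.counts_array >= min_count)[0]:
            kmer = decode_kmer(int(idx), stats.k)
            row = f"{kmer}\t{stats.counts_array[idx]}\t{stats.counts_array[idx]/total:.6g}"
            if affinity is not None:
                row += f"\t{affinity.ka_array[idx]:.6g}"
            fh.write(row + "\n")
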