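"""Thermodynamic SELEX simulator: synthetic ground truth for the toolkit.

The simulator emulates selection of a 40-bp random-region ligand pool by one
TF (HT-SELEX) or by a TF pair purified consecutively (CAP-SELEX).  Binding is
modelled with the standard PWM energy model under mononucleotide
independence: the affinity of a site is the product of the motif's column
frequencies, normalised so the consensus site has affinity 1, and the best
site on either strand dominates the ligand.

For a single-TF model the ligand affinity is the best single-site affinity.
For a TF-pair model the ligand must be bound by both TFs (consecutive
affinity purification discards ligands bound by only one), so the ligand
affinity is the best product a_A * a_B over all non-overlapping placements of
one site per TF; placements realising the planted (gap, orientation)
arrangement are boosted by the cooperativity factor omega.  omega = 1
recovers independent co-binding, omega = 0 forbids the paired arrangement.

Each selection round retains ligand i with probability proportional to
a_i / (a_i + K_ratio) — the equilibrium bound fraction with the free-TF
activity expressed in affinity units — followed by uniform resampling with
replacement back to the pool size (PCR amplification).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .selex_io import DNA, Motif, ReadPool
from .kmer_engine import MarkovBackground

ORIENT_ALIASES = {"FF": "++", "FR": "+-", "RF": "-+", "RR": "--",
                  "++": "++", "+-": "+-", "-+": "-+", "--": "--"}


@dataclass
class SelectionModel:
    """Planted binding landscape for one simulated SELEX experiment.

    Either PWM-based (``motif_a`` alone or with ``motif_b`` plus a
    cooperative planted arrangement) or, for single-TF experiments, an
    explicit per-k-mer affinity table (``affinity_table``) under the
    single-k-mer-dominance assumption: the ligand's affinity is the table
    value of its best window (both strands).
    """

    motif_a: Motif | None = None
    motif_b: Motif | None = None
    cooperativity: float = 1.0       # omega
    gap: int = 0                     # bases between A site end and B site start
    orientation: str = "++"          # strands of the A and B sites, A first
    k_ratio: float = 10.0            # saturation constant in consensus units
    rounds: int = 3
    amplification: str = "uniform"   # uniform | expected | none
    affinity_table: np.ndarray | None = None  # dense over 4**table_k k-mers
    table_k: int | None = None

    def __post_init__(self) -> None:
        if self.cooperativity < 0:
            raise ValueError("cooperativity must be >= 0")
        if self.motif_a is None and self.affinity_table is None:
            raise ValueError("need motif_a or an affinity_table")
        if self.affinity_table is not None and self.table_k is None:
            k = round(np.log(len(self.affinity_table)) / np.log(4))
            if 4 ** k != len(self.affinity_table):
                raise ValueError("affinity table length is not a power of 4")
            self.table_k = int(k)
        self.orientation = ORIENT_ALIASES[self.orientation]


@dataclass
class SimTruth:
    """Reproducible record of a simulation run."""

    seed: int
    n_reads: int
    read_length: int
    rounds: int
    affinities: np.ndarray = field(repr=False)       # per initial read
    planted_best: np.ndarray = field(repr=False)     # read's max is planted arr.
    planted_pos: np.ndarray = field(repr=False)      # A-site start of that arr.
    counts_per_cycle: list = field(default_factory=list, repr=False)


# ---------------------------------------------------------------------------
# Library synthesis
# ---------------------------------------------------------------------------

def simulate_library(n_reads: int, length: int = 40,
                     background: MarkovBackground | None = None,
                     seed: int = 0) -> ReadPool:
    """Draw an i.i.d. cycle-0 pool from a Markov background (uniform if None)."""
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    if background is not None:
        pool = background.sample(n_reads, length, rng)
        pool.label = "sim-cycle0"
        return pool
    codes = rng.integers(0, 4, size=(n_reads, length))
    lut = np.frombuffer(DNA.encode(), dtype=np.uint8)
    flat = lut[codes].tobytes().decode()
    reads = [flat[i * length:(i + 1) * length] for i in range(n_reads)]
    return ReadPool(reads, cycle=0, label="sim-cycle0")


# ---------------------------------------------------------------------------
# Affinity model
# ---------------------------------------------------------------------------

def _window_scores(codes: np.ndarray, motif: Motif) -> np.ndarray:
    """Per-window site affinities of a motif on the + strand of each read,
    normalised so a consensus site scores 1.  Shape (n, L - width + 1)."""
    freq = motif.frequencies
    with np.errstate(divide="ignore"):
        lr = np.log(freq) - np.log(freq.max(axis=0, keepdims=True))
    lr[np.isneginf(lr)] = -40.0  # zero-frequency base: effectively forbidden
    width = motif.length
    n, L = codes.shape
    W = L - width + 1
    if W < 1:
        raise ValueError("read shorter than motif")
    S = np.zeros((n, W))
    for j in range(width):
        S += lr[codes[:, j:j + W], j]
    return np.exp(S)


def _strand_scores(codes: np.ndarray, motif: Motif) -> dict[str, np.ndarray]:
    return {"+": _window_scores(codes, motif),
            "-": _window_scores(codes, motif.reverse_complement())}


def _suffix_max(x: np.ndarray) -> np.ndarray:
    return np.maximum.accumulate(x[:, ::-1], axis=1)[:, ::-1]


def _pair_join_max(sa: np.ndarray, sb: np.ndarray, width_a: int) -> np.ndarray:
    """max over i, j with j >= i + width_a of sa[:, i] * sb[:, j]."""
    n, Wa = sa.shape
    Wb = sb.shape[1]
    suf = _suffix_max(sb)
    best = np.zeros(n)
    for i in range(Wa):
        t = i + width_a
        if t >= Wb:
            break
        np.maximum(best, sa[:, i] * suf[:, t], out=best)
    return best


def pool_affinities(pool: ReadPool, model: SelectionModel,
                    return_truth: bool = False):
    """Vectorised ligand affinities of every read under the selection model."""
    codes = pool.encoded()
    n = codes.shape[0]
    if model.affinity_table is not None:
        from .kmer_engine import revcomp_codes, window_codes
        ids = window_codes(codes, model.table_k)
        table = np.asarray(model.affinity_table, dtype=float)
        vals = np.maximum(table[ids],
                          table[revcomp_codes(ids, model.table_k)])
        aff = vals.max(axis=1)
        if return_truth:
            return aff, np.ones(n, dtype=bool), vals.argmax(axis=1)
        return aff
    sa = _strand_scores(codes, model.motif_a)
    wa = model.motif_a.length
    if model.motif_b is None:
        aff = np.maximum(sa["+"], sa["-"]).max(axis=1)
        if return_truth:
            best = np.maximum(sa["+"], sa["-"])
            return aff, np.ones(n, dtype=bool), best.argmax(axis=1)
        return aff

    sb = _strand_scores(codes, model.motif_b)
    wb = model.motif_b.length
    sa_best = np.maximum(sa["+"], sa["-"])
    sb_best = np.maximum(sb["+"], sb["-"])

    s_a_pl = sa[model.orientation[0]]
    s_b_pl = sb[model.orientation[1]]
    Wa, Wb = s_a_pl.shape[1], s_b_pl.shape[1]
    shift = wa + model.gap  # B-site start minus A-site start at the planted gap
    n_pl = Wa - max(shift + wb - (Wb + wb - 1), 0)
    planted = np.zeros((n, Wa))
    for i in range(Wa):
        j = i + shift
        if 0 <= j < Wb:
            planted[:, i] = s_a_pl[:, i] * s_b_pl[:, j]
    planted_max = planted.max(axis=1)
    planted_arg = planted.argmax(axis=1)

    if model.cooperativity >= 1.0:
        general = np.maximum(_pair_join_max(sa_best, sb_best, wa),
                             _pair_join_max(sb_best, sa_best, wb))
        aff = np.maximum(general, model.cooperativity * planted_max)
    else:
        # paired arrangement down-weighted (forbidden at omega = 0): exclude
        # the exact planted cells from the general maximum, then re-add them
        # scaled by omega.
        general = np.maximum(
            _pair_join_max(sb_best, sa_best, wb),
            _general_excluding_planted(sa, sb, wa, model))
        aff = np.maximum(general, model.cooperativity * planted_max)
    if return_truth:
        is_planted = model.cooperativity * planted_max >= aff - 1e-15
        return aff, is_planted, planted_arg
    return aff


def _general_excluding_planted(sa, sb, width_a, model) -> np.ndarray:
    """A-then-B joint maximum excluding the planted (strand pair, gap) cells."""
    best = np.zeros(sa["+"].shape[0])
    for stra in "+-":
        for strb in "+-":
            A, B = sa[stra], sb[strb]
            if (stra, strb) != (model.orientation[0], model.orientation[1]):
                np.maximum(best, _pair_join_max(A, B, width_a), out=best)
                continue
            suf = _suffix_max(B)
            Wb = B.shape[1]
            for i in range(A.shape[1]):
                t = i + width_a
                jstar = t + model.gap
                if t >= Wb:
                    break
                cand = np.zeros(A.shape[0])
                if jstar + 1 < Wb:
                    cand = suf[:, jstar + 1].copy()
                if jstar > t:  # window [t, jstar-1]
                    np.maximum(cand, B[:, t:min(jstar, Wb)].max(axis=1), out=cand)
                np.maximum(best, A[:, i] * cand, out=best)
    return best


def ligand_affinity(read: str, model: SelectionModel) -> float:
    """Affinity of a single read (convenience wrapper over the pool scorer)."""
    pool = ReadPool([read], cycle=0)
    return float(pool_affinities(pool, model)[0])


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def simulate_selection(pool: ReadPool, model: SelectionModel, seed: int = 0,
                       expand: bool = True):
    """Run ``model.rounds`` selection rounds on a cycle-0 pool.

    Returns (pools, truth) where pools[c-1] is the cycle-c pool.  Since
    selection never mutates reads, affinities are computed once on the unique
    initial reads and each round only updates multiplicities.  With
    ``expand=False`` the returned pools keep the initial read list and carry
    per-read multiplicities in ``truth.counts_per_cycle`` (the weighted and
    expanded representations are statistically identical).
    """
    rng = np.random.default_rng(seed)
    if model.amplification == "expected" and expand:
        expand = False  # fractional multiplicities cannot be expanded
    aff, is_planted, planted_pos = pool_affinities(pool, model, return_truth=True)
    w = aff / (aff + model.k_ratio)
    n = pool.n_reads
    counts = np.ones(n, dtype=np.int64)
    truth = SimTruth(seed=seed, n_reads=n, read_length=pool.read_length,
                     rounds=model.rounds, affinities=aff,
                     planted_best=is_planted, planted_pos=planted_pos)
    pools = []
    for cycle in range(1, model.rounds + 1):
        probs = counts * w
        total = probs.sum()
        if total <= 0:
            raise RuntimeError(f"selection extinction in round {cycle}")
        if model.amplification == "uniform":
            counts = rng.multinomial(n, probs / total).astype(np.int64)
        elif model.amplification == "expected":
            # deterministic amplification: propagate exact expected
            # frequencies (emulates the high-diversity regime of real
            # libraries, whose molecule counts dwarf the sequencing depth,
            # without per-round bottleneck noise)
            counts = n * probs / total
        elif model.amplification == "none":
            counts = rng.binomial(counts, w).astype(np.int64)
            if counts.sum() == 0:
                raise RuntimeError(f"selection extinction in round {cycle}")
        else:
            raise ValueError(f"unknown amplification {model.amplification!r}")
        truth.counts_per_cycle.append(counts.copy())
        if expand:
            idx = np.repeat(np.arange(n), counts)
            reads = [pool.reads[i] for i in idx]
            pools.append(ReadPool(reads, cycle=cycle,
                                  label=f"{pool.label}-cycle{cycle}"))
        else:
            pools.append(ReadPool(list(pool.reads), cycle=cycle,
                                  label=f"{pool.label}-cycle{cycle}"))
    return pools, truth


def table_selection_kmer_stats(n_reads: int, table: np.ndarray, rounds: int = 3,
                               length: int = 40, k_ratio: float = 10.0,
                               seed: int = 0, chunk: int = 200000):
    """Memory-lean selection of a large random library by a planted per-k-mer
    affinity table, returning (cycle-0 stats, cycle-r stats).

    The ligand affinity is the best window's table value on either strand
    (single-k-mer dominance); selection propagates exact expected frequencies
    (weight (a/(a+K))**rounds per read).  Reads are processed in chunks as
    encoded matrices and never materialised as strings, so libraries of
    millions of molecules fit in memory.  Strand-combined k-mer counts.
    """
    from .kmer_engine import KmerStats, revcomp_codes, window_codes
    k = round(np.log(len(table)) / np.log(4))
    if 4 ** k != len(table):
        raise ValueError("affinity table length is not a power of 4")
    table = np.asarray(table, dtype=float)
    rng = np.random.default_rng(seed)
    counts0 = np.zeros(4 ** k)
    counts_r = np.zeros(4 ** k)
    total_w = 0.0
    for start in range(0, n_reads, chunk):
        m = min(chunk, n_reads - start)
        codes = rng.integers(0, 4, size=(m, length), dtype=np.int64)
        ids = window_codes(codes, k)
        rc = revcomp_codes(ids, k)
        a = np.maximum(table[ids], table[rc]).max(axis=1)
        w = (a / (a + k_ratio)) ** rounds
        total_w += w.sum()
        flat = ids.ravel()
        flat_rc = rc.ravel()
        counts0 += np.bincount(flat, minlength=4 ** k)
        counts0 += np.bincount(flat_rc, minlength=4 ** k)
        wrep = np.repeat(w, ids.shape[1])
        counts_r += np.bincount(flat, weights=wrep, minlength=4 ** k)
        counts_r += np.bincount(flat_rc, weights=wrep, minlength=4 ** k)
    windows_per_read = length - k + 1
    scale = n_reads / total_w  # normalise selected pool back to library size
    stats0 = KmerStats(k=k, counts_array=counts0,
                       total_positions=2 * n_reads * windows_per_read,
                       cycle=0, both_strands=True)
    stats_r = KmerStats(k=k, counts_array=counts_r * scale,
                        total_positions=2 * n_reads * windows_per_read,
                        cycle=rounds, both_strands=True)
    return stats0, stats_r


def consensus_motif(consensus: str, major: float = 0.85, name: str = "") -> Motif:
    """Helper: a count motif with ``major`` frequency on the consensus base
    and the remainder split evenly — convenient for planting landscapes."""
    L = len(consensus)
    counts = np.full((4, L), (1 - major) / 3 * 1000)
    for j, c in enumerate(consensus):
        counts[DNA.index(c), j] = major * 1000
    return Motif(counts, name=name or f"consensus-{consensus}")


def heterogeneous_motif(consensus: str, majors, name: str = "",
                        minor_split=(0.5, 0.3, 0.2)) -> Motif:
    """A count motif with per-column consensus frequencies ``majors`` and the
    remaining mass split unevenly over the minor bases.  Column-to-column
    heterogeneity mirrors real TF motifs (variable information content) and
    keeps planted k-mer affinities free of large tie classes."""
    counts = np.zeros((4, len(consensus)))
    minor_split = np.asarray(minor_split, dtype=float)
    for j, (c, mj) in enumerate(zip(consensus, majors)):
        rest = [b for b in range(4) if b != DNA.index(c)]
        counts[DNA.index(c), j] = mj * 1000
        for b, m in zip(rest, minor_split * (1 - mj)):
            counts[b, j] = m * 1000
    return Motif(counts, name=name or f"het-{consensus}")


# ---------------------------------------------------------------------------
# Reference study conditions
# ---------------------------------------------------------------------------
#
# Canonical planted landscapes used by the examples, the test suite and the
# acceptance script.  The characteristic 8-mers are non-self-complementary,
# non-shift-repetitive and mutually distant in every literal shifted
# alignment, as real TF core sites typically are after shared 4-mers are
# excluded; shift-palindromic 8-mers (e.g. a GGATCC core) would place a
# ghost arrangement in the wrong pairing of the positional-MI analysis.

DEMO_EIGHTMER_A = "GCTCCTGT"
DEMO_EIGHTMER_B = "ATGGTTAG"
DEMO_MOTIF_MAJOR = 0.55  # soft columns keep enriched pools diverse at n=5e4
DEMO_COMPOSITE_CONSENSUS = "GACGCTATGG"
DEMO_LANDSCAPE_CONSENSUS = "GCTAACGTGT"
DEMO_LANDSCAPE_MAJORS = (0.70, 0.65, 0.60, 0.675, 0.625,
                         0.65, 0.70, 0.60, 0.675, 0.625)


def demo_pair_model(cooperativity: float = 100.0, gap: int = 5,
                    orientation: str = "++", rounds: int = 3,
                    amplification: str = "uniform") -> SelectionModel:
    """The reference cooperative TF-pair model (two soft 8-column motifs
    with the demo characteristic 8-mers as consensus)."""
    return SelectionModel(
        motif_a=consensus_motif(DEMO_EIGHTMER_A, DEMO_MOTIF_MAJOR, name="tfA"),
        motif_b=consensus_motif(DEMO_EIGHTMER_B, DEMO_MOTIF_MAJOR, name="tfB"),
        cooperativity=cooperativity, gap=gap, orientation=orientation,
        rounds=rounds, amplification=amplification)


def demo_composite_motif() -> Motif:
    """The reference planted composite motif: 10 moderately sharp columns
    (consensus frequency drawn once in 0.75-0.9, Dirichlet minor split),
    reproducible from a fixed generator seed."""
    rng = np.random.default_rng(1)
    consensus = DEMO_COMPOSITE_CONSENSUS
    counts = np.zeros((4, len(consensus)))
    for j, c in enumerate(consensus):
        mj = rng.uniform(0.75, 0.9)
        minors = rng.dirichlet([1, 1, 1]) * (1 - mj)
        rest = [b for b in range(4) if b != DNA.index(c)]
        counts[DNA.index(c), j] = mj * 1000
        for b, m in zip(rest, minors):
            counts[b, j] = m * 1000
    return Motif(counts, name="composite")


def demo_affinity_landscape(k: int = 10) -> np.ndarray:
    """Planted per-k-mer relative-affinity table of the reference soft
    heterogeneous landscape (strand-symmetric, consensus = 1)."""
    from .kmer_engine import revcomp_codes
    motif = heterogeneous_motif(DEMO_LANDSCAPE_CONSENSUS,
                                DEMO_LANDSCAPE_MAJORS, name="landscape")
    freq = motif.frequencies
    ratio = freq / freq.max(axis=0, keepdims=True)
    ids = np.arange(4 ** k, dtype=np.int64)
    s = np.ones(4 ** k)
    x = ids.copy()
    for j in range(k - 1, -1, -1):
        s = s * ratio[x & 3, j]
        x >>= 2
    return np.maximum(s, s[revcomp_codes(ids, k)])
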