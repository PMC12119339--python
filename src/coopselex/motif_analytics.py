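"""Motif-level analytics: gapped k-mer similarity, motif alignment,
core-vs-flank divergence (JSD / Jaccard), consensus score differentials,
minimum-dominating-set reduction and discovery-saturation estimation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import LinearConstraint, milp
from scipy.spatial.distance import squareform

from .selex_io import DNA, Motif

logger = logging.getLogger("coopselex")


# ---------------------------------------------------------------------------
# Gapped k-mer similarity
# ---------------------------------------------------------------------------
#
# A motif is summarised by the vector of expected occurrence counts of every
# gapped k-mer — a k-mer with at most one internal gap of length <= max_gap —
# across all windows fully contained in the motif, under the motif's
# column-independent frequency model.  The similarity of two motifs is the
# cosine of their vectors, strand-symmetrised by averaging the forward and
# reverse-complement vectors.  Inner products factorise over columns,
#     <vA, vB> = sum over gap configs, offset pairs of
#                prod_j <colA(oA + pos_j), colB(oB + pos_j)>,
# so the (4**k)-dimensional vectors are never materialised.

def _gap_configs(k: int, max_gap: int):
    yield tuple(range(k))  # ungapped
    for g in range(1, k):
        for ell in range(1, max_gap + 1):
            yield tuple(j + (ell if j >= g else 0) for j in range(k))


def _config_views(freq: np.ndarray, span: int) -> list[np.ndarray]:
    """Column matrices for each valid window of ``span`` columns; the motif
    is padded with uniform columns when shorter than the span."""
    L = freq.shape[1]
    if L < span:
        pad = span - L
        left = pad // 2
        cols = np.concatenate([np.full((4, left), 0.25), freq,
                               np.full((4, pad - left), 0.25)], axis=1)
        return [cols]
    return [freq[:, o:o + span] for o in range(L - span + 1)]


def _vector_inner(freq_a: np.ndarray, freq_b: np.ndarray, k: int,
                  max_gap: int) -> float:
    total = 0.0
    for positions in _gap_configs(k, max_gap):
        span = positions[-1] + 1
        for wa in _config_views(freq_a, span):
            for wb in _config_views(freq_b, span):
                prod = 1.0
                for p in positions:
                    prod *= float(wa[:, p] @ wb[:, p])
                    if prod == 0.0:
                        break
                total += prod
    return total


def gapped_kmer_similarity(motif_a: Motif, motif_b: Motif, k: int = 10,
                           max_gap: int = 5) -> float:
    """Symmetric, strand-symmetric similarity in [0, 1]; 1 for identical
    motifs (and for a motif vs its reverse complement)."""
    fa = motif_a.frequencies
    fb = motif_b.frequencies
    fa_rc = fa[::-1, ::-1]
    fb_rc = fb[::-1, ::-1]

    def sym_inner(x, x_rc, y, y_rc):
        return 0.25 * (_vector_inner(x, y, k, max_gap) +
                       _vector_inner(x, y_rc, k, max_gap) +
                       _vector_inner(x_rc, y, k, max_gap) +
                       _vector_inner(x_rc, y_rc, k, max_gap))

    num = sym_inner(fa, fa_rc, fb, fb_rc)
    na = sym_inner(fa, fa_rc, fa, fa_rc)
    nb = sym_inner(fb, fb_rc, fb, fb_rc)
    if na <= 0 or nb <= 0:
        return 0.0
    return float(min(num / np.sqrt(na * nb), 1.0))


# ---------------------------------------------------------------------------
# Motif alignment and core/flank divergence
# ---------------------------------------------------------------------------

def jensen_shannon_divergence(p, q) -> float:
    """Base-2 JSD between two base distributions; in [0, 1] bits."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    m = 0.5 * (p + q)

    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


@dataclass
class MotifAlignment:
    """Ungapped alignment of a monomer motif onto a composite motif."""

    offset: int           # composite column where oriented monomer column 0 sits
    orientation: str      # same | revcomp
    score: float          # summed per-column similarity (1 - JSD)
    overlap: tuple        # (composite start, composite end), half-open

    @property
    def overlap_length(self) -> int:
        return self.overlap[1] - self.overlap[0]


def align_motifs(monomer: Motif, composite: Motif,
                 min_overlap: int = 4) -> MotifAlignment:
    """Best ungapped offset/orientation maximising the summed per-column
    similarity 1 - JSD; ties broken by smaller |offset|, same strand first."""
    fc = composite.frequencies
    Lc, Lm = composite.length, monomer.length
    best = None
    for orientation in ("same", "revcomp"):
        fm = monomer.frequencies if orientation == "same" \
            else monomer.frequencies[::-1, ::-1]
        for offset in range(-(Lm - min_overlap), Lc - min_overlap + 1):
            start = max(0, offset)
            end = min(Lc, offset + Lm)
            if end - start < min_overlap:
                continue
            score = sum(1.0 - jensen_shannon_divergence(
                fc[:, c], fm[:, c - offset]) for c in range(start, end))
            key = (-score, abs(offset), orientation != "same", offset)
            if best is None or key < best[0]:
                best = (key, MotifAlignment(offset=offset, orientation=orientation,
                                            score=score, overlap=(start, end)))
    if best is None:
        raise ValueError(f"no alignment with overlap >= {min_overlap}")
    return best[1]


def _aligned_section(monomer: Motif, aln: MotifAlignment,
                     start: int, end: int) -> np.ndarray:
    fm = monomer.frequencies if aln.orientation == "same" \
        else monomer.frequencies[::-1, ::-1]
    return fm[:, start - aln.offset:end - aln.offset]


def _score_all_kmers(freq: np.ndarray) -> np.ndarray:
    """Affinity (product of frequencies) of every k-mer against a section;
    k-mer index is dense base-4, first base most significant."""
    scores = np.ones(1, dtype=np.float64)
    for j in range(freq.shape[1]):
        scores = np.multiply.outer(scores, freq[:, j]).ravel()
    return scores


def top_kmer_set(freq: np.ndarray, frac_of_max: float = 0.9) -> np.ndarray:
    scores = _score_all_kmers(freq)
    return np.nonzero(scores >= frac_of_max * scores.max())[0]


@dataclass
class DivergenceReport:
    """Divergence of a composite motif's core from the monomer inner flanks."""

    analysable: bool
    overlap: tuple | None = None
    jsd_total_bits: dict = field(default_factory=dict)    # per monomer
    jaccard: dict = field(default_factory=dict)           # per monomer
    distinct_by_jsd: bool | None = None
    distinct_by_jaccard: bool | None = None
    reason: str = ""


def core_flank_divergence(composite: Motif, mono_a: Motif, mono_b: Motif,
                          jsd_threshold: float = 0.5,
                          jaccard_threshold: float = 0.5,
                          jaccard_max_overlap: int = 13,
                          kmer_frac: float = 0.9) -> DivergenceReport:
    """Quantify how distinct the composite core (the region covered by both
    aligned monomers) is from what each individual TF would bind.

    Total JSD above ``jsd_threshold`` bits against either monomer flags the
    core as distinct by JSD; a Jaccard index of near-maximal k-mers below
    ``jaccard_threshold`` against both monomers flags it as distinct by
    Jaccard (Jaccard is only computed when the overlap is shorter than
    ``jaccard_max_overlap`` columns).
    """
    aln_a = align_motifs(mono_a, composite)
    aln_b = align_motifs(mono_b, composite)
    start = max(aln_a.overlap[0], aln_b.overlap[0])
    end = min(aln_a.overlap[1], aln_b.overlap[1])
    if end <= start:
        return DivergenceReport(analysable=False,
                                reason="monomer alignments do not overlap")
    fc = composite.frequencies[:, start:end]
    report = DivergenceReport(analysable=True, overlap=(start, end))
    sections = {"A": _aligned_section(mono_a, aln_a, start, end),
                "B": _aligned_section(mono_b, aln_b, start, end)}
    for label, fm in sections.items():
        report.jsd_total_bits[label] = float(sum(
            jensen_shannon_divergence(fc[:, j], fm[:, j])
            for j in range(end - start)))
    report.distinct_by_jsd = any(v > jsd_threshold
                                 for v in report.jsd_total_bits.values())
    if end - start < jaccard_max_overlap:
        set_c = set(top_kmer_set(fc, kmer_frac).tolist())
        for label, fm in sections.items():
            set_m = set(top_kmer_set(fm, kmer_frac).tolist())
            union = set_c | set_m
            report.jaccard[label] = (len(set_c & set_m) / len(union)
                                     if union else 1.0)
        report.distinct_by_jaccard = all(v < jaccard_threshold
                                         for v in report.jaccard.values())
    return report


def consensus_score_differential(monomer: Motif, composite: Motif,
                                 pseudocount: float = 1.0):
    """(score_own, score_on_composite): the monomer's best natural-log
    log-odds score against its own consensus sequence and against the
    composite consensus.  Off-sequence overhang positions contribute 0
    (background-level)."""
    lo = monomer.log_odds(pseudocount=pseudocount)
    lo_rc = lo[::-1, ::-1]

    def best_score(target: str) -> float:
        codes = [DNA.index(c) for c in target]
        Lt, Lm = len(codes), lo.shape[1]
        best = -np.inf
        for mat in (lo, lo_rc):
            for offset in range(-(Lm - 1), Lt):
                s = sum(mat[codes[offset + j], j]
                        for j in range(Lm) if 0 <= offset + j < Lt)
                best = max(best, s)
        return best

    return best_score(monomer.consensus), best_score(composite.consensus)


# ---------------------------------------------------------------------------
# Dominating set
# ---------------------------------------------------------------------------

def similarity_matrix(motifs: list[Motif], similarity_fn=None, **kwargs) -> np.ndarray:
    if similarity_fn is None:
        similarity_fn = gapped_kmer_similarity
    n = len(motifs)
    S = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        S[i, j] = S[j, i] = similarity_fn(motifs[i], motifs[j], **kwargs)
    return S


def dominating_set(adjacency: np.ndarray, ilp_max_nodes: int = 200):
    """Minimum dominating set of an undirected graph given as a boolean
    adjacency matrix (diagonal ignored).

    Solved exactly as an integer linear program for graphs up to
    ``ilp_max_nodes`` nodes; larger graphs use the greedy 1+ln(Delta)
    approximation.  Returns (sorted node indices, mode) with mode in
    {"ilp", "greedy"}.
    """
    A = np.asarray(adjacency, dtype=bool).copy()
    np.fill_diagonal(A, False)
    n = A.shape[0]
    if n == 0:
        return [], "ilp"
    cover = A | np.eye(n, dtype=bool)  # x_v + sum_{u in N(v)} x_u >= 1
    if n <= ilp_max_nodes:
        res = milp(c=np.ones(n),
                   constraints=LinearConstraint(cover.astype(float), lb=1.0),
                   integrality=np.ones(n), bounds=(0, 1))
        if res.status == 0:
            chosen = sorted(np.nonzero(np.round(res.x) > 0.5)[0].tolist())
            return chosen, "ilp"
        logger.warning("dominating-set ILP failed (%s); falling back to greedy",
                       res.message)
    chosen = []
    uncovered = np.ones(n, dtype=bool)
    while uncovered.any():
        gains = cover[:, uncovered].sum(axis=1)
        v = int(np.argmax(gains))
        chosen.append(v)
        uncovered &= ~cover[v]
    return sorted(chosen), "greedy"


def dominating_set_motifs(motifs: list[Motif], similarity_fn=None,
                          threshold: float = 0.1, **kwargs):
    """Representative motifs: nodes of a minimum dominating set of the motif
    similarity graph (edge when similarity > threshold)."""
    S = similarity_matrix(motifs, similarity_fn, **kwargs)
    idx, mode = dominating_set(S > threshold)
    return [motifs[i] for i in idx], mode


def is_dominating(adjacency: np.ndarray, nodes) -> bool:
    A = np.asarray(adjacency, dtype=bool).copy()
    np.fill_diagonal(A, False)
    cover = A | np.eye(A.shape[0], dtype=bool)
    sel = np.zeros(A.shape[0], dtype=bool)
    sel[list(nodes)] = True
    return bool(cover[:, sel].any(axis=1).all())


# ---------------------------------------------------------------------------
# Discovery saturation
# ---------------------------------------------------------------------------

def sqrt_model(N, A: float, B: float):
    """Discovery model p = A * sqrt(N) + B (clusters found after N pairs)."""
    return A * np.sqrt(N) + B


@dataclass
class SaturationFit:
    A: float
    B: float
    N_total: int
    curve: np.ndarray = field(repr=False)   # (n_points, 2): N, mean clusters
    n_subsamples: int = 0

    @property
    def estimate_total_clusters(self) -> float:
        return float(sqrt_model(self.N_total, self.A, self.B))

    def evaluate(self, N) -> float:
        return float(sqrt_model(N, self.A, self.B))


def discovery_curve(pair_to_cluster: dict, n_subsamples: int = 300,
                    seed: int = 0, grid=None) -> np.ndarray:
    """Mean number of distinct clusters discovered vs number of TF pairs
    sampled (without replacement), averaged over ``n_subsamples`` draws."""
    pairs = sorted(pair_to_cluster)
    clusters = np.array([hash(pair_to_cluster[p]) for p in pairs])
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = np.unique(np.linspace(1, n, 20).astype(int))
    points = []
    for N in grid:
        vals = [len(np.unique(clusters[rng.choice(n, size=int(N), replace=False)]))
                for _ in range(n_subsamples)]
        points.append((int(N), float(np.mean(vals))))
    return np.array(points, dtype=float)


def sqrt_extrapolate(curve: np.ndarray, N_total: int,
                     n_subsamples: int = 0) -> SaturationFit:
    """Least-squares fit of p = A*sqrt(N) + B and extrapolation to N_total."""
    curve = np.asarray(curve, dtype=float)
    if curve.shape[0] < 2:
        raise ValueError("need >= 2 curve points")
    if N_total < curve[:, 0].max():
        raise ValueError("N_total smaller than the largest curve point")
    X = np.column_stack([np.sqrt(curve[:, 0]), np.ones(len(curve))])
    (A, B), *_ = np.linalg.lstsq(X, curve[:, 1], rcond=None)
    return SaturationFit(A=float(A), B=float(B), N_total=int(N_total),
                         curve=curve, n_subsamples=n_subsamples)


def linear_lower_bound(curve: np.ndarray, N_total: int,
                       anchor_N: float = 50000) -> float:
    """Linear extrapolation through the curve point nearest ``anchor_N`` and
    the last point; a lower bound because the discovery curve is concave."""
    curve = np.asarray(curve, dtype=float)
    if curve.shape[0] < 2:
        raise ValueError("need >= 2 curve points")
    i = int(np.argmin(np.abs(curve[:-1, 0] - anchor_N)))
    (x1, y1), (x2, y2) = curve[i], curve[-1]
    if x2 == x1:
        raise ValueError("anchor points coincide")
    slope = (y2 - y1) / (x2 - x1)
    return float(y2 + slope * (N_total - x2))


def ward_cluster_counts(similarity: np.ndarray, thresholds) -> dict:
    """Number of Ward-linkage clusters of a motif similarity matrix at each
    distance threshold, with distance 1 - s."""
    D = 1.0 - np.asarray(similarity, dtype=float)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="ward")
    return {float(t): int(fcluster(Z, t=t, criterion="distance").max())
            for t in thresholds}
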