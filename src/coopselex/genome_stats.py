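"""Genomic statistics: PWM scanning, region-set enrichment (hypergeometric)
and the conservation pipeline with artificial-control-motif nulls.

Enrichment of motif matches in a region subset against a universe is tested
with the one-sided hypergeometric tail and quantified as the relative
frequency fold change log2((k/n)/(m/N)).  Conservation of matches is tested
against matches of artificial control motifs built by recombining the two
halves of the original motif — controls keep the half-site content but break
the composite arrangement — with a per-motif constrained/non-constrained
threshold fitted as a two-component Gaussian mixture on average phyloP
scores.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from sklearn.mixture import GaussianMixture

from .selex_io import DNA, ConservationTrack, Motif, RegionSet
from .motif_analytics import gapped_kmer_similarity

logger = logging.getLogger("coopselex")

SCORE_FLOOR = 2.0  # natural-log-odds floor for PWM matches


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

@dataclass
class Match:
    chrom: str
    start: int
    end: int
    strand: str
    score: float
    motif: str


@dataclass
class MatchSet:
    matches: list
    score_threshold: float
    target_count: int | None = None
    motif_name: str = ""

    def __len__(self) -> int:
        return len(self.matches)

    def __iter__(self):
        return iter(self.matches)

    def by_chrom(self) -> dict[str, list]:
        out: dict[str, list] = {}
        for m in self.matches:
            out.setdefault(m.chrom, []).append(m)
        for v in out.values():
            v.sort(key=lambda m: (m.start, m.end, m.strand))
        return out


def _encode_seq(seq: str):
    buf = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.zeros(len(buf), dtype=np.uint8)
    valid = np.zeros(len(buf), dtype=bool)
    for i, c in enumerate(DNA):
        hit = buf == ord(c)
        codes[hit] = i
        valid |= hit
    return codes, valid


def base_composition(sequences: dict[str, str]) -> np.ndarray:
    counts = np.ones(4)
    for seq in sequences.values():
        codes, valid = _encode_seq(seq)
        counts += np.bincount(codes[valid], minlength=4)
    return counts / counts.sum()


def scan_motif(sequences: dict[str, str], motif: Motif,
               target_matches: int | None = 300000,
               min_score: float = SCORE_FLOOR,
               background: np.ndarray | None = None) -> MatchSet:
    """Log-odds scan of both strands against a background base composition.

    The score threshold is the smallest score that still retains at least
    ``target_matches`` matches, but never below the ``min_score`` floor; when
    fewer matches reach the floor, all floor-passing matches are returned
    with a warning.
    """
    if not sequences:
        raise ValueError("empty sequence set")
    if background is None:
        background = base_composition(sequences)
    lo = motif.log_odds(background)
    width = motif.length
    hits: list[Match] = []
    for strand, mat in (("+", lo), ("-", lo[::-1, ::-1])):
        for chrom, seq in sequences.items():
            if len(seq) < width:
                continue
            codes, valid = _encode_seq(seq)
            W = len(seq) - width + 1
            S = np.zeros(W)
            ok = np.ones(W, dtype=bool)
            for j in range(width):
                S += mat[codes[j:j + W], j]
                ok &= valid[j:j + W]
            S[~ok] = -np.inf
            for pos in np.nonzero(S >= min_score)[0]:
                hits.append(Match(chrom, int(pos), int(pos) + width, strand,
                                  float(S[pos]), motif.name))
    threshold = min_score
    if target_matches is not None and len(hits) > target_matches:
        scores = np.sort([m.score for m in hits])[::-1]
        threshold = float(scores[target_matches - 1])
        hits = [m for m in hits if m.score >= threshold]
    elif target_matches is not None and len(hits) < target_matches:
        logger.warning("scan_motif(%s): only %d matches reach the score "
                       "floor %g (target %d)", motif.name, len(hits),
                       min_score, target_matches)
    hits.sort(key=lambda m: (-m.score, m.chrom, m.start, m.strand))
    return MatchSet(hits, score_threshold=threshold,
                    target_count=target_matches, motif_name=motif.name)


def write_matches_bed(matchset: MatchSet, path) -> None:
    with open(path, "w") as fh:
        for m in matchset:
            fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{m.motif}\t"
                     f"{m.score:.4f}\t{m.strand}\n")


# ---------------------------------------------------------------------------
# Region enrichment
# ---------------------------------------------------------------------------

@dataclass
class ContingencyResult:
    k: int
    n: int
    m: int
    N: int
    log2_fold_change: float
    p_value: float
    direction: str            # enrichment | depletion | none
    enriched: bool = False
    fold_change: float | None = None   # conditional fold change (conservation)
    flags: list = field(default_factory=list)


def _regions_with_match(regions: RegionSet, matches_by_chrom: dict) -> int:
    count = 0
    starts_ends = {c: ([m.start for m in ms], [m.end for m in ms])
                   for c, ms in matches_by_chrom.items()}
    for iv in regions:
        chrom, start, end = iv[0], iv[1], iv[2]
        if chrom not in starts_ends:
            continue
        starts, ends = starts_ends[chrom]
        i = bisect.bisect_left(starts, end)
        # any match with start < end and end > start overlaps
        if any(ends[j] > start for j in range(max(0, i - 64), i)):
            count += 1
    return count


def region_enrichment(matchset: MatchSet, subset: RegionSet,
                      universe: RegionSet, p_threshold: float = 0.01,
                      log2fc_threshold: float = 0.75) -> ContingencyResult:
    """Hypergeometric enrichment/depletion of matches in a region subset.

    k = subset regions with >= 1 match, n = |subset|, m = universe regions
    with >= 1 match, N = |universe|.  The tail is chosen by the sign of the
    log2 fold change (upper for enrichment, lower for depletion; p = 1 at
    exactly 0).
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    ids = {iv[:3] for iv in universe}
    missing = [iv for iv in subset if iv[:3] not in ids]
    if missing:
        logger.warning("region_enrichment: %d subset regions not in universe",
                       len(missing))
    by_chrom = matchset.by_chrom()
    k = _regions_with_match(subset, by_chrom)
    n = len(subset)
    m = _regions_with_match(universe, by_chrom)
    N = len(universe)
    if n == 0 or m == 0:
        log2fc = 0.0
    elif k == 0:
        log2fc = -np.inf
    else:
        log2fc = float(np.log2((k / n) / (m / N)))
    if log2fc > 0:
        direction = "enrichment"
        p = float(sstats.hypergeom.sf(k - 1, N, m, n))
    elif log2fc < 0:
        direction = "depletion"
        p = float(sstats.hypergeom.cdf(k, N, m, n))
    else:
        direction, p = "none", 1.0
    enriched = direction == "enrichment" and p < p_threshold \
        and log2fc > log2fc_threshold
    return ContingencyResult(k=k, n=n, m=m, N=N, log2_fold_change=log2fc,
                             p_value=p, direction=direction, enriched=enriched)


# ---------------------------------------------------------------------------
# Artificial control motifs
# ---------------------------------------------------------------------------

RECOMBINATIONS = ("RL", "L+rcR", "rcL+R")


@dataclass
class ControlMotifSet:
    original: Motif
    controls: list            # (Motif, (split, kind))
    excluded: list            # (Motif, (split, kind), similarity)
    n_duplicates: int = 0

    @property
    def motifs(self) -> list[Motif]:
        return [c for c, _ in self.controls]


def make_control_motifs(motif: Motif, similarity_fn=None,
                        exclude_above: float = 0.1,
                        deduplicate: bool = True, **sim_kwargs) -> ControlMotifSet:
    """Artificial control motifs by half recombination.

    For every split point leaving both halves at least floor(L/3) columns,
    three controls are formed: right+left, left+revcomp(right) and
    revcomp(left)+right.  Controls too similar to the original (similarity
    above ``exclude_above``) are excluded; duplicates (e.g. for palindromic
    motifs) are removed and counted.
    """
    if similarity_fn is None:
        similarity_fn = gapped_kmer_similarity
    L = motif.length
    min_half = L // 3
    if min_half < 1 or L < 2 * min_half or L < 6:
        logger.warning("make_control_motifs: motif %s too short (L=%d)",
                       motif.name, L)
        return ControlMotifSet(motif, [], [])
    counts = motif.counts
    seen = set()
    controls, excluded = [], []
    n_dup = 0
    for split in range(min_half, L - min_half + 1):
        left = counts[:, :split]
        right = counts[:, split:]
        variants = {
            "RL": np.concatenate([right, left], axis=1),
            "L+rcR": np.concatenate([left, right[::-1, ::-1]], axis=1),
            "rcL+R": np.concatenate([left[::-1, ::-1], right], axis=1),
        }
        for kind in RECOMBINATIONS:
            c = variants[kind]
            key = c.round(6).tobytes()
            if deduplicate and key in seen:
                n_dup += 1
                continue
            seen.add(key)
            ctrl = Motif(c.copy(), name=f"{motif.name}-ctrl-{split}-{kind}",
                         motif_class="control")
            prov = (split, kind)
            sim = similarity_fn(motif, ctrl, **sim_kwargs)
            if sim > exclude_above:
                excluded.append((ctrl, prov, float(sim)))
            else:
                controls.append((ctrl, prov))
    return ControlMotifSet(motif, controls, excluded, n_duplicates=n_dup)


# ---------------------------------------------------------------------------
# GMM conservation threshold
# ---------------------------------------------------------------------------

@dataclass
class GMMThreshold:
    threshold: float
    degenerate: bool
    seed: int


def gmm_conservation_threshold(avg_scores, seed: int = 0,
                               n_init: int = 10) -> GMMThreshold:
    """Two-component GMM split of per-match average conservation scores.

    The threshold is the smallest score at which the posterior of the
    higher-mean component exceeds 0.5; 10 random EM initialisations are run
    and the best model kept (equal-complexity models, so best likelihood and
    best BIC coincide).  Degenerate fits fall back to the median, flagged.
    """
    x = np.asarray(avg_scores, dtype=float).reshape(-1, 1)
    if len(x) < 20:
        raise ValueError("need >= 20 scores")
    if np.ptp(x) < 1e-12:
        return GMMThreshold(float(np.median(x)), degenerate=True, seed=seed)
    gmm = GaussianMixture(n_components=2, n_init=n_init, random_state=seed,
                          reg_covar=1e-6)
    try:
        gmm.fit(x)
    except Exception:
        return GMMThreshold(float(np.median(x)), degenerate=True, seed=seed)
    hi = int(np.argmax(gmm.means_.ravel()))
    resp = gmm.predict_proba(x)[:, hi]
    if resp.max() < 0.5 or resp.min() > 0.5:
        return GMMThreshold(float(np.median(x)), degenerate=True, seed=seed)
    grid = np.linspace(float(x.min()), float(x.max()), 2001).reshape(-1, 1)
    post = gmm.predict_proba(grid)[:, hi]
    above = np.nonzero(post > 0.5)[0]
    if len(above) == 0:
        return GMMThreshold(float(np.median(x)), degenerate=True, seed=seed)
    return GMMThreshold(float(grid[above[0], 0]), degenerate=False, seed=seed)


# ---------------------------------------------------------------------------
# Conserved-match testing
# ---------------------------------------------------------------------------

def _filter_excluded(matches, exclude: RegionSet | None):
    if exclude is None:
        return list(matches)
    by_chrom: dict[str, list] = {}
    for iv in exclude:
        by_chrom.setdefault(iv[0], []).append((iv[1], iv[2]))
    out = []
    for m in matches:
        ivs = by_chrom.get(m.chrom, ())
        if not any(s < m.end and m.start < e for s, e in ivs):
            out.append(m)
    return out


def select_top_nonoverlapping(matches, top_n: int):
    """Greedy selection of the highest-scoring mutually non-overlapping
    matches (both strands share the genomic footprint)."""
    kept = []
    occupied: dict[str, list] = {}   # chrom -> sorted list of (start, end)
    for m in sorted(matches, key=lambda m: (-m.score, m.chrom, m.start, m.strand)):
        ivs = occupied.setdefault(m.chrom, [])
        i = bisect.bisect_left(ivs, (m.start, m.end))
        clash = (i > 0 and ivs[i - 1][1] > m.start) or \
                (i < len(ivs) and ivs[i][0] < m.end)
        if clash:
            continue
        ivs.insert(i, (m.start, m.end))
        kept.append(m)
        if len(kept) == top_n:
            break
    return kept


def mean_track_score(track: ConservationTrack, m) -> float:
    return track.mean_score(m.chrom, m.start, m.end)


def conserved_match_test(true_matches: MatchSet, control_matches: MatchSet,
                         track: ConservationTrack, top_n: int = 10000,
                         threshold: float | None = None,
                         exclude_regions: RegionSet | None = None,
                         gmm_seed: int = 0) -> ContingencyResult:
    """Is the true motif's match set more conserved than control matches?

    True and control matches are merged, the ``top_n`` highest-scoring
    non-overlapping matches are selected, and a match is conserved when its
    average per-base score exceeds the motif-specific GMM threshold (fitted
    on the true matches overlapping the constrained-base mask unless a
    threshold is supplied).  One-sided Fisher's exact test (upper tail) on
    the true/control x conserved/other table; the effect size is the
    conditional frequency fold change (k/n) / ((m-k)/(N-n)).
    """
    flags: list[str] = []
    true_list = _filter_excluded(true_matches, exclude_regions)
    ctrl_list = _filter_excluded(control_matches, exclude_regions)
    if threshold is None:
        masked = [m for m in true_list
                  if track.overlaps_mask(m.chrom, m.start, m.end)]
        scores = [mean_track_score(track, m) for m in masked]
        if len(scores) < 20:
            raise ValueError("too few mask-overlapping true matches for the GMM")
        g = gmm_conservation_threshold(scores, seed=gmm_seed)
        threshold = g.threshold
        if g.degenerate:
            flags.append("gmm-degenerate")
    tagged = [(m, True) for m in true_list] + [(m, False) for m in ctrl_list]
    order = select_top_nonoverlapping([m for m, _ in tagged], len(tagged))
    is_true = {id(m): t for m, t in tagged}
    selected = order[:top_n]
    if len(selected) < top_n:
        flags.append(f"only-{len(selected)}-nonoverlapping-matches")
    N = len(selected)
    n = sum(1 for m in selected if is_true[id(m)])
    conserved = [mean_track_score(track, m) > threshold for m in selected]
    k = sum(1 for m, c in zip(selected, conserved) if c and is_true[id(m)])
    m_tot = sum(conserved)
    p = float(sstats.hypergeom.sf(k - 1, N, m_tot, n)) if n else 1.0
    if n and N > n and (m_tot - k) > 0:
        fold = (k / n) / ((m_tot - k) / (N - n))
    elif k > 0:
        fold = np.inf
    else:
        fold = 0.0
    log2fc = float(np.log2(fold)) if 0 < fold < np.inf else \
        (np.inf if fold == np.inf else -np.inf)
    return ContingencyResult(k=k, n=n, m=m_tot, N=N,
                             log2_fold_change=log2fc, p_value=p,
                             direction="enrichment", fold_change=float(fold)
                             if fold != np.inf else np.inf, flags=flags)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down FWER adjustment (monotone, >= raw p)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    nvals = len(p)
    for rank, idx in enumerate(order):
        running = max(running, (nvals - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg FDR q-values."""
    p = np.asarray(p_values, dtype=float)
    nvals = len(p)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 1.0
    for rank in range(nvals - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * nvals / (rank + 1))
        adj[idx] = running
    return adj


# ---------------------------------------------------------------------------
# Half-site conservation correlation
# ---------------------------------------------------------------------------

@dataclass
class HalfsiteResult:
    q_value: float
    significant: bool
    n_pairs_tested: int
    null_mean: float
    null_sd: float
    q_matrix: np.ndarray = field(repr=False, default=None)


def _score_matrix(matches, track: ConservationTrack, width: int) -> np.ndarray:
    rows = []
    for m in matches:
        if m.end - m.start != width:
            continue
        vec = [track.score(m.chrom, p) for p in range(m.start, m.end)]
        if m.strand == "-":
            vec = vec[::-1]
        rows.append(vec)
    return np.asarray(rows, dtype=float)


def halfsite_correlation(matches, track: ConservationTrack, half_split: int,
                         control_matches=None, min_matches: int = 100,
                         alpha: float = 0.05) -> HalfsiteResult:
    """Does conservation of one half-site predict conservation of the other?

    Pearson correlations of per-base scores across matches are computed for
    every position pair; a Gaussian null is fitted to the corresponding
    correlations in control-motif matches; one-sided p-values are
    BH-adjusted and the minimum q over the inter-half block (lower triangle
    convention: half-1 position i paired with half-2 position j where
    i > j - half_split) is reported.
    """
    matches = list(matches)
    if not matches:
        raise ValueError("no matches")
    width = matches[0].end - matches[0].start
    if not (0 < half_split < width):
        raise ValueError("half_split must be inside the motif")
    X = _score_matrix(matches, track, width)
    if X.shape[0] < min_matches:
        raise ValueError(f"need >= {min_matches} matches, got {X.shape[0]}")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    if control_matches is None:
        raise ValueError("control matches required for the empirical null")
    Xc = _score_matrix(control_matches, track, width)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr_c = np.corrcoef(Xc, rowvar=False)
    tri = np.tril_indices(width, k=-1)
    null_vals = corr_c[tri]
    null_vals = null_vals[np.isfinite(null_vals)]
    if len(null_vals) < 3:
        raise ValueError("control correlations degenerate")
    mu, sd = float(np.mean(null_vals)), float(np.std(null_vals, ddof=1))
    sd = max(sd, 1e-12)
    pairs = [(i, j) for i in range(width) for j in range(i + 1, width)]
    pvals, valid_pairs = [], []
    for i, j in pairs:
        r = corr[i, j]
        if not np.isfinite(r):
            logger.info("halfsite_correlation: constant column pair (%d,%d) "
                        "skipped", i, j)
            continue
        pvals.append(float(sstats.norm.sf(r, loc=mu, scale=sd)))
        valid_pairs.append((i, j))
    q = bh_adjust(pvals)
    qmat = np.full((width, width), np.nan)
    for (i, j), qv in zip(valid_pairs, q):
        qmat[i, j] = qmat[j, i] = qv
    inter = [qv for (i, j), qv in zip(valid_pairs, q)
             if i < half_split <= j and i > j - half_split]
    if not inter:   # fall back to the whole inter-half block
        inter = [qv for (i, j), qv in zip(valid_pairs, q)
                 if i < half_split <= j]
    if not inter:
        raise ValueError("no valid inter-half position pairs")
    qmin = float(min(inter))
    return HalfsiteResult(q_value=qmin, significant=qmin < alpha,
                          n_pairs_tested=len(valid_pairs), null_mean=mu,
                          null_sd=sd, q_matrix=qmat)


# ---------------------------------------------------------------------------
# Spacing conservation
# ---------------------------------------------------------------------------

def pair_spacing_counts(matches_a: MatchSet, matches_b: MatchSet,
                        track: ConservationTrack | None = None,
                        thresholds: tuple | None = None,
                        max_gap: int = 30) -> dict:
    """Counts of A-match/B-match pairs by (gap, orientation).

    A pair is an A match followed by a B match on the same sequence with
    gap = start_B - end_A in [0, max_gap); the orientation label combines
    the two strands (F = '+').  With a track and per-motif thresholds, only
    pairs in which both matches are conserved are counted.
    """
    table: dict[tuple, int] = {}
    by_b = matches_b.by_chrom()
    for chrom, a_list in matches_a.by_chrom().items():
        b_list = by_b.get(chrom, [])
        b_starts = [b.start for b in b_list]
        for a in a_list:
            lo = bisect.bisect_left(b_starts, a.end)
            hi = bisect.bisect_left(b_starts, a.end + max_gap)
            for b in b_list[lo:hi]:
                gap = b.start - a.end
                if not (0 <= gap < max_gap):
                    continue
                if track is not None and thresholds is not None:
                    ta, tb = thresholds
                    if not (mean_track_score(track, a) > ta and
                            mean_track_score(track, b) > tb):
                        continue
                orient = ("F" if a.strand == "+" else "R") + \
                         ("F" if b.strand == "+" else "R")
                key = (gap, orient)
                table[key] = table.get(key, 0) + 1
    return table


@dataclass
class SpacingConservationReport:
    observed: dict
    p_values: dict
    q_values: dict
    significant: list
    n_null: int


def spacing_conservation(matches_a: MatchSet, matches_b: MatchSet,
                         track: ConservationTrack, thresholds: tuple,
                         control_pairings: list, max_gap: int = 30,
                         fdr: float = 0.01) -> SpacingConservationReport:
    """Which (gap, orientation) cells hold more conserved match pairs than
    expected from control-motif pairings?

    ``control_pairings`` is a list of (MatchSet, MatchSet, (threshA, threshB))
    triples — true-vs-control and control-vs-true pairings — forming the
    empirical null.  One-sided empirical p-values per cell, BH-adjusted at
    the given FDR.
    """
    if len(matches_a) == 0 or len(matches_b) == 0:
        raise ValueError("empty match sets")
    observed = pair_spacing_counts(matches_a, matches_b, track, thresholds,
                                   max_gap)
    null_tables = [pair_spacing_counts(ma, mb, track, th, max_gap)
                   for ma, mb, th in control_pairings]
    n_null = len(null_tables)
    cells = sorted(set(observed) |
                   {c for t in null_tables for c in t})
    pvals = {}
    for cell in cells:
        obs = observed.get(cell, 0)
        exceed = sum(1 for t in null_tables if t.get(cell, 0) >= obs)
        pvals[cell] = (1 + exceed) / (1 + n_null) if obs > 0 else 1.0
    qarr = bh_adjust([pvals[c] for c in cells])
    qvals = dict(zip(cells, (float(q) for q in qarr)))
    significant = sorted(c for c in cells if qvals[c] < fdr
                         and observed.get(c, 0) > 0)
    return SpacingConservationReport(observed=observed, p_values=pvals,
                                     q_values=qvals, significant=significant,
                                     n_null=n_null)
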