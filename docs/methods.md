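# Methods

`coopselex` implements the computational core of a CAP-SELEX screen for
DNA-mediated transcription-factor (TF) cooperativity: detection of
spacing/orientation preferences between two DNA-bound TFs, discovery of
composite motifs whose sequence preference differs from either TF alone,
multinomial position-count-matrix (PCM) construction, motif-set reduction,
genomic enrichment and conservation statistics, and discovery-saturation
estimation.  A thermodynamic SELEX simulator provides the synthetic ground
truth on which every statistical component is calibrated and validated.

## Relative affinity from selection cycles

SELEX is modelled as thermodynamic, affinity-proportional selection.  For
ligand species *i* with dissociation constant K_d(D_i) and free TF activity
[T_free], one selection round transforms pool fractions as

    F'_i / F'_j = ((K_d(D_j) + [T_free]) / (K_d(D_i) + [T_free])) F_i / F_j.

After r rounds, assuming a single k-mer per ligand dominates its selection,
the relative affinity of a k-mer k is estimated from its frequency in the
selected cycle against a background model of the input library:

    K_a(k) = ((F_k^r / F_ref^r) / (P0(k) / P0(ref)))^(1/r),

where ref is the most abundant k-mer of the selected pool (so K_a(ref) = 1
by construction) and P0 is the expected input frequency under a fifth-order
Markov chain fitted to the cycle-0 reads (add-one pseudocount per context;
the initial m-mer distribution is taken from all windows, i.e. assuming
stationarity).  A count pseudocount of 0.5 (Jeffreys-like) is added to every
k-mer before frequency computation so that zero-count k-mers receive a
finite small K_a; the printed estimator is undefined at zero counts and 0.5
keeps ranks stable.  `pseudocount=0` is accepted for tables that already
contain exact expected frequencies (simulator output).

The estimator is rank-consistent in the infinite-library limit: the
expected cycle-1 frequency of a k-mer is F(x) = w(x) + E[(w_other −
w(x))⁺], which is monotone in the planted site strength w(x).  At finite
library sizes, k-mers below the affinity of a typical read's best window
are dominated by "hitchhiking" (they ride along in ligands selected by a
stronger site elsewhere) and their ranks are unreliable; this is a property
of the method, not of the implementation, and it bounds how deep into the
table any validation can reach.

## Spacing and orientation preferences by positional mutual information

Each TF is represented by a characteristic 8-mer — a locally maximal
enriched 8-mer, i.e. one more than fivefold enriched over the background
expectation and more enriched than every 8-mer within Huddinge distance 1.
The 8-mer and its reverse complement are partitioned into ten indexed
4-mers (indexes 1–5: forward windows at offsets 0–4; indexes 6–10: the
reverse-complement windows, index 6 being the reverse complement of window
5).  For a TF pair the two sets are paired "forward" (index j with j) and
"inverse" (j with 5+j or j−5), covering all four strand arrangements of
the two sites; 4-mers present in both sets are excluded because they carry
single-TF signal.

For every non-overlapping position pair (pos2 − pos1 ≥ 4) the mutual
information

    MI(pos1, pos2) = Σ_pairs P(4merA, 4merB) log2 [ P(4merA, 4merB) /
                     (P_pos1(4merA) P_pos2(4merB)) ]

is summed over the surviving 4-mer pairs, with plain empirical
probabilities and 0·log(0/x) taken as 0 (no smoothing — smoothing would
inflate MI).  A 40-bp read yields exactly 561 position pairs per pairing;
the top 5% is 28 cells per pairing.

**Calling rule.**  A cooperative arrangement registers in exactly one
pairing (forward for ++/−− site arrangements, inverse for +−/−+), so the
concentration test — top cells concentrated on fewer than 6 distinct
(offset, pairing) groups — is evaluated per pairing, and an interaction is
called when either pairing concentrates.  Pooling both pairings' top cells
into one group count would add ~28 noise cells spread over ~25 offsets from
the silent pairing and could never call anything.  The `preferred`
arrangement is the modal (offset, pairing) group of the top cells of the
most concentrated pairing (ties: higher summed MI, smaller offset, forward
before inverse).  Top cells with MI ≤ 0 disqualify a pairing: a degenerate
zero-information matrix carries no spacing signal.  `top_frac` and
`max_groups` are exposed as configuration; the <6-groups default is
conservative on desk-scale simulated pools, whose MI matrices are noisier
than deep experimental libraries, so detection power is best measured by
the `preferred` call.

Offsets map to biology as gap = offset − 8, the spacing between the two
characteristic 8-mers; negative gaps (overlapping sites) are retained.

## Composite motif discovery

Relative-affinity tables (k = 10) are computed for the TF-pair selection
and the two single-TF selections against the same cycle-0 background.  A
10-mer is a composite candidate when it ranks in the top 50% of the
pair-selection table (percentile computed over k-mers with nonzero counts)
and its pair-selection affinity is at least 1.5× the better of its two
single-TF affinities.  Candidates are reduced to seeds by Hamming-distance-1
dominance (a candidate is a seed iff no candidate within Hamming distance 1
has higher affinity; ties break lexicographically).

Seeds are refined into degenerate IUPAC seeds: the seed is extended outward
while the most/least frequent base ratio at the flank of seed-matching
reads exceeds 2, and positions where the most frequent base falls below 0.5
receive N, or the 2–3-base IUPAC code when the second/third most frequent
base ratio exceeds 2.  Flank decisions require a minimum *effective* number
of matches (Kish effective sample size ≥ 50, default): with PCR-duplicated
reads, raw weighted counts would overstate the evidence and drive runaway
extension.  Seeds longer than 10 bp switch the counting to multinomial
level 2 (one extra mismatch allowed).

The PCM column at position i counts windows (both strands) matching the
seed everywhere except position i, which is left free — the interrogated
base never contributes to the alignment, eliminating seed bias — so column
totals legitimately differ between positions.  Background correction
subtracts the count expected under the cycle-0 Markov chain for the same
sequence class (computed exactly by dynamic programming over contexts and
the mismatch budget), floors at zero and adds a pseudocount of 1.

## Motif analytics

* **Gapped k-mer similarity** — a motif is summarised by the expected
  occurrence counts of every gapped 10-mer (at most one internal gap of
  ≤ 5) over windows fully inside the motif under its column-independent
  frequency model; similarity is the cosine of two motifs' vectors,
  strand-symmetrised by averaging forward and reverse-complement vectors.
  Inner products factorise over columns, so the 4^10-dimensional vectors
  are never materialised.  Identical motifs (and a motif vs its reverse
  complement) score 1.
* **Alignment** — best ungapped offset/orientation maximising summed
  per-column similarity 1 − JSD (base-2 Jensen–Shannon divergence), minimum
  overlap 4 columns, deterministic tie-breaks.  This replaces an external
  alignment tool; only the best alignment is needed downstream.
* **Core/flank divergence** — the composite core is the region covered by
  both aligned monomers; distinctness is called by total JSD > 0.5 bits
  against either monomer section, and by a Jaccard index < 0.5 against both
  monomer sections of the near-maximal k-mer sets (k-mers scoring ≥ 90% of
  each section's maximum; computed only for overlaps shorter than 13
  columns).
* **Consensus score differential** — the monomer's best natural-log
  log-odds score on its own consensus vs on the composite consensus, over
  all offsets and strands, with overhanging positions contributing 0.
* **Dominating set** — the minimum dominating set of the motif similarity
  graph is solved exactly as an integer linear program (HiGHS via
  `scipy.optimize.milp`) up to a configurable node count, above which the
  standard greedy approximation is used; the mode is reported.
* **Saturation** — the discovery curve (mean clusters found vs pairs
  sampled, 300 subsamples without replacement per grid point) is fitted by
  least squares to p = A·√N + B and evaluated at the total number of TF
  pairs; a linear extrapolation through the point nearest N = 50,000 and
  the last point gives a lower bound (the curve is concave).  Ward
  clustering of 1 − s distances across a threshold grid provides the
  second, clustering-based count.

## Genomic statistics

PWM scanning uses natural-log odds against the scanned sequences' base
composition (pseudocount 1 per count cell), both strands; the score
threshold is the smallest score retaining at least the target number of
matches (default 300,000), never below the floor of 2; when fewer matches
reach the floor, all floor-passing matches are returned with a warning.

Region enrichment uses the one-sided hypergeometric tail (upper when the
relative frequency fold change log2((k/n)/(m/N)) is positive, lower when
negative, p = 1 at exactly 0) with k = subset regions containing a match,
n = subset size, m = universe regions with a match, N = universe size; the
default call requires p < 0.01 and log2 fold change > 0.75.

Conservation testing compares each motif's matches with matches of
artificial control motifs built by half recombination (all split points
leaving both halves ≥ ⌊L/3⌋ columns; right+left, left+revcomp(right),
revcomp(left)+right; controls with similarity > 0.1 to the original are
excluded, duplicates removed).  A per-motif constrained/other threshold is
fitted as a two-component Gaussian mixture (10 random EM initialisations,
best model kept; for equal-complexity models best likelihood and best BIC
coincide) on average per-base scores of mask-overlapping matches; the
threshold is the smallest score at which the posterior of the higher-mean
component exceeds 0.5, with a flagged median fallback for degenerate fits.
True and control matches are merged, the top 10,000 non-overlapping matches
by score are selected greedily, and the true/control × conserved/other
table is tested one-sided (Fisher/hypergeometric upper tail), with the
conditional frequency fold change (k/n)/((m−k)/(N−n)) as effect size and
Holm FWER adjustment across motifs.  Undefined track positions contribute
0 to a match's average score.

Half-site coupling: Pearson correlations of per-base scores across matches
for every position pair ('−'-strand matches reversed into motif
coordinates), an empirical Gaussian null from control-match correlations,
BH adjustment, and the minimum q over the inter-half block (lower-triangle
convention: half-1 position i with half-2 position j where i > j −
half_split) reported; FDR < 0.05 is significant.

Spacing conservation counts A-match/B-match pairs by (gap < 30,
orientation), restricted to pairs where both matches exceed their motif's
conservation threshold, against an empirical null from control pairings;
one-sided empirical p-values, BH at FDR 0.01.  The empirical p floor is
1/(n_null + 1), so the number of control pairings must exceed roughly
100× the number of tested cells for the FDR threshold to be reachable.

## The simulator and what it does (and does not) emulate

`selex_sim` emulates 40-bp random-region ligand pools subjected to
thermodynamic selection.  Binding uses the standard PWM energy model under
mononucleotide independence: site affinity is the product of column
frequencies, normalised so the consensus site is 1; the best site on either
strand dominates a ligand.  For a single TF the ligand affinity is the best
single-site affinity (or, alternatively, the table value of its best window
under an explicit per-k-mer landscape — the estimator's own dominance
assumption).  For a TF pair the ligand must be bound by both TFs
(consecutive affinity purification discards single-bound ligands), so the
affinity is the best product a_A·a_B over non-overlapping placements, with
the planted (gap, orientation) arrangement boosted by the cooperativity
factor ω; ω = 1 recovers independent co-binding and ω = 0 forbids the
paired arrangement.  Selection retains ligand i with probability
proportional to a_i/(a_i + K_ratio) (K_ratio = 10 by default: the
weak-binding, affinity-proportional regime the estimator is derived in),
followed by amplification:

* `uniform` (default) — multinomial resampling with replacement back to the
  pool size each round (stochastic PCR bottleneck);
* `expected` — deterministic propagation of exact expected frequencies,
  emulating real libraries whose molecular diversity (~10^12) dwarfs any
  desk-scale pool, so that no single molecule's descendants dominate;
* `none` — plain Bernoulli survival without re-amplification.

The simulator does not model sequencing errors, PCR sequence bias, bead
capture efficiency or protein concentration titrations.  Consequences for
interpreting passing tests: conclusions transfer to real data only insofar
as real pools are diverse (the `expected` mode is the closer emulation),
selection is approximately affinity-proportional, and ligands carry at most
a handful of competing sites.

### Reference study conditions (scaled-down problem sizes)

All simulation-based calibration uses fixed, package-defined conditions:

* **Spacing/MI studies** — 50,000 reads of 40 bp, three selection rounds
  with stochastic amplification, planted characteristic 8-mers GCTCCTGT
  and ATGGTTAG with column consensus frequency 0.55.  The 8-mers are
  non-self-complementary, non-shift-repetitive and mutually distant in
  every literal shifted alignment, as real core sites effectively are after
  the shared-4-mer exclusion; shift-palindromic 8-mers would place a ghost
  arrangement in the wrong pairing.  Soft columns keep the enriched pool
  diverse enough for MI at this pool size.  Null calibration runs ω = 1
  over 100 seeds; power runs ω = 100 (gap 5) and requires the planted
  arrangement as the preferred call in ≥ 9/10 seeds.  Selected pools are
  deduplicated before the MI computation (PCR-duplicate collapse).
* **Composite discovery** — planted 10-column composite (consensus
  GACGCTATGG, column consensus frequencies 0.75–0.9), monomer landscapes
  from the two 8-mers above; candidate discovery on 200,000-molecule
  libraries after three rounds with `expected` amplification; PCM recovery
  on 400,000-molecule libraries after one round, where the weak-binding
  regime makes the multinomial column distribution equal the planted
  frequencies in expectation (after r rounds the columns sharpen as f^r,
  which is a property of deep-cycle SELEX motifs generally).  Recovery is
  measured as mean per-column total variation < 0.1.
* **Affinity recovery** — a soft heterogeneous 10-column landscape under
  single-k-mer dominance, 4,000,000 molecules of 20 bp (HT-SELEX-style
  short ligands), one selection round with exact expected frequencies.
  One round keeps the enrichment dynamic range equal to the K_a range
  itself; after three rounds it spans K_a³ ≈ 10^6 and no desk-scale depth
  can populate the top percentile of the 10-mer table (the r-th-root
  arithmetic of the estimator is covered by unit tests on constructed
  counts).  Spearman > 0.9 between estimated and planted affinities is
  required on the top 1% of canonical 10-mers.

## Numerical choices and degenerate inputs

* k-mers are densely indexed (A,C,G,T → 0..3, first base most significant);
  tables above k = 12 are refused (memory guard).
* Reference-k-mer and seed ties break lexicographically; alignment ties
  break by smaller |offset|, same strand first; preferred-group ties by
  higher summed MI, then smaller offset, forward before inverse.
* Reads containing non-ACGT characters or deviating from the pool's read
  length are dropped at load and tallied, never corrected.
* Zero-frequency motif cells are handled by context-appropriate
  pseudocounts (0.5 count-space for affinity tables, 1 for log-odds and
  PCM columns); genome scan windows containing non-ACGT bases are skipped.
* All stochastic components accept explicit seeds; simulations are
  bit-reproducible from (configuration, seed).

## Known limitations

* The interaction caller's strict <6-groups rule under-calls on desk-scale
  pools (it was tuned on deep experimental libraries); `preferred` is the
  robust desk-scale readout and `max_groups` is configurable.
* Hitchhiking bounds the resolvable depth of k-mer affinity tables at any
  realistic sequencing depth; ranks below the typical-read floor are noise.
* The composite/spacing motif classification is a string-containment
  heuristic, standing in for expert curation.
* Genome-scale conservation analyses are exercised on synthetic fixtures;
  the toolkit reads real bedGraph/BED/FASTA inputs but ships no downloads.
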