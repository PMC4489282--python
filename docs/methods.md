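# Methods

This note documents the models, parameter choices, and numerical
conventions of `rankrecovery`, and what the synthetic studies do and do
not demonstrate.

## Coordinates and interval arithmetic

All internal coordinates are 0-based half-open (BED convention); 1-based
dialects (GTF) are converted at the reader boundary. Chromosome names are
opaque strings — `chr1` and `1` never alias, since silent aliasing
produces wrong overlaps; an explicit alias table can be applied upstream
if needed. Interval queries run on per-chromosome interval trees and are
oracle-tested against per-base counting.

`overlap_fraction(query, others)` denominates by the **query** length and
counts union coverage (double-covered bases once). In peak-to-CRR mapping
the CRR is the query: a CRR joins the foreground when ≥ `min_fraction`
(default 0.4) of *its* bases lie under input peaks. The alternative
reading — fraction of the peak covered — is not used; with the CRR as the
scored and recovered unit, thresholding on CRR coverage is the
interpretation that makes the foreground a property of the universe
rather than of peak fragmentation (mapping is invariant to splitting a
peak into abutting pieces).

## CRR construction

Feature sets are merged with book-ended coalescing (touching intervals
form one contiguous candidate). Exclusion runs in three steps: (1) drop
merged regions whose insulator-covered fraction ≥ 0.2 or exon-covered
fraction ≥ 0.8 — both thresholds are fractions *of the region's length*,
reading the exon clause parallel to the insulator clause; (2) split
survivors at the boundaries of any remaining insulator/exon overlap,
keeping only sub-intervals free of excluded bases; (3) drop fragments
< 30 bp. Regions shorter than the 1000 bp target are extended:
symmetrically when both flanks are free (deficit split floor/ceil), with
a blocked flank's share redirected to the free flank, stopping at
forbidden intervals and chromosome bounds. Extension does not re-merge
regions that come to touch; post-extension overlap is permitted.
Idempotence of exclusion and exact agreement with a mark-every-base
brute force are tested on randomized toy genomes.

## CRM scoring

The motif scorer is deliberately simple and fully specified: encode the
region over {A,C,G,T,N}; for every window on either strand compute the
summed log₂(p_motif/p_background); windows with positive sums are
candidate hits; the region score is the maximum total weight of any set
of non-overlapping hits (weighted interval scheduling, solved by dynamic
programming). N bases contribute log-odds 0 (background-equal), so
masked sequence is neutral. Sequences shorter than the motif score 0.
An HMM-based CRM scorer could be substituted behind the same
one-function interface; the scorer here is the package's own definition,
chosen so that an exhaustive-enumeration oracle can certify it exactly.

Count matrices convert to probabilities with pseudocount 0.001 per cell,
so log-odds are always finite.

## Cross-genome rank aggregation

Each genome ranks all regions by CRM score (missing orthologs rank after
scored regions and are then *imputed* rank-ratio 1.0 — uninformative
rather than dropped, keeping N constant per region so Q values are
comparable). For sorted ratios b₁ ≤ … ≤ b_N the aggregate is the joint
CDF of uniform order statistics,

    Q = P(U₍₁₎ ≤ b₁, …, U₍N₎ ≤ b_N) = N! · c_N,
    c_0 = 1,  c_k = Σ_{j=1..k} (−1)^{j+1} c_{k−j} b_{k−j+1}^j / j!

the classical alternating recursion. It is exact for N = 1 (Q = r), for
all-ones (Q = 1), and matches the closed form 2ab − a² at N = 2; a
Monte-Carlo sweep (10⁶ draws, N ≤ 5) bounds deviations within sampling
error. The recursion alternates signs and loses accuracy only for N far
beyond the ≤ 10 genomes used here. Combined features (motif + track
rankings merged into one) reuse the same aggregation on rank ratios.

## Ranking and ties

Scores order descending; ties break by a pseudo-random shuffle seeded by
CRC32 of `(seed, feature_id)` — deterministic across runs and platforms,
independent of Python hash randomization. Absent scores rank after all
present scores. Every ranking is validated as a permutation of the CRR
universe. The database persists as a TSV rank matrix plus a JSON sidecar
carrying feature metadata, the seed, and an MD5 checksum of the region
ids; loading verifies the checksum.

## Recovery statistics

- `T_auc = round(total × fraction)`, half-away-from-zero, clamped ≥ 1.
  This rounding reproduces all three published defaults (6115, 4692,
  1364) from their universe sizes.
- AUC = (1/T_auc) · Σ_{x=1..T_auc} rc(x)/F — the mean normalized
  recovery at integer ranks, i.e. a unit-width step integral, so
  AUC ∈ [0,1] exactly and the arithmetic examples are exact. F is the
  foreground size (not min(F, T_auc)).
- NES uses the mean and **population** standard deviation (÷ n) of the
  AUCs of all features in the same database; motifs, open chromatin,
  histone marks, and TF ChIP-seq normalize separately. σ = 0 yields NES
  0 for every feature. By construction the NES set has mean 0 and
  population SD 1.
- The leading edge maximizes rc(x) − (mean(x) + 2·sd(x)) over
  x ≤ T_le; ties resolve to the smallest x; T_le defaults to T_auc
  (exposed as `--le-rank`) since no canonical window exists. A curve
  everywhere below the null band still reports its argmax with
  `positive=False`.
- Report threshold NES > 3.0; quick mode restricts motifs to a named
  subset (data, not code) and requires NES > 4.0.

A note on small databases: population z-scores over n features are
bounded by √(n−1). A 5-track database therefore cannot produce NES > 2
no matter how strong the enrichment; meaningful NES thresholds of 3–4
presuppose databases of dozens to thousands of features. Tests of the
5-track toy database assert top rank at the bound rather than NES > 3.

## Motif annotation

SSD motif distance: minimum over all ungapped offsets and both
orientations of the **mean** per-column sum of squared probability
differences, with unaligned columns compared against the background
distribution (penalizing length mismatch proportionally; mean rather
than sum keeps the metric length-scale-free). Clustering is
average-linkage on the SSD matrix; the cluster count maximizes the
Calinski–Harabasz index over k = 2..min(10, n−1), computed from the
squared-distance matrix alone via SSW = Σ_c (1/2n_c) Σ_{i,j∈c} d²_ij;
k = 1 when n ≤ 2 or the motifs show no scatter (SSW and SSB both ~0).
Perfectly tight non-trivial clusterings (SSW = 0, SSB > 0) score +∞.

Closest-gene assignment uses |region midpoint − TSS| on the region's
chromosome with lexicographic tie-break — the simplest defensible rule;
no gene-body or window logic is applied. Motif→TF lookup orders
candidates direct > orthology > similarity, keeping the best evidence per
TF.

## Synthetic studies

`make_case` generates the complete toy study from one seed: i.i.d.
background genomes (no Markov structure, GC 0.5) with the PWM background
set to the generator composition so log-odds calibration is exact; CRRs
built by the *real* builder from three synthetic feature tracks plus
insulator and exon masks; one informative PWM planted (3 sites per
region, consensus-sampling temperature 0.3) into 21 of 30 foreground
regions (70%) in both genomes; 19 decoy PWMs; 5 tracks with one enriched
(signal 10 ± 1 vs 1 ± 1); a gene annotation with one gene per foreground
region plus decoys; and truth records sufficient to score any leading
edge without re-reading the genome. Regeneration from the same seed is
byte-identical.

Scaled study conditions for the tiny case: 2 × 50 kb chromosomes yield
~175–200 CRRs, so the build targets 400 bp regions (200 × 1000 bp cannot
tile 100 kb) and analyses use an AUC window of 20% of the database.
The window must be at least the foreground size: with F foreground
regions, a window of T < F ranks saturates a perfect ranking's AUC at
(T+1)/(2F), capping the attainable NES regardless of signal. At genome
scale the 0.5% default (rank 6115) vastly exceeds typical foregrounds,
so the scaled analogue keeps T ≥ F. These are fixed properties of the
generator, not tuning knobs.

What passing these studies shows — and does not. The fixtures prove the
statistics recover a strong, consistently planted signal against i.i.d.
background and that every pipeline stage agrees with brute-force
oracles. Real chromatin data differ in ways the generator deliberately
omits: sequence composition structure (repeats, CpG islands), correlated
decoy motifs, peak-shape and replicate structure of real tracks, and
genome-scale universe sizes. Enrichment thresholds that behave well here
can need recalibration on real databases.

## Determinism

All randomness flows from one integer seed: fixture generation, tie
shuffles, and noise draws derive per-purpose seeds from it. Two runs with
the same seed produce byte-identical reports, target BEDs, and SIF
networks (asserted in the suite). `--threads` is accepted for interface
compatibility; computation is single-threaded, so results are trivially
independent of it.

## Known limitations

- The CRM scorer is additive over non-overlapping hits; it has no hit
  count penalty or spacing model, so very long regions accumulate score
  with length. Rankings within a fixed-width universe are unaffected.
- BigWig input is not parsed; coverage scoring takes per-base arrays
  (e.g. loaded from bedGraph).
- The fly-style `upstream_plus_introns` search space requires intron
  intervals in the annotation; a TSS-only table limits gene mode to
  `around_tss`.
- NES is a z-score, not a calibrated p-value; no multiple-testing
  control is applied beyond the threshold.
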