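# Methods

`mitocomp` reimplements, as a tested library + CLI, the comparative
analyses typically reported for a newly sequenced insect mitochondrial
genome: gene-order comparison against the ancestral insect arrangement,
composition/skew/codon-usage statistics, start/stop-codon classification,
control-region repeat analytics, conservation profiling across taxa,
base-compositional heterogeneity testing, and branch-length heterogeneity
summaries. Every stage is verifiable against synthetic data with known
ground truth; no downloads are required.

## Data model and conventions

Coordinates are 0-based half-open internally; tabular annotation files use
the human-friendly 1-based inclusive dialect. Circular genomes encode
origin-spanning features with `end > length`. Strands are J (majority) and
N (minority); an N-strand feature's coding sequence is the reverse
complement of its genome slice. The canonical vocabulary is the 37
mitochondrial genes (13 PCGs, 22 tRNAs with trnL1/trnL2 and trnS1/trnS2
isoacceptors, 2 rRNAs) plus the control region `CR`; a synonym map
normalizes GenBank qualifiers (COX1→COI, 12S→rrnS, …). `N` is a legal
sequence character but never counts as a base in any statistic.

## Gene order

A genome's arrangement is a signed circular permutation: the ordered list
of (gene, strand) pairs, equal up to rotation. Rearrangement is quantified
by the **directed, strand-signed breakpoint (adjacency) distance** — the
number of circular neighbour pairs of one order absent from the other. It
is symmetric, rotation-invariant, zero iff the orders coincide, and
detects the transpositions relevant here (e.g. the derived trnC-before-trnW
state of higher lacewings scores 3 against the ancestral W–C–Y order).
Inversion/DCJ distances are deliberately out of scope. Strand participates
in adjacency identity, so a gene moved across strands breaks its
adjacencies.

Junction accounting reports, for each circularly consecutive feature pair,
the gap (negative = overlap, positive = spacer). The control region is an
order element, but its flanks are excluded from the intergenic-spacer
totals, which count non-coding sequence outside the control region only; a
spacer "region" requires gap ≥ 1.

## Composition and codon usage

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C), computed on the J strand for
the whole genome and control region and on coding strands for gene-class
concatenations; a skew is null when its base pair is absent (reverse
complementation negates both skews — property-tested). Codon statistics
use the invertebrate mitochondrial code (translation table 5: AGR = Ser,
ATA = Met, TGA = Trp; stops TAA/TAG; 62 sense codons). RSCU is
count × family degeneracy / family total over each amino acid's synonymous
family **as defined by table 5** — Ser is 8-fold, Leu 6-fold, Met and Trp
2-fold; families with zero usage report null. Stop codons, including
incomplete terminal T/TA (completed in vivo by polyadenylation), are
excluded from usage and codon-position statistics. Start codons are
canonical iff ATN; stops are read off the annotated 3′ end, with
non-multiple-of-three lengths classified as incomplete.

## Disparity index and Monte-Carlo homogeneity test

For a gap-free pair of aligned sequences, the composition distance is

    Dc = ½ Σ_{x∈{A,C,G,T}} |count_x(a) − count_x(b)|,   Nd = # differing sites,

with Dc ≤ Nd and equality exactly when all differences push composition
the same way. The homogeneity null holds that substitution direction is
symmetric: at each observed differing site, which sequence carries which
of the two observed bases is a fair coin. The **disparity index** is
ID = Dc − E[Dc | null], estimated by Monte-Carlo (default 1000
replicates); the p-value uses the add-one estimator
(1 + #{Dc_rep ≥ Dc_obs})/(R + 1), significance at α = 0.01. Under the
null, ID has mean ≈ 0 and the test is calibrated (measured type-I rate
0.008 at α = 0.01 over 1000 homogeneous 1 kb pairs; p-values pass a KS
uniformity check); against fully directional pairs with Nd = 50 in 1 kb
the power is ~100%.

Replicates are drawn efficiently by pooling differing sites by unordered
base pair: the net directional excess per pool is 2·Binomial(m, ½) − m,
which is distributionally identical to per-site coin flips (the
equivalence is itself unit-tested). Pairwise matrices derive per-pair
random substreams from the user seed and the *sorted* taxon pair, so
results are invariant under taxon-order permutation. Complete deletion
(drop every column containing gap/N in any row) is applied globally before
pairwise testing. Codon-position partitions (PCG123, PCG12, PCG1/2/3, and
PCG12R appending an rRNA alignment) are selected via a per-column
codon-position map. Partitions are ranked best-to-worst by ascending
grand-mean ID. No numeric equivalence with MEGA's disparity-index
normalization is claimed; magnitudes here are calibrated to the
direction-symmetric null, and cross-study comparisons should be
qualitative (rankings, outliers).

## Conservation

%INUC is the percentage of columns where all taxa carry the same
unambiguous base; gap/N columns count in the denominator but are never
identical, matching the "positions" totals conventionally reported for
rRNA alignments. Variable sites have ≥2 distinct bases among gap-free
states; parsimony-informative sites have ≥2 states each in ≥2 taxa.
Structural regions (stems/loops) are accepted as user-supplied column
ranges, never predicted.

## Control-region repeats

Four detectors:

* **Exact motif counting** allows overlapping matches (for AT/AAT-style
  motifs overlap is impossible, so this is observationally equivalent to
  tiling there).
* **Microsatellites**: maximal perfect tandem runs, unit length 1–8 bp,
  ≥2 copies and ≥8 bp span by default; each run is reported once with its
  primitive unit, and overlapping runs are deduplicated longest-first.
* **Spectral tandem finder**: per window (256 bp, step 128), the
  periodogram sums squared DFT magnitudes of the four mean-centred base
  indicator tracks. Reported *peaks* use an auto-calibrated threshold —
  the Bonferroni-corrected upper-tail quantile of a Gamma(3) fit to the
  per-bin power, ≈6–7.5 SD depending on window size — giving ≤~5% of
  random windows a peak (a naive 3 SD rule fires on essentially every
  window once a spectrum has hundreds of bins). Candidate periods for
  verification are proposed more permissively (top-power bins and their
  low-order harmonics, ±1); the selective step is **lag verification**:
  maximal-scoring segments (score = agreement − floor, Kadane-style, so
  segments anchor on their high-identity core rather than creeping along
  flanks) of the lag-p self-agreement track, accepted when the segment has
  ≥16 agreement positions at the identity floor (default 0.8) or ≥12 at
  ≥0.9. Measured on 1 kb uniform random sequence: tandem hits in 1/40
  seeds, periodogram peaks in 1/60; planted arrays (period 2–10, span
  ≥ period·(copies−1) ≥ 12) recovered with exact period and span within
  one period in 50/50 seeds. Arrays spanning less than ~12 bp of
  lag-agreement are below the detector's sensitivity floor by design —
  at that scale chance and signal are statistically indistinguishable.
* **Approximate repeat pairs**: exact 8-mer seeds propose diagonals; each
  diagonal's agreement track is scanned for maximal-scoring segments of
  length ≥ min_len (default 20) and identity ≥ the floor (default 0.80),
  capped at the diagonal offset so the two copies cannot overlap. Pairs
  are reported with a parenthetical-ambiguity consensus, e.g. `AT(T/A)A`.
  At identity floor 1.0 the scorer reduces to maximal exact runs and
  matches an exhaustive suffix-comparison oracle. Note that in an ~88% AT
  control region, 20-mers at 80% identity are abundant *bona fide*
  quasi-repeats of the sequence; raising `min_len` toward the repeat
  length of interest (30–41) isolates distinctive copies.
* **Degenerate motif search** accepts a per-symbol code map (full IUPAC by
  default; e.g. `N={A,T}` for the conserved transcription-termination
  binding motif TTAAATNNNNTNAGAT found between ND1 and trnS2).

## Branch lengths

Tip depths are root-to-tip path sums over a rooted tree (basal polytomies
are rejected unless an outgroup is supplied for re-rooting; the root's own
edge is excluded). Heterogeneity is summarized by mean, SD, CV, max/min
ratio and optional per-clade means.

## Synthetic data

All generators are pure functions of spec + seed.

* **Genomes.** The default spec emulates a lacewing-scale mitogenome:
  16,221 bp, ancestral insect gene order, gene lengths at the magnitudes
  typical of insect mitogenomes (PCGs 159–1,735 bp, tRNAs 64–71, rRNAs
  798/1,325, CR 1,358), 11 junction overlaps totalling 38 bp and 13
  intergenic spacers totalling 128 bp (largest 63 bp between trnI and
  trnQ; an 18 bp spacer between trnS2 and ND1 carries the planted
  termination-factor motif). PCGs are built codon-by-codon from
  per-position base distributions (rejecting stops), giving per-position
  A+T near 68/66/89% and T>A ranking; truth records carry the exact
  stop-rejection-conditioned expectations. Start/stop plans default to 7
  ATG / 4 ATT / 1 ATC / COI = TCG and complete TAA/TAG stops except
  incomplete T for ND4, ND5, COII, CytB. The ATP8/ATP6 and ND4/ND4L 7 bp
  overlaps are made consistent by forcing the shared `ATGATAA` heptamer
  into both reading frames (overlaps whose downstream partner is a tRNA
  simply inherit the upstream bases). The control region is sampled at
  88.5% A+T with planted microsatellites ((ATTTT)₄, (TAATATAA)₂, (AT)₈,
  (AT)₆) and two ~90%-identical 41-nt copies at offsets 224 and 428.
  What this does *not* emulate: realistic codon autocorrelation, tRNA/rRNA
  secondary structure, replication-driven skew gradients — so passing
  tests demonstrate correctness of the measurements, not realism of every
  genomic feature.
* **Alignments.** An ancestral codon sequence evolves independently per
  taxon; substitutions replace a base uniformly among the other three
  (symmetric, δ = 0) or, with probability δ, by a draw toward {A,T} —
  a one-parameter dial producing exactly the directional compositional
  heterogeneity the disparity index targets. No phylogenetic correlation
  or among-site rate variation is simulated.
* **Trees.** Random rooted bifurcating topologies built by random joins;
  every node carries its depth below the root, chosen below the lower
  child's depth, and terminal edges are solved so each tip's root-to-tip
  depth equals base_depth × its multiplier exactly.

## Problem sizes and numerical choices

Default analysis sizes mirror the study design the package addresses: 11
taxa (55 pairwise comparisons), 1000 Monte-Carlo replicates, α = 0.01.
Calibration suites use 1000 homogeneous 1 kb pairs (type-I), 100
directional pairs (power), 50 planted-repeat seeds and 40 random
sequences (repeat calibration) — sizes at which the binomial envelopes
quoted above are meaningful while the full test suite runs in under a
minute. Percentages are reported to one decimal. Degenerate cases: Nd = 0
short-circuits the disparity test to ID = 0, p = 1; empty synonymous
families yield null RSCU; skews with empty denominators are null rather
than zero.

## Known limitations

* The disparity index's scale is tied to this package's
  direction-symmetric null; values are not numerically interchangeable
  with other implementations' normalizations.
* The tandem finder's sensitivity floor (~12 bp of lag-agreement) excludes
  the shortest microsatellites from *spectral* detection; the exact
  microsatellite scanner covers that regime.
* Approximate-pair extension is ungapped; diverged copies with indels are
  reported as fragmented pairs, if at all.
* `gene_order_of` trusts annotations; unmappable features are flagged and
  ignored by downstream order comparison, not re-annotated.
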