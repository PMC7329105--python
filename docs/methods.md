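# Methods

`aphidiet` implements the analysis chain of an amplicon-metabarcoding diet
study: degenerate COI primers are evaluated in silico against a barcode
library, the amplicon's taxonomic resolution is quantified, raw MiSeq-style
paired reads from predator gut contents are reduced to per-individual prey
detections, and prey-composition differences between predator species are
tested by permutation. A synthetic-data layer generates every input with
known ground truth, so the chain is testable end to end without external
databases.

## In-silico primer evaluation

A degenerate primer is a mixture of concrete oligos described by IUPAC
codes (W = A/T, R = A/G, …). Physical properties treat each degenerate
position as the average over its possibilities, which makes GC content and
molecular weight exactly linear in the expansion (a tested invariant):

- GC% = 100 · Σᵢ |{G,C} ∩ possᵢ| / |possᵢ| / L
- MW  = Σᵢ mean(massᵦ, b ∈ possᵢ) − 61.96 g/mol, with monophosphate
  residue masses A 313.21, C 289.18, G 329.21, T 304.20
- Tm: Wallace rule 2(A+T) + 4(G+C) with fractional degenerate counting
  (default), or Biopython's nearest-neighbour model averaged over the
  expansion. Published Tm values depend on unstated salt/method parameters
  and are reported, not validated.

Amplification is predicted by a position-weighted mismatch penalty.
Binding events come from an ungapped alignment at the binding site (located
by minimum-penalty scan when no coordinate is given; ties resolve to the
most 3'-proximal site; reverse primers are evaluated on the
reverse-complement strand, which a property test pins to be exactly
equivalent to forward evaluation of the complemented template). The default
scheme scores transversions 40 and transitions 20, multiplies the five
3'-terminal positions by 4 / 3 / 2.5 / 2 / 1.5, compounds adjacent
mismatches by 1.5 each, charges 50 per indel (gapped mode only), and fails
a template above 120 points. The calibration logic: a lone 3'-terminal
transversion (160) blocks extension, any single internal mismatch (≤ 40)
does not, and roughly three internal transversions or a weighted 3' cluster
reach the threshold. The table, weights and threshold are data
(`MismatchScoringScheme`, JSON-loadable), not code. A primer pair covers a
template only when both primers pass; coverage is reported per taxon group
and an empty group reports "not applicable" (None) rather than 0/0.

## Amplicon taxon resolution

Percent identity is defined as matches over aligned columns of a global
edit-distance alignment restricted to the mutually covered region: terminal
indel runs (one sequence extending past the other) are excluded, internal
gaps count as mismatches, ambiguity codes match compatibly. Arguments are
ordered canonically before alignment so identity is strictly symmetric even
when several co-optimal alignments exist.

A record is *species-resolvable* at threshold t when all other records
within t are conspecific; matches spanning several species of one genus
give genus-level; cross-genus or no matches give unresolved. A genus is
species-resolvable when every species-labeled member is. The threshold
search evaluates every candidate — each distinct observed pairwise identity
at or above the 90% start plus midpoints between consecutive values — under
a lexicographic objective: first minimize retained cross-species matches,
then maximize species-level records; the smallest optimal candidate is
returned with the full score trace. A brute-force re-evaluation of the same
candidate set serves as the test oracle. Records covering fewer than 296
bases of the amplicon are excluded beforehand (≥ 296 kept, boundary
inclusive).

Similarity summaries: intraspecific mean ± SD over all conspecific pairs of
species with ≥ 2 sequences; within-genus variability over genus-only
records in genera with > 2 of them (sample SD, absent when no group
qualifies).

## Reads-to-diet pipeline

Stages, in order, each conserving reads (in = out + discarded, with reason
codes, accumulated in a stage log):

1. **Adapter clipping** — 3' adapter occurrences located by
   mismatch-tolerant scan (≤ 2 mismatches, ≥ 8 bases overlap at the read
   end), read truncated at the match.
2. **Quality trimming** — edge bases below Q3 removed, then a 4-base
   sliding window 5'→3'; the read is cut before the first window with mean
   quality < 20; reads shorter than 250 nt are discarded.
3. **Pair merging** — R2 reverse-complemented; best ungapped overlap
   (matches − mismatches, ties to the longer overlap) with ≥ 10 nt and
   mismatch fraction ≤ 0.25 accepted; conflicts take the higher-quality
   base. The 308 bp amplicon on 2×300 chemistry always overlaps, so
   non-merging reads are artefacts and are dropped.
4. **Demultiplexing** — a read is assigned iff exactly one sample's
   (forward, reverse) MID-tag pair matches the read ends with ≤ 1 mismatch
   per tag, in either orientation; tags and primers are then stripped.
   Reads matching ≥ 2 samples go to the unassigned pool as "ambiguous" —
   never arbitrarily assigned.
5. **Dereplication** — identical sequences collapse to uniques with size
   counts (sizes sum to the input count; a tested conservation property).
6. **Abundance filter** — uniques with size below the per-pool threshold
   removed ("fewer than N" removed, so size ≥ N kept). The threshold starts
   at 10 and rises to one more than the largest *impossible* detection in
   that pool — any unique observed in a negative control — mitigating
   tag-jumping: every artefact actually observed in controls would have
   been removed everywhere.
7. **Chimera screen** — a unique is flagged when it can be exactly split
   into a prefix of one ≥ 2×-more-abundant unique and a suffix of another;
   the most abundant unique can never be flagged. This two-parent crossover
   model replaces full denoising.
8. **Centroid clustering** — greedy single pass in decreasing-abundance
   order (ties lexicographic, for byte-reproducibility): join the first
   centroid within 99% identity, else found a new one.
9. **Taxonomic assignment** — matches are library records with ≥ 98.36%
   identity over ≥ 296 aligned bases; all-conspecific matches give species
   rank, several species of one genus give genus rank, otherwise
   unassigned (best identity always reported).
10. **Detection matrix** — rows are individuals, columns target-group
    (aphid) taxa, cells summed reads; predator-assigned and unassigned
    reads are tallied separately, so a predator-only individual is an
    explicit aphid-negative row.

The pipeline is deterministic given input order; there is no randomness.

## Composition statistics

Per-individual presence/absence is aggregated into landscape ×
sampling-round (× predator species) units and converted to within-row
detection proportions (row sums 0 or 1). The Hellinger transform
(cell → √(cell/row sum), zero rows unchanged) makes Euclidean distance
appropriate for proportion data with many zeros.

- **PERMANOVA**: one-factor pseudo-F from the among/within partition of
  squared distances, F = (SS_A/(a−1)) / (SS_W/(n−a)). Permutations shuffle
  group labels *within strata only* (sampling rounds), so round effects
  cannot masquerade as species effects; p = (1 + #{F\* ≥ F}) / (1 + n_perm),
  counting the observed labelling — standard and conservative. A stratum
  containing one group level only triggers a warning (no permutation
  freedom). The statistic is verified against an independent double-loop
  oracle, against scikit-bio's permanova (unstratified), and against exact
  enumeration of all within-stratum arrangements on 6–8 rows; the
  stratified type-I error is checked at the 5% nominal level over 500 null
  simulations.
- **Dispersion**: principal-coordinate embedding of the distance matrix
  with the standard imaginary-axis correction for negative eigenvalues;
  per-row distance to its group centroid; one-way F across groups;
  permutation p by relabelling rows and recomputing centroid distances in
  the fixed embedding. Singleton groups are excluded with a warning.
- **NMDS**: Kruskal stress-1 minimized by alternating isotonic regression
  of embedded distances on the dissimilarity order with Guttman-transform
  updates; the first start is the metric (PCoA) solution, further starts
  (default 20) are random; iteration stops on stress change < 1e-7 or a
  stress increase (the previous configuration is kept, so the reported
  stress sequence is monotone); the lowest-stress start wins. All-equal
  distance matrices are flagged degenerate with stress 0. The published
  stress value is start- and data-dependent and is not a validation target.

Recovery-rate summaries are plain count arithmetic (positives/total to
0.1%, ratios between named strata, NaN for empty strata), and
`complementary_trap_share` recovers one trap type's species share from the
totals and the other type's share. Mixed-model fits on these tables are
deliberately out of scope; the package stops at the tables.

## Synthetic data: what it emulates, and what it does not

`simulate_library` builds a genus/species/replicate hierarchy: one random
root per genus, species at a pairwise congeneric divergence drawn from
1–8% (spanning both sides of the 98.36% assignment threshold), conspecific
replicates at 0.2% pairwise divergence (the ~99.8% intraspecific identity
such COI libraries show), genera unrelated (< 90% identity). Divergence
parameters are *pairwise* targets; each branch receives half. Substitutions
only, by default — identity thresholds sit near boundaries and indel
conventions would confound them.

`simulate_gut_samples` emits MID-tagged paired 300 nt reads: tag + primer +
amplicon + primer site + tag, with per-cycle linear mean-quality decay
(Q38 → Q25, Gaussian jitter SD 3, the simplest profile that exercises the
window trimmer), per-base substitution errors (default 0.1%), predator
reads topped up to 90% of each sample (the predator-dominated read sets
gut-content metabarcoding produces), single-crossover chimeras (0.5% of
molecules), and whole-read tag-jumps to a uniformly chosen other sample
(1%), all logged as ground truth. Because predator reads dominate, the
largest impossible detections in negative controls are predator jumps, so
the derived threshold comfortably exceeds any aphid jump — the mechanism
behind per-pool threshold inflation in real runs.

Not emulated: instrument-specific error spectra, quality-dependent error
rates, PCR amplification stochasticity beyond fixed expected counts, indel
sequencing errors, and primer-binding bias (every composition taxon
amplifies). Passing end-to-end tests therefore demonstrates the pipeline's
filter logic and threshold arithmetic under controlled noise, not
robustness to real instrument artefacts.

## Problem sizes and tolerances used by the test suite

Chosen as the smallest sizes that make each property informative: libraries
of 12–54 sequences for threshold-search oracles (exhaustive search is
quadratic in candidates × records); 8 gut samples × ~190 aphid reads plus
90% predator reads and 3 negative controls (~25k read pairs) for full-chain
recovery; 500 null simulations × 99 permutations on 16 × 6 composition
matrices for the PERMANOVA type-I check (accepted band 2–8%, ± ~3 binomial
SD around 5%); ≤ 20 sequences for the clustering membership oracle.
Floating-point comparisons use half the last printed digit for published
table values and relative 1e-6 elsewhere.

## Known limitations

- The mismatch-penalty defaults are a calibrated stand-in for an external
  tool's unpublished table; coverage percentages from real libraries will
  differ from published figures unless that tool's exact table is supplied.
- Identity is edit-distance based; for heavily gapped or partial barcodes
  the "mutually covered region" convention can differ from BLAST local
  identity.
- The chimera screen only detects exact two-parent single crossovers.
- The pipeline holds all reads in memory; it targets study-sized pools
  (millions of reads), not production sequencing archives.
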