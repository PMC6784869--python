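# Methods

This note documents the models behind each module, the parameters that
matter, what the synthetic-data generators do and do not emulate, and the
numerical and design choices taken where the problem was genuinely open.

## Synthetic data and ground truth

All pipeline stages are validated against data generated by
`grasskit.simulate`. Generators are pure functions of `(config, seed)`: each
draws from a `numpy` Generator seeded with `SeedSequence([seed, tag])`
(a distinct tag per generator), so identical configs give byte-identical
outputs and the different generators never share random state.

**Genome substrate.** Chromosomes are i.i.d. background sequence with a mild
AT bias (base probabilities 0.28/0.22/0.22/0.28, ~44 % GC, in the range of
grass genomes). Genes, intact LTR retrotransposons, solo-LTRs and SSR runs
are packed left-to-right with Dirichlet-distributed random gaps; infeasible
packing raises `PlacementError`. Coordinates are 0-based half-open
internally; annotation tables carry 1-based inclusive columns for GFF-style
export.

**LTR elements and the molecular clock.** Each family has one consensus LTR
(default 400 bp). An intact element planted with true age T is emitted as
TSD + 5′LTR + internal + 3′LTR + TSD, with each LTR copy evolved
independently a K2P branch length of rT from the consensus
(r = 1.3 × 10⁻⁸ site⁻¹yr⁻¹ by default, transition/transversion ratio 2.0, the
standard default in the absence of better information), so the realized
5′/3′ divergence is K = 2rT in expectation. The substitution process uses
the exact 4×4 K2P transition matrix (matrix exponential), not a one-hit
approximation, so multiple hits at one site occur at the correct rate.
Target-site duplications are 4–6 bp. Four single guard bases adjacent to the
TSDs and the internal-region boundaries are constrained to differ from the
base they would otherwise mirror: without this, a planted element whose
flanking base happens to equal the adjacent LTR base admits an equally valid
alternative [TSD][LTR] decomposition shifted by one, and "true coordinates"
would not be well defined. This is a well-posedness constraint on the truth,
not an aid to any particular detector.

**BAC pools.** BAC inserts are placed without overlap, emulating a minimal
tiling path, so read ambiguity arises only from repeats or from an optional
planted duplication copied between two clones in different rows and columns
(reads falling entirely inside that duplication are recorded as ambiguous in
the truth). Reads have uniform start positions, fixed length, and
independent substitution errors only — no indels, no quality model, no
long-read error profile.

**F2 cross.** Two inbred parents (AA × BB). Each gamete receives a Poisson
number of crossovers per chromosome (default mean 2.0, matching a ~200 cM
chromosome) placed uniformly, with no interference — the simplest defensible
null; real RAD-seq marker ascertainment and interference are not modelled.
Genotype error flips a code to one of the other two (default 1 %); missing
data is set independently (default 5 %). The truth records marker order,
true genetic positions (cM = 100 · rate · pos/L), every breakpoint and each
gamete's starting phase, so genotypes can be reconstructed independently.

**Population.** Ancestral allele frequencies are Beta(c, c) with
c = h/(1−2h) chosen so the mean heterozygosity is h (default 0.3); group
frequencies follow a Balding–Nichols draw at F = 0.05 around them; three
groups of 30/64/53 accessions (147 total) by default. Inside the sweep
window the swept group's expected heterozygosity is divided by the
configured factor (default 10) by moving its allele frequency toward
fixation on the nearer side. A binary phenotype follows homozygosity for
the swept group's major allele at the window-central SNP with probability
`phenotype_linkage` (default 1.0). This frequency-based model has no linkage
disequilibrium decay or coalescent structure; a separate msprime-based
neutral generator (`simulate_neutral_haplotypes`) provides proper coalescent
haplotypes for calibrating π against θ_W.

**Ortholog tables.** A core collinear gene order shared by five genomes
(two focal + three outgroups); deletions remove core genes from the focal
genome only, insertions add focal-only genes, and optional noise plants
spurious homology pairs. No inversions or translocations are simulated.

What passing tests show, and do not show: recovery results on these data
demonstrate the correctness of the *rules and estimators* under their stated
assumptions (substitution-only reads, no interference, no LD, clean
collinearity). They do not demonstrate robustness to real-data pathologies
such as indel sequencing error, segmental duplication beyond the planted
cases, reference bias, or marker ascertainment.

## Pool deconvolution

The assignment rule is the contribution; the aligner is a stand-in. The
bundled matcher seeds with exact 21-mers, enumerates candidate gapless
placements, and scores coverage (aligned read fraction) and identity
(matches/aligned columns) — exact for substitution-only reads. Production
users can ingest PAF from any aligner instead. Thresholds default to
identity ≥ 0.99 and coverage ≥ 0.90, compared inclusively. "Appeared only
once in all crossing pools" is interpreted at pool granularity: hits to
several contigs within one pool do not make a read ambiguous, because pools
(not contigs) define the cross point. Rejection reasons are assigned in the
fixed order no_hit → row_ambiguous → col_ambiguous → empty_cell.

## Genetic map

* Bin consensus: majority genotype among non-missing member SNPs, requiring
  ≥ 60 % agreement and no tie, else missing.
* Recombination fraction between bins: events/(2 × informative individuals),
  counting A↔H and H↔B as one event and A↔B as two; H↔H pairs count zero
  events because their two-recombinant resolution is invisible without
  flanking information — this biases r for unlinked pairs down to ~0.375,
  which is harmless here because grouping uses a much lower threshold.
  r is capped at 0.499.
* Grouping: single-linkage components at r ≤ 0.25 — a reproducible,
  dependency-free stand-in for interactive grouping software.
* Ordering: greedy nearest-neighbour chaining followed by 2-opt reversals
  minimizing Σ adjacent r; a group is oriented so its first contig's bins
  ascend in physical position. Acceptance is truth recovery (Kendall τ), not
  algorithm identity.
* Crossover sanitation: "an upper limit on the physical distance between two
  adjacent crossovers of at least 1 Mb" is read as a *minimum separation*
  between adjacent crossovers — the only reading under which the correction
  serves its stated purpose of killing spurious close double crossovers.
  Segments bounded by two crossovers closer than 1 Mb are set to missing
  (applied to a fixed point); then the physically shortest interior segments
  are removed until ≤ 10 events remain. The operation never adds crossovers
  and is idempotent (property-tested).
* Bin merging: adjacent bins ≤ 100 kb apart whose genotype vectors agree on
  all mutually non-missing entries are merged, the called values filling the
  gaps.
* Pseudomolecules: contigs ordered by mean cM of their bins (ties by
  physical order), oriented by the sign of the within-contig correlation
  between bin position and cM (single-bin or indeterminate → forward),
  joined with 100-N gaps (gap size is a convention; nothing downstream
  depends on it).

Desk-scale problem sizes used by the tests and the acceptance script:
7 chromosomes × 40 Mb, 500 markers, 200 individuals, 1 % error, 5 % missing.
Marker spacing (~560 kb) is deliberately below the 1 Mb crossover-separation
threshold so that single-marker genotyping errors present as removable
double crossovers — the same geometry (dense bins, sparse crossovers) that
makes the correction effective at chromosome scale.

## LTR toolkit

* Intact detector: exact 13-mer seeds within a spacing window
  (internal 1–15 kb, LTR 100–3000 bp), gapless x-drop extension
  (+1/−2, drop 25), identity ≥ 0.85. Boundaries are refined by searching
  shifts of ±4 bp for a flanking target-site duplication, scoring candidates
  by 2·len − shift (a longer duplication is stronger evidence; a chance
  match far from the extension boundary should not outrank a short one at
  it). Overlapping candidates are resolved by maximum-total-weight interval
  scheduling, weight dominated by TSD strength: a chimeric pairing of two
  neighbouring same-family elements carries at best a weak chance TSD, so
  the true elements it would span outweigh it. `require_tsd=True` restricts
  output to TSD-confirmed elements; recommended when families are young and
  homogeneous, at the cost of missing elements with decayed TSDs.
  Known limitation: two nearby recent solo-LTRs of one family can still be
  paired into a spurious "intact" element (they mimic its structure exactly
  up to the TSD); no structure-blind detector can fully exclude this.
* Solo-LTR detector: 13-mer seed clusters against each library LTR, edlib
  infix alignment over the candidate locus, identity = 1 − dist/len,
  reported strictly above 0.85, after excluding anything overlapping an
  intact element (so an intact element's own LTRs are never counted as
  solos).
* Divergence: K2P over the globally aligned 5′/3′ LTR pair of an intact
  element, gap columns excluded. The phrase "5′ and 3′ solo-LTRs" in the
  source procedure is internally inconsistent (a solo-LTR has no pair); the
  dating substrate here is the two LTRs of each intact element. The global
  aligner uses match 2 / mismatch −1 / gap open −6 / extend −2: with unit
  edit costs, two substitutions can be rewritten as an indel pair whose gap
  columns then vanish from the K2P counts, biasing distances down ~5 % at
  K ≈ 0.05 — the affine costs remove that artefact (bias < 2.5 % across
  K = 0.0065…0.052 in the age-recovery tests).
* Ages: T = K/(2r). Printed solo/intact ratios are rounded half-up to one
  decimal. Insertion-burst histograms use 0.25-Myr bins to 5 Myr.

## Annotation filter

Rules are applied per gene in the fixed precedence TE → non-coding →
pseudogene → low-support → confidence, with the mean expression computed
once over the entire input (verdicts are therefore order-independent, and
each gene receives exactly one label). All thresholds follow the printed
rules: strict > 50 aa / > 50 % for TE-relatedness; protein < 50 aa without
protein evidence for non-coding; full coverage plus length < 70 % of the
coverer plus expression below half the mean for multi-exon pseudogenes;
single-exon EST/RNA-only models need < 100 aa *and* sub-half-mean expression
to be dropped. "Fully covered" is consumed as a precomputed relation; the
alignment engine behind it is pluggable (the 50 % identity convention
mirrors the functional-annotation thresholds and is configurable, since the
source does not print one). lncRNA: length > 200 bp, no ORF > 50 aa,
external coding score ≤ 0. Tandem duplicates: paralogues on one chromosome
separated by ≤ 2 genes; segmental: chained collinear paralogue pairs (≥ 2
pairs, ≤ 2 intervening non-collinear genes).

## Synteny and indels

Chaining is sparse DP over homology anchors: score = anchor count, strict
monotonicity in both genomes (both orientations searched), chains broken by
gaps > 10 genes, ties broken by smaller total gap then earliest start,
blocks extracted best-first with each anchor used once, minimum 3 anchors
(the Fig.-2-style preset uses 5 anchors at similarity ≥ 0.8). The DP is
verified against exhaustive search on ≤ 12-gene permutations. Note that
block *extraction* under exact ties is not symmetric between genome
orderings; anchor-set symmetry holds whenever the best chains are unique.

Indel calls use outgroup triangulation: "collinear orthologue in an
outgroup" means anchor membership in a genome-vs-outgroup block, not mere
presence in a homology table. Deletion in the focal genome: a partner-genome
gene inside a focal-vs-partner block, anchored to the focal genome nowhere,
with ≥ 2 of the three outgroups holding it in collinear position. Insertion:
a focal gene inside a block, anchored to no other genome at all, whose
nearest flanking anchors (not necessarily immediately adjacent genes — the
source is ambiguous; nearest anchors is the implemented reading) are each
supported by ≥ 2 outgroups.

## Population genetics

π is the sum over SNPs of the unbiased per-site heterozygosity
2c(n−c)/(n(n−1)) (allele counts from non-missing calls), divided by the
*window length* — the windowed convention, not callable length
(configurable). θ_W = S/(a₍ₙ₋₁₎L) with n the group's haplotype count. FST is
the Hudson (1992) two-population estimator, window-aggregated as the ratio
of summed numerators to summed denominators, chosen over Weir–Cockerham for
robustness to unequal sample sizes (the source names only a software
package, not an estimator); reported values are clipped below at zero with
the raw value retained. Windows are [start, start + 100 kb) at 10-kb steps;
a truncated final window is flagged. The MAF filter excludes SNPs with minor
allele frequency strictly below 5 % (the boundary is kept). Sweep thresholds
(7.7, 4.3) are user parameters: they encode genome-wide quantiles of a
particular data set, not universal constants. Haplotypes for association are
homozygous-majority strings (heterozygous or missing anywhere in the region
excludes the accession); the top-2 haplotypes × phenotype table gets a
two-sided Fisher exact test, skipped for degenerate tables.

## Summary arithmetic

N50 uses the standard descending-cumulative convention (the informal
parenthetical definition circulating in report prose is garbled). percent,
mean_length and the solo/intact ratio are computed in exact rational
arithmetic and rounded half-up exactly once at the printed precision —
half-up, not banker's, because that is what the checked printed values use.

## Problem sizes and runtime

The default test suite and `scripts/acceptance.py` run single-CPU in well
under a minute each, using the desk-scale sizes stated above (3.5 Mb
genomes / 96 BACs for deconvolution, 280 Mb / 500 markers / 200 individuals
for the map, 100 elements per age class for dating, 200-gene ortholog
tables, 2 000 SNPs × 147 accessions × 10 seeds for sweeps). These sizes are
the package's validation conditions; all thresholds and rates above are the
study conditions or standard defaults, fixed before the recovery
experiments were run.
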