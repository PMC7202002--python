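# Methods

`cladeqc` implements the bespoke computational stages of a clade-scale
short-read genome resource: profiling each sample from its unassembled
reads, post-processing and decontaminating draft scaffolds, resolving
heterozygous assemblies to a majority-haplotype consensus, remapping
annotated features between genomes through alignment chains, and testing
feature orthology by reciprocal best hits. This note records the models,
the parameters that matter, and the numerical choices made where the
procedure was genuinely open.

## Synthetic data: what it emulates and what it does not

Every pipeline input can be generated with known truth
(`cladeqc.synthetic_data`), so the estimators are validated by recovery
rather than against external downloads.

* **Diploid genomes** (`simulate_diploid`): haplotype A is i.i.d. sequence
  at a GC target (default 0.42, a typical drosophilid read GC) with
  repeat families planted as mutated copies of a common unit; haplotype B
  differs from A at truth variants drawn at `het_rate` per bp
  (default regime 2e-3, the upper end of the observed variant-branch
  frequencies). SNP:indel ratio defaults to 10; indel lengths are
  geometric (mean 2 bp) and capped at 49 bp, with structural variants
  drawn separately (>= 50 bp, `sv_rate` per Mb) — so the 50 bp SV
  convention used by the consensus stage is respected by construction.
* **Reads** (`simulate_reads`): 100 bp pairs from ~350 bp inserts
  (sd 20 bp), fragments drawn uniformly and assigned to either haplotype
  with probability 1/2; uniform substitution errors only. Read names
  carry the haplotype and fragment coordinates, which makes the coverage
  and error-rate oracles possible without a mapper.
* **Phased calls** (`simulate_phased_vcf`): truth variants partitioned
  into phase blocks with exponential genomic lengths (mean
  `phase_block_mean`); per-block orientation flips at `swap_rate` emulate
  phasing errors; allele depths are Poisson(depth/2) per haplotype.
* **Ortholog tiles** (`simulate_ortholog_tiles`): 2 kb tiles embedded in
  a reference scaffold; the diverged genome applies i.i.d. substitutions
  at rate 1 − target identity (substitution-only, so truth chains stay
  gapless), optionally split/reordered/inverted into several scaffolds
  with tiles never spanning a breakpoint.

Not emulated: machine-specific error and quality profiles, optical/tile
artifacts, GC-coverage bias, indel divergence between the two genomes in
the tile simulation, and real repeat landscapes (repeat copies are
single-family and non-nested). Passing recovery tests therefore
demonstrate correctness of the estimators under their stated model, not
robustness to every artifact of real libraries.

One global seed expands to per-stage child seeds by fixed enumeration
(`SeedSequence(seed, spawn_key=(stage,))`), making stage outputs
byte-reproducible independently of each other.

## Read preprocessing

Quality trimming is two-sided Phred/Mott trimming (the BBDuk
`qtrim=rl` semantics): scanning inward from each end with
`s <- max(0, s + (q_i − threshold))`, the cut sits one past the last
position where `s` attained its running maximum; both ends are trimmed
independently and reads shorter than `min_length` (default 51) are
discarded. The k-mer contaminant filter removes a pair when either mate
has a length-75 window within Hamming distance 1 of any contaminant
window on either strand; the distance-1 search uses the pigeonhole
split (exact match on either k-mer half, then full verification), which
is exact. N positions mismatch everything — conservative, since an N can
never be evidence of a contaminant match.

SSR contaminant detection flags a pair only when **both** mates are
covered >= 80% (`dominance`) by a tandem repeat of period 8 or 10 with
the same canonical motif (lexicographic minimum over rotations of the
unit and its reverse complement). The 0.8 default separates pure-repeat
fragments from genomic loci that merely contain an SSR; at 100 bp reads
the false-positive rate on random sequence is effectively zero (tested
over 1,000 pairs).

## k-mer spectrum profiling

`k = 41` throughout (canonical k-mers, N-windows skipped). The spectrum
conserves mass exactly: sum of multiplicity x count equals the number of
windows scanned.

**Genome size.** The error trough is the first local minimum of the
spectrum over its *observed* (nonzero) multiplicity bins; a 3-bin moving
median stabilizes the search when the spectrum has more than 10 observed
bins (real-data regime; tiny spectra are used raw so that worked
examples remain hand-checkable). A spectrum that does not descend at its
start has no error branch and the trough is the first bin; a spectrum
with no peak beyond the trough (singleton-dominated, i.e. coverage too
low) raises "not estimable" — mirroring samples whose coverage was too
low to profile. The estimate is solid k-mer mass / peak multiplicity.
Because the integer argmax quantizes the estimate in steps of 1/mode
(about 5–6% at 30x read coverage), the peak multiplicity is refined on
rich spectra to the count-weighted centroid of the bins within ±4 of the
argmax; sparse spectra keep the raw argmax. With this refinement the
estimator recovers a 100 kb simulated genome to well under 1% at 30x.

**Branch frequencies.** Over (k−1)-mer vertices of the solid-k-mer de
Bruijn graph (both orientations) with >= 2 single-base extensions: a
vertex is a *variant branch* when its top two extension counts are
balanced (minor/major >= `r_min` = 0.25) and sum to <= `c_rep` x mode
(= 1.75 x), and a *repeat branch* when the sum exceeds that cap. The
constants separate diploid allele branches (two halves of one coverage
unit) from collapsed-repeat branches (>= 2 coverage units) with margin;
they are configuration, not claims about any external profiler, and the
module's guarantees are property-based (frequencies strictly monotone in
simulated heterozygosity and repeat copy number; near zero on clean
homozygous genomes).

## Scaffold surgery and contamination gates

Scaffolds split at N-runs strictly longer than `max_gap` (inclusive
threshold; default 600 bp from the plausible upper bound for a ~350 bp
insert library — the per-library value is configuration). Contigs split
on every N including single Ns. Hard-masking replaces a region with a
fixed 300 Ns. IUPAC ambiguity codes (except N) resolve to a uniform
random compatible base under a seed. Contaminant spans trim terminal
hits and split internal ones; the GC x k-mer-coverage gate is a
rectangle with inclusive bounds on both axes (matching how such gates
are quoted), applied to scaffolds >= 1 kb. Confirmation of candidates
against a sequence database is outside the computational core; the
module accepts an externally confirmed id list.

## Assembly metrics

NG(x) is the scaffold length at which the descending cumulative length
sum first reaches x% of the **estimated** genome size; NG50 = NG(50),
and NG(1..100) is the NG graph (undefined entries mark where the curve
never reaches the axis — assemblies shorter than x% of the genome).
Setting the genome size to the total assembly length recovers N50
exactly. Gene-sized fraction uses an inclusive 6.3 kb threshold (the
average gene length in a well-annotated close relative). Pearson
correlation and OLS regression pass through scipy/statsmodels with
pairwise NA dropping; reported percentages round to one decimal while
internal values keep full precision.

## Majority-haplotype consensus

Overlapping calls cluster by intersecting reference spans (which
subsumes shared start positions); within a cluster a structural variant
(>= 50 bp allele or symbolic) wins, otherwise the call with the greatest
supporting alt read depth, ties broken by longer span then position.
Phase sets are scored by cumulative allele read depth per haplotype with
indels and SVs weighted 0.5 (indel alignments distort depths roughly
twofold relative to SNPs); the majority haplotype's non-reference
alleles are retained as homozygous calls, un-phased variants keep the
deeper of ref/alt. Two deterministic tie rules the procedure leaves
open: score ties go to haplotype A (the first genotype allele), and an
un-phased ref/alt depth tie keeps the reference. "Read count" is the
per-allele AD-style depth — the only per-variant, per-allele count the
file format carries. Application is VCF-semantics (1-based, anchored
indels) with a hard error on any reference mismatch.

## Coordinate lifting

Chains are validated on parse (block spans must reconcile with header
spans; target strand must be +). An interval remaps through a chain when
at least `min_match` (default 0.1) of its bases fall in aligned blocks,
measured against the source interval length; the reported query interval
spans min..max of the projected positions, bridging chain gaps interior
to the projection — 2 kb tiles routinely cross small chain gaps and the
sequence of interest lies under the full span. `bases_mapped` counts
only block-aligned bases. Minus-strand results convert from
reversed-sequence to forward coordinates. With multiple qualifying
chains one result per chain is returned; the largest coordinate span is
retained on disambiguation (ties: more aligned bases, then lower chain
id). The projection is asserted equal to an independent per-base oracle,
including minus-strand and gap-bridging cases.

## Local alignment and reciprocal best hits

The aligner is an exact affine-gap Smith–Waterman (numba-compiled) with
BLASTN-style scoring: reward +2, penalty −3, gap open 5, gap extend 2
(a length-L gap costs 5 + 2L). Multiple hits come from iterated
alignment with the consumed query interval masked between passes, so
per-query hits never overlap on the query. Subjects small enough are
aligned in full; genome-scale subjects are first scanned for exact
11-mer seeds (both strands), seeds cluster by diagonal (tolerance 64,
>= 2 seeds per cluster to exclude chance matches), and the exact DP runs
on padded windows around each cluster. The top score is therefore exact
whenever a two-seed cluster exists — guaranteed in practice down to well
below 75% identity for 2 kb queries. E-values use the Karlin–Altschul
form E = K·m·n·exp(−λS) with configurable (λ, K); the defaults
(0.625, 0.41) are for this scoring scheme, and only the E-value's
monotone behavior is relied upon. The default threshold for an n-tile
screen is 1/n to two significant figures (0.00029 for the 3,457-tile
enhancer set).

A tile is a reciprocal best hit when (i) the best hit of its lifted
sequence back onto genome 1 overlaps the original tile interval by
>= 1 bp and (ii) the best hit of the tile sequence onto genome 2
overlaps the lifted interval. For RBH pairs the tile-vs-ortholog hits
are reduced to non-overlapping query intervals (descending score; nested
hits removed, partial overlaps trimmed to their longest free stretch
with subject coordinates proportionally adjusted and flagged
approximate) and summarized as query coverage (% of query positions
covered) and length-weighted percent identity.

## Problem sizes and tolerances

The recovery studies run at desk scale as the package's own test
conditions: genome-size recovery on a 100 kb nonrepetitive genome at
30x error-free coverage (tolerance 5%); branch-frequency monotonicity on
80 kb at 25x with paired seeds; consensus recovery on 100 kb at
`het_rate` 2e-3 with depth-20 calls, 5 kb phase blocks and a 0.25 block
swap rate (site agreement >= 99.9% against an oracle that enumerates
both haplotype options per block); and the orthology screen on 50 two-kb
tiles with scaffold shuffling and one inversion, at tile identities 1.0,
0.9 and 0.75 (100% RBH at identity 1.0; >= 90% at 0.75; rate
non-increasing in divergence). Oracle-equivalence suites use 500 random
length sets (NG values), 400 random intervals over ~80 synthetic gapped
chains (liftOver), 100 random pairs up to ~260 bp (Smith–Waterman), and
exhaustive Hamming comparison for the k-mer filter.

## Known limitations

* The branch-frequency constants (`r_min`, `c_rep`) are heuristic gates;
  absolute frequencies are not comparable across k or coverage regimes,
  only contrasts under matched conditions.
* The seeded alignment path can miss a best hit with no two-seed
  cluster (queries far below ~60% identity or shorter than ~50 bp);
  such regimes fall outside the enhancer-screen design point.
* Hit trimming adjusts subject coordinates proportionally, which is
  approximate for gapped hits; downstream statistics use query-side
  lengths only.
* `simulate_ortholog_tiles` produces substitution-only divergence;
  indel divergence between genomes (and hence gapped truth chains) is
  exercised through hand-built and randomized chains in the liftOver
  tests instead.
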