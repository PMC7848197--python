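# Methods

`haploxo` automates a comparative-genomics workflow that was traditionally
done by eye on percentage-identity plots: given two phased, megabase-scale
haplotype assemblies of the same genomic region (the motivating case is the
human MHC class I region between *GPX5* and *MICB*), find where the pairwise
SNP density switches between near-zero and several SNPs per kb, and read
those switches as ancestral recombination breakpoints. Alongside, it
genotypes dimorphic retroelement insertions from RepeatMasker annotation and
uses them to partition haplotypes into ancestral lineages.

## Model and assumptions

The underlying model is a mosaic model of haplotype structure: each extended
haplotype is a concatenation of blocks drawn from a small pool of ancient
ancestral lineages. Two haplotypes that share a lineage over a block are
nearly identical there (of order 1 counted SNP per 100 kb); where their
lineages differ, divergence is two to three orders of magnitude higher
(around 7 SNPs per kb). Under these conditions the pairwise SNP-density
signal is close to a piecewise-constant Poisson process, and the junction
between a conserved and a divergent block — a SNP-density crossover (XO) —
is a changepoint in that process.

Assumptions that matter:

* the two sequences are co-linear (no inversions or translocations);
  structural events appear only as indels;
* SNP density within a block is roughly homogeneous — the changepoint
  refinement models each side as a single Poisson rate;
* assembly artifacts (N-runs, locally mis-assembled stretches) produce
  characteristic mismatch patterns that the exclusion filters can recognize.

## Pipeline stages

**Alignment** (`pairwise_align`). Sequences are anchored on 31-mers that
occur exactly once in each sequence, collapsed into maximal exact-match
anchors, and chained by the strictly co-linear chain of greatest total
anchor length (leftmost tie-break for determinism). Inter-anchor gaps up to
`max_gap_fill` (5 kb) on both sides are closed with an optimal unit-cost
edit-distance alignment (edlib); larger gaps become unaligned segments —
structural indels, never SNP sources. Blocks containing indels are then
re-aligned whole (up to `polish_limit`, 200 kb): filling each gap with
pinned anchor boundaries can cost one or two operations more than the
global optimum when the optimal path re-synchronizes through coincidental
matches near an indel, and the polish removes exactly that gap. Cost ties
between a substitution and a micro-indel representation are resolved toward
substitutions, which is how a human reads an identity plot and keeps
adjacent SNPs from being re-expressed as insertion/deletion pairs.
Duplicated regions without unique anchors stay unaligned; variants there
fall under the exclusion rules anyway.

**SNP calling and filters** (`snp_calling`). Every aligned column with two
differing plain bases is a raw substitution. Filters then mark the calls
that manual counting would skip, each one total and independent:

| filter | rule | default |
|---|---|---|
| `DENSE_CLUSTER` | any 50-nt window (all offsets) with >5 substitutions removes all its members | 5 per 50 nt |
| `N_PROXIMAL` | within 50 bp of an N-run of ≥3 nt on either sequence | 50 bp flank |
| `GAP_PROXIMAL` | within 50 bp of an alignment-gap run ≥50 bp | 50 bp / 50 bp |
| `SIMPLE_REPEAT` | inside Simple_repeat / Low_complexity / Satellite annotation; internal perfect-tandem detector (unit 2–6, ≥12 nt, ≥2 units) when no track given | — |
| `HOMOPOLYMER` | inside a single-base run ≥8 nt on either sequence | 8 nt |

The N-run (3 nt), gap-run (50 bp) and homopolymer (8 nt) lengths are this
package's choices — the source workflow called these cases "obvious"
without printing numbers; all are configurable. A raw call always appears
exactly once, either counted or with a non-empty filter set.

**Density classification and crossover localization** (`xo_detection`).
Counted SNPs are profiled in sliding windows (default 100 kb window / 10 kb
step; thresholds are stated per 100 kb, partial windows are normalized).
Labels: SPR (SNP-poor) strictly below 20 counted SNPs per 100 kb, SRR
(SNP-rich) strictly above 100, INTERMEDIATE between. Same-label windows
merge into maximal runs; an interior run vouching for less than one full
window of genome (stepped extent `n_windows × step` < `min_run_length`) is
absorbed by its dominant neighbour, so a single-window blip never becomes a
block. Terminal runs are truncated by the region edge and are measured by
their genomic union instead — otherwise a genuine terminal block in a
region only a few windows long would be absorbed.

At each SPR↔SRR junction the changepoint c maximizes the two-rate Poisson
profile log-likelihood n_L·log(n_L/ℓ_L) + n_R·log(n_R/ℓ_R) over the span
from the last window fully in the left run to the first window fully in the
right run. The log-likelihood is convex in c between adjacent SNPs, so it
suffices to scan the boundaries immediately at and immediately after each
SNP; this candidate set is also closed under mirror reflection, which makes
the estimator strand/direction symmetric. Ties go to the leftmost
candidate. The reported coordinate is the first counted SNP on the dense
side of c (the "first SNP of the dense block" convention a human reader
applies); its alleles are reported as "X/Y". Junctions involving
INTERMEDIATE runs are reported only when requested.

**Repeat association** (`repeat_association`). Each call is annotated with
its containing repeat element (nested fragments resolved by Smith–Waterman
score, then length, then position), or the nearest elements on each side
("left/right" context), the repeat names within a configurable 10-kb
radius, signed distances to gene anchors (negative inside the feature), and
exact motif scans on both strands (e.g. the PRDM9-bound THE1B motif
ATCCATG/CATGGAT, and retroelement target-site-duplication motifs used to
locate empty insertion sites). Family matching is prefix-based with a small
alias table (ERV3-16A3 ≡ HERV16).

**Marker genotyping** (`marker_genotyping`). A dimorphic retroelement indel
is recognized by the ordered signature of repeat elements flanking its
insertion site, never by genome coordinates, which shift between
assemblies. A site matches when the telomeric flank string, then the
centromeric flank string, occur in annotation order within the configured
gaps; the content between the flanks is then compared against the
present-allele content (ordered, with an insertion-span check) and the
absent-allele relic. Calls are 2 (present), 1 (absent or solitary relic),
0 (uncallable — never an exception). The flagship discrimination is the
HERVK9 provirus: MER9/HERVK9-int/MER9 when present versus the single
recombined solitary MER9 when absent. STR loci are counted as the longest
pure tandem run of the motif starting in the locus (no mismatch tolerance —
unit counts are reported exactly). Cross-classifying HERVK9 and SVA-HB
yields the four ancestral lineages (HERVK9±/SVA-HB±). The shipped catalogue
(`data/markers.yaml`) defines 12 markers; HERVK9's flanks and content and
AluHG's flanks and TSD follow the published descriptions, while the other
markers' flank signatures are this package's own plausible stand-ins, since
no published per-marker signature list exists — they are editable YAML.

## Synthetic data: what it emulates and what it does not

`synthetic_data` generates the study conditions all tests run under:
a uniform-random ancestral sequence, sibling lineages derived by
independent per-site substitution at 7 SNPs/kb (mutated base uniform over
the three alternatives — no transition bias is modelled), mosaic haplotypes
concatenated from lineage blocks at configured breakpoints, private
within-lineage mutations at half the 1-per-100-kb pairwise rate per
haplotype, marker sites scaffolded from the same definitions the genotyper
reads, and artifacts (N-runs, ≥6-substitution clusters in 50 nt,
microsatellite overwrites, deletions). Every planted feature is recorded in
a truth table, and a fixed seed reproduces every output byte.

What it does not emulate: coalescent genealogies, recombination-rate maps,
selection, transition/transversion bias, real repeat landscapes (flank
cassettes are random sequence carrying the right annotation names), or HLA
coding alleles. Passing tests therefore demonstrate that the algorithms
recover planted truth under the stated density contrast and artifact model
— not that real assemblies meet those assumptions. One intrinsic
consequence of random background sequence: it genuinely contains ≥8-nt
homopolymers (about 18 per 400 kb) and occasional chance tandem runs, so a
few planted substitutions legitimately fall under the context filters; the
recovery tests account for exactly this.

## Numerical choices and degenerate inputs

* All randomness flows through one seeded `numpy` generator per run; seeds
  derived from a user seed stay below 2^31.
* Changepoint ties and chain-score ties break leftmost; output is invariant
  to permutation of the SNP input order.
* A region shorter than one window yields a single-window profile; zero
  SNPs on the sparse side puts the changepoint at the first dense SNP; a
  junction span without counted SNPs is reported as unrefinable rather than
  guessed.
* `anchor_align` refuses pairs with no unique shared 31-mers (too
  divergent or too repetitive) instead of returning a garbage chain.
* Uncallable marker sites return 0, mirroring the 0 code used for
  unresolvable rows in published marker matrices; a structural third state
  (duplicated/rearranged insertions) is deliberately not modelled.

## Problem sizes used by the test suite

Crossover recovery runs 100 seeded 400-kb simulations (1 SNP/100 kb vs
7 SNPs/kb, breakpoint at 200 kb) through the full align→call→filter→detect
path, requiring ≤2 kb localization error in ≥95 runs; observed error is
typically ~100 bp median. Aligner optimality is checked against an
independent quadratic-DP oracle on 50 pairs of 3–10 kb at ≤1% divergence
with one indel ≤500 bp. Marker recovery uses 100 panels of all 12 markers
with random genotypes. These sizes are the package's validation conditions;
the pipeline itself is routinely run on multi-megabase inputs.

## Known limitations

* Single-coverage, co-linear alignment only: inversions and translocations
  are invisible (they surface as unaligned segments).
* The changepoint model assumes one rate per side of a junction; gradual
  density ramps are localized at the likelihood optimum, which may not be a
  biologically meaningful point.
* Flank-signature genotyping depends on RepeatMasker naming conventions; a
  library change that renames families requires updating the alias table or
  the marker YAML.
* The anchor chain DP is quadratic in the number of anchors; for pairs at
  uniform high divergence (where anchors are dense but fragmented) it can
  become the dominant cost.
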