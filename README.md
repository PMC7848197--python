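# haploxo

SNP-density crossover mapping and dimorphic retroelement genotyping for
pairwise alignments of megabase-scale haplotype sequences.

Extended haplotypes of regions like the human MHC class I cluster are
mosaics of ancient ancestral blocks. When two phased assemblies share a
block, they are almost SNP-free across it (a SNP-poor region, **SPR**,
<20 counted SNPs per 100 kb); where their ancestry differs, divergence
jumps by orders of magnitude (a SNP-rich region, **SRR**, >100 per 100 kb,
averaging ~7 SNPs/kb). The junction where an alignment switches between
the two — a SNP-density crossover (XO) — marks a putative ancestral
recombination breakpoint. Historically these junctions were read by eye
from percentage-identity plots; `haploxo` automates the whole workflow for
people who work with phased assemblies of highly polymorphic regions:

1. **align** two near-identical long sequences into co-linear blocks
   (unique 31-mer anchors, highest-total-length chain, optimal
   edit-distance gap fill);
2. **call SNPs** and apply the classical manual-counting exclusions
   (dense clusters of >5 substitutions per 50 nt, sites within 50 bp of
   N-runs or long deletion strings, simple repeats, homopolymers);
3. **detect crossovers**: sliding-window SPR/SRR classification, then
   nucleotide-resolution refinement of each junction by maximizing the
   two-rate Poisson log-likelihood
   `n_L·log(n_L/ℓ_L) + n_R·log(n_R/ℓ_R)` over the candidate span;
4. **annotate** each junction against RepeatMasker tracks (containing or
   flanking elements, families within 10 kb, PRDM9-motif and TSD scans);
5. **genotype** dimorphic retroelement indels (Alu, SVA, HERV) from their
   flanking-element signatures — presence is allele 2, absence allele 1 —
   and partition haplotypes into the four HERVK9±/SVA-HB± ancestral
   lineages.

A first-class simulator (`haploxo.synthetic_data`) generates haplotype
mosaics with exact ground truth (breakpoints, planted SNPs, marker
genotypes, assembly artifacts), so every stage is testable without any
external download.

## Worked example

Simulate a 300-kb pair that shares ancestry on [0, 150 kb) and diverges
after, then run the pipeline:

```sh
haploxo simulate --length 300000 --breakpoint 150000 --seed 3 --out-dir sim1
haploxo run sim1/hapA.fasta sim1/hapB.fasta --out-dir run1
```

which prints

```
{'raw_snps': 1041, 'counted_snps': 1033, 'crossovers': 1, 'marker_genotypes': 0} (mosaic) -> run1/
```

1041 raw substitutions were called, 1033 survive the exclusion filters,
and one SPR↔SRR junction was found. `run1/crossovers.tsv` holds the call:

```
a_id  b_id  position_a  position_b  boundary_snp  direction  left_label  right_label  support_left  support_right
hapA  hapB  150288      150288      G/A           SPR->SRR   SPR         SRR          1             81
```

The junction is placed at position 150,288 — 288 bp from the planted
breakpoint — at a G/A boundary SNP, with 1 counted SNP in the 10 kb to its
left and 81 in the 10 kb to its right. `haploxo report run1` renders the
density strip (`X` marks windows containing the call):

```
     40000-140000     ==================== SPR               0.0/100kb
     50000-150000     ==================== SPR               1.0/100kb
     60000-160000     ~~~~~~~~~~~~~~~~~~~~ INTERMEDIATE     82.0/100kb X
     70000-170000     #################### SRR             146.0/100kb X
```

With RepeatMasker tracks (`--rm-out-a/--rm-out-b`) the same run also fills
the repeat context of each junction, writes the marker genotype matrix and
the lineage table. Each stage is available as its own subcommand
(`align`, `call-snps`, `detect-xo`, `annotate`, `genotype-markers`) reading
and writing plain TSV, and as library functions with the same names.

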