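# Dimorphic retroelement indel markers of the MHC class I region.
#
# Each marker is recognised by the ordered repeat-element signature flanking
# its insertion site in a RepeatMasker annotation track, never by genome
# coordinates (which shift between haplotype assemblies).  flank_tel is the
# telomeric flank string, flank_cen the centromeric one; present_content is
# the ordered element content of the insertion allele (call 2), and
# absent_content the solitary relic left on the empty allele (call 1), when
# any.  size_range_present bounds the insertion span in bp.
markers:
  - name: HERVK9
    # alpha block, between HLA-G and HLA-H; the empty allele carries the
    # solitary MER9 left by LTR-LTR recombination of the provirus
    flank_tel: [LTR16B2, MLT1F1, AluY, L1ME3]
    flank_cen: [Charlie9, Charlie9, L1PA10, MLT1F1, THE1C]
    present_content: [MER9, HERVK9-int, MER9]
    absent_content: [MER9]
    size_range_present: [5500, 7500]

  - name: SVA-HB
    # beta block, between HLA-C and HLA-B
    flank_tel: [AluSx, L1MB8]
    flank_cen: [MLT1D, AluJb]
    present_content: [SVA-HB]
    absent_content: []
    size_range_present: [700, 1900]

  - name: AluHG
    # between HLA-G and HLA-H, near the MICF pseudogene
    flank_tel: [FordPrefect]
    flank_cen: [HAL1]
    present_content: [AluY]
    absent_content: []
    size_range_present: [250, 350]
    tsd_motif: CACTTAAACAT

  - name: AluHF
    flank_tel: [ERV3-16A3_I]
    flank_cen: [LTR16B]
    present_content: [AluY]
    absent_content: []
    size_range_present: [250, 350]

  - name: AluHJ
    flank_tel: [L1PA7]
    flank_cen: [MER41B]
    present_content: [AluY]
    absent_content: []
    size_range_present: [250, 350]

  - name: AluOR
    flank_tel: [L1MC4]
    flank_cen: [MIRb]
    present_content: [AluY]
    absent_content: []
    size_range_present: [250, 350]

  - name: AluTF
    flank_tel: [MLT1A0]
    flank_cen: [L2a]
    present_content: [AluY]
    absent_content: []
    size_range_present: [250, 350]

  - name: AluMICB
    flank_tel: [MER5A]
    flank_cen: [L1MA9]
    present_content: [AluY]
    absent_content: []
    size_range_present: [250, 350]

  - name: SVA-HC
    flank_tel: [AluSg, MIRc]
    flank_cen: [L1PA13]
    present_content: [SVA-HC]
    absent_content: []
    size_range_present: [700, 1900]

  - name: SVA-HA
    flank_tel: [LTR13]
    flank_cen: [AluSq, L1MB3]
    present_content: [SVA-HA]
    absent_content: []
    size_range_present: [700, 1900]

  - name: SVA-MIC
    flank_tel: [THE1B]
    flank_cen: [LTR33, MER2]
    present_content: [SVA-MIC]
    absent_content: []
    size_range_present: [700, 2900]

  - name: MER5-LTR33-indel
    # the 9.5-kb structural indel between HLA-C and HLA-B
    flank_tel: [AluY, MLT1G3]
    flank_cen: [AluJb, MLT2C1]
    present_content: [MER5B, LTR33]
    absent_content: []
    size_range_present: [8500, 10500]
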