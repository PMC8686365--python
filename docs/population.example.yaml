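# Strain-spec schema for `matloci synth --spec <file>`.
#
# strains: list of strain recipes
#   strain_id:      unique name; output goes to strains/<strain_id>/
#   karyotype:      mono | di
#   hd_types:       1 (mono) or 2 (di) of Type1..Type4
#   hd_allele_ids:  allele labels per haplotype; same (type, allele) pair on
#                   both nuclei of a dikaryon is rejected (incompatible)
#   b_allele_ids:   P/R-locus allele labels (omit when with_pr is false)
#   with_pr:        also emit the ~22 kb P/R contig (default true)
strains:
  - strain_id: demo_mono
    karyotype: mono
    hd_types: [Type4]
    hd_allele_ids: [a1]
    b_allele_ids: [b1]
  - strain_id: demo_dik
    karyotype: di
    hd_types: [Type1, Type1]
    hd_allele_ids: [a1, a2]
    b_allele_ids: [b1, b2]
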