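# Mapping from variant-annotation consequence terms to the three effect classes
# used for mutation-burden counting. Editable: pass a custom mapping file to
# read_variant_table to override. Terms are matched case-insensitively after
# replacing spaces with underscores.
nonsynonymous:
  - missense
  - missense_mutation
  - missense_variant
  - nonsense
  - nonsense_mutation
  - stop_gained
  - stop_lost
  - nonstop_mutation
  - start_lost
  - translation_start_site
  - frameshift
  - frame_shift_del
  - frame_shift_ins
  - frameshift_variant
  - in_frame_del
  - in_frame_ins
  - inframe_deletion
  - inframe_insertion
  - splice_site
  - splice_acceptor_variant
  - splice_donor_variant
synonymous:
  - silent
  - synonymous
  - synonymous_variant
other:
  - intron
  - intron_variant
  - utr
  - 5'utr
  - 3'utr
  - 5_prime_utr_variant
  - 3_prime_utr_variant
  - igr
  - intergenic
  - rna
  - lincrna
  - noncoding
  - upstream_gene_variant
  - downstream_gene_variant
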