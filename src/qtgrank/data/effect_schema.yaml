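# Default mapping from annotation effect terms (SnpEff-style Sequence
# Ontology dialect) to binary per-gene polymorphism features.  A
# feature is set when a gene carries at least one variant with a
# matching term; rules with require_deleterious additionally demand a
# SIFT-style deleterious call.  Annotation dialects vary, so this file
# is a documented reconstruction and can be replaced per run.
is_nonsyn_deleterious:
  terms: [missense_variant, missense]
  require_deleterious: true
is_nonsyn:
  terms: [missense_variant, missense]
  require_deleterious: false
is_synonymous:
  terms: [synonymous_variant, synonymous]
  require_deleterious: false
is_frameshift:
  terms: [frameshift_variant, frameshift]
  require_deleterious: false
is_stop_gained:
  terms: [stop_gained]
  require_deleterious: false
is_stop_lost:
  terms: [stop_lost]
  require_deleterious: false
is_splice:
  terms: [splice_acceptor_variant, splice_donor_variant, splice_region_variant, splice]
  require_deleterious: false
is_utr:
  terms: [5_prime_UTR_variant, 3_prime_UTR_variant, UTR]
  require_deleterious: false
is_intron:
  terms: [intron_variant, intron]
  require_deleterious: false
is_upstream:
  terms: [upstream_gene_variant, upstream]
  require_deleterious: false
is_downstream:
  terms: [downstream_gene_variant, downstream]
  require_deleterious: false
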