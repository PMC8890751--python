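# Demo configuration for `vertmark run` — a small simulated marker bank
# (two groups: vertically evolving vs transfer-laden families).
seed: 11
taxa_per_domain: 6
stem_length: 2.0
domain_tree_height: 1.0
alignment_length: 200
gamma_shape: 0.5
gamma_categories: 4
bootstrap_replicates: 20
marker_groups:
  - {n: 6, n_transfers: 0, class: ribosomal}
  - {n: 6, n_transfers: 3, class: non_ribosomal}
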