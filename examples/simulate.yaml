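# Demo configuration for `vertmark simulate` — one gene family.
n_taxa_A: 6
n_taxa_B: 6
stem_length: 2.0
domain_tree_height: 1.0
n_transfers: 2
transfer_mode: inter_domain
alignment_length: 300
gamma_shape: 0.5
seed: 4
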