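# Example synthetic-scenario configuration for `ohnoscope simulate --spec`.
# A 2R gene family in which the single cyclostome gene is orthologous to
# the beta subtype and the fourth (delta) paralogue was lost.
pairing: [[alpha, delta], [beta, gamma]]
cyclostome_orthology: beta
losses: [delta]
species_per_subtype: 3
branch_length_scale: 1.0
alpha: 1.0
n_columns: 2000
seed: 0
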