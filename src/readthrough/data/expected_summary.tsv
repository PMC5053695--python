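field	value
n_species	52
n_gene_pairs	37
n_validated_as_predicted	28
n_sanger_isoforms	15
n_validated_events	43
n_validated_gene_pairs	35
n_frame_maintained	17
median_intergenic_bp	3941
n_validated_pairs_lt_1kb	7
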