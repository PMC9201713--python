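n_samples: 80
n_genes: 110
n_cell_types: 11
n_reps: 30
boruta_max_iter: 8
boruta_trees: 30
deconv_backend: nnls
n_drugs: 4
n_drug_lines: 40
gsea_perms: 50
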