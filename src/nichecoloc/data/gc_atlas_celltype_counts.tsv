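cell_type	n_cells
Erythrocytes	795
Plasma	26426
B	17605
Mast	6381
Myeloid	22617
CD8_T	71534
NK	24572
CD4_T	41994
Treg	11123
Endocrine	2884
Epithelial	44066
Endothelial	9323
Fibroblast	14094
Smooth_muscle	3465
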