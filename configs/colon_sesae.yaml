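# Stacked-autoencoder configuration for colon-cancer-shaped data
# (2000 genes, 62 samples, 2 classes). Two hidden layers of 100 nodes
# for every corruption parameter a = 1..5.
model: sesae
hidden_sizes: [100, 100]
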