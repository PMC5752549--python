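# Stacked-autoencoder configuration for breast-cancer-shaped data
# (30006 genes, 20 samples, 2 classes). Two hidden layers of 50 nodes
# for every corruption parameter a = 1..5.
model: sesae
hidden_sizes: [50, 50]
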