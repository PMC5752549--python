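# Stacked-autoencoder configuration for leukemia-shaped data
# (12600 genes, 60 samples, 4 classes). Two hidden layers of 30 nodes
# for every corruption parameter a = 1..5.
model: sesae
hidden_sizes: [30, 30]
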