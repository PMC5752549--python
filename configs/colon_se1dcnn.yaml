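# 1-D CNN configuration for colon-cancer-shaped data, a = 1 column.
# Published k1 per a = 1..5: 25, 5, 20, 12, 20; k2 per a: 20, 10, 7, 9, 5
# (kernel size 21 and pool width 4 in both stages for every a).
model: se1dcnn
k1: 25
k2: 20
w1: 21
w2: 21
p1: 4
p2: 4
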