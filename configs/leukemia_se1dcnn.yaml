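# 1-D CNN configuration for leukemia-shaped data, a = 1 column.
# Published k1 per a = 1..5: 22, 17, 22, 9, 17; k2 per a: 5, 5, 5, 16, 5
# (kernel size 21 and pool width 4 in both stages for every a).
model: se1dcnn
k1: 22
k2: 5
w1: 21
w2: 21
p1: 4
p2: 4
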