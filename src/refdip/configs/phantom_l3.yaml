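# desk-scale depth-3 hourglass for 64x64 phantoms
depth: 3
nd: [16, 32, 64]
nu: [16, 32, 64]
ns: [4, 4, 4]
kd: [3, 3, 3]
ku: [3, 3, 3]
ks: [1, 1, 1]
input_channels: 2
output_channels: 2
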