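# 512x512 acquisition: depth-5 hourglass
depth: 5
nd: [8, 16, 32, 64, 128]
nu: [8, 16, 32, 64, 128]
ns: [8, 8, 8, 8, 8]
kd: [3, 3, 3, 3, 3]
ku: [3, 3, 3, 3, 3]
ks: [1, 1, 1, 1, 1]
input_channels: 2
output_channels: 2
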