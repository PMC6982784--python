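# 256x256 acquisition: depth-6 hourglass
depth: 6
nd: [6, 32, 64, 128, 128, 128]
nu: [6, 32, 64, 128, 128, 128]
ns: [4, 4, 4, 4, 4, 4]
kd: [3, 3, 3, 3, 3, 3]
ku: [3, 3, 3, 3, 3, 3]
ks: [1, 1, 1, 1, 1, 1]
input_channels: 2
output_channels: 2
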