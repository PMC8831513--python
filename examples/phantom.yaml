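# 3-cm spherical cavity, 1 mm voxels, 2 mm wall shell
shape: sphere
radius: 1.5
spacing: [0.1, 0.1, 0.1]
wall_thickness: 0.2
seed: 0
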