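# Small demonstration sweep: one 3-cm spherical cavity, two wall absorptions,
# three Intralipid concentrations, no intracavity absorption (case 1).
phantoms:
  - shape: sphere
    radius: 1.5
    spacing: [0.1, 0.1, 0.1]
    wall_thickness: 0.2
    seed: 0
intralipid_pct: [0.0, 1.0, 2.3]
mua_wall: [0.2, 1.0]
n_photons: 20000
seed: 7
cases: [1]
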