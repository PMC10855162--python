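# Q-clean small-angle diffractogram of the sphere-in-solvent toy.
# structure/trajectory/species_db are supplied on the command line.
mode: diffract
wrapped: true
q: {min: 0.0, max: 1.0, count: 301, orientations: 100, seed: 1}
method: qclean
background:
  cut:
    box:
      edges: [20.0, 20.0, 20.0]
      center: [10.0, 10.0, 10.0]
      sld: 6.646          # solvent scattering length density
      sld_scale: 1.0e-5   # in units of 1e-5 A^-2
normalization: per-atom
output: toy_qclean.tsv
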