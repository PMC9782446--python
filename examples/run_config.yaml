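# Schematic run configuration (illustration of the format on a synthetic
# two-atom fixture; real dye configs list one wavefunction per medium and
# the fragment/pathway atom numbering of the actual molecule).
#
# Atom indices are 1-based, matching molecular-viewer numbering.
# Generate the referenced bundles first:
#   phenochrom fixtures --out examples/fixtures
dye: toy
scheme: npa          # npa | lowdin | mulliken | scpa
tau: 0.0             # indeterminate band on CT (%); 0 = strict sign
inputs:
  - {label: gas,   epsilon: 1.0,   path: examples/fixtures/two_fragment.json}
  - {label: H2O,   epsilon: 78.36, path: examples/fixtures/two_fragment.json}
fragments:
  X: [1]             # acceptor heterocycle atoms
  Y: [2]             # phenolate donor atoms
# pathways:          # ordered atom chains, phenolate oxygen first, e.g.
#   P-N: [12, 11, 9, 7, 5, 3, 1]
#   P-P: [12, 11, 9, 7, 5, 3, 2, 1]
out: examples/out
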