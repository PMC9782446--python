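# phenochrom

Predicting the solvatochromism of pyridinium phenolate dyes from
quantum-chemical wavefunctions.

## The problem

Phenolate–heterocycle dyes (Brooker's merocyanine, Reichardt's betaine and
their relatives) are the workhorse polarity sensors of solution chemistry,
but whether a new dye will be a **negative** (hypsochromic with polarity),
**positive** (bathochromic) or **inverted** (positive-to-negative switch at
an inversion point) solvatochrome cannot be read off its structure. The
ground state of such a donor–acceptor dye X–Y is a resonance mixture of a
charge-separated **zwitterionic** form (phenolate anion / pyridinium
cation) and a neutral **quinoid** form; which one dominates — and how the
balance shifts with medium permittivity ε — decides the solvatochromism.

`phenochrom` quantifies that balance from closed-shell DFT wavefunctions
(Molden files or a documented JSON bundle) computed in a series of
dielectric media, with three diagnostics:

* **BLA / BOA** — bond-length and bond-order alternation along a
  user-declared conjugation pathway of m bonds, enumerated from the
  phenolate oxygen:

  BLA = ⟨d<sub>even</sub>⟩ − ⟨d<sub>odd</sub>⟩,  BOA = ⟨B<sub>even</sub>⟩ − ⟨B<sub>odd</sub>⟩,

  with d the bond lengths and B the Mayer bond orders
  B<sub>AB</sub> = Σ<sub>a∈A</sub>Σ<sub>b∈B</sub> (PS)<sub>ab</sub>(PS)<sub>ba</sub>.
  Quinoid ground state ⇔ BLA > 0, BOA < 0; zwitterionic ⇔ BLA < 0, BOA > 0.

* **Fragment orbital compositions** — the percentage of each MO carried by
  the donor (Y, phenolate) and acceptor (X) fragments under Mulliken,
  Löwdin, SCPA or natural-atomic-orbital (NAO/NPA) partitions.

* **CT(%)** — the charge-transfer statistic of the HOMO→LUMO transition,

  CT(%) = %Y<sub>HOMO</sub> − %Y<sub>LUMO</sub> = 100·(P<sub>Y</sub><sup>g</sup> − P<sub>Y</sub><sup>e</sup>).

  CT > 0 (zwitterionic ground state) predicts negative solvatochromism,
  CT < 0 (quinoid) predicts positive, and a single −→+ sign change along
  ascending ε predicts inverted solvatochromism with the inversion at the
  first positive medium.

## Worked example

Classify a printed CT(%) series over the standard gas → CHCl₃ → Me₂SO →
H₂O grid (ε = 1, 4.71, 46.83, 78.36):

```
$ phenochrom classify --ct-values "-1.0 5.5 9.8 9.3" --dye brooker
{
  "dye": "brooker",
  "media": [
    {"label": "gas",   "epsilon": 1.0,   "ct": -1.0, "state": "quinoid"},
    {"label": "CHCl3", "epsilon": 4.71,  "ct": 5.5,  "state": "zwitterionic"},
    {"label": "Me2SO", "epsilon": 46.83, "ct": 9.8,  "state": "zwitterionic"},
    {"label": "H2O",   "epsilon": 78.36, "ct": 9.3,  "state": "zwitterionic"},
  ],
  "call": "inverted",
  "inversion_medium": "CHCl3",
  ...
}
```

The dye is quinoid in the gas phase (CT = −1.0 < 0) and zwitterionic in
every solvent, so it is called **inverted** with the inversion at the
gas → chloroform step — the classic behaviour of Brooker's merocyanine.

The same logic runs from wavefunctions: a YAML config lists one Molden
(or JSON-bundle) file per medium, the X/Y fragment split and any pathways
(atom indices 1-based, as in molecular viewers; see
`examples/run_config.yaml`), and

```
phenochrom composition --config run.yaml --scheme npa --out out/
phenochrom ct          --config run.yaml --out out/
phenochrom classify    --config run.yaml --out out/
phenochrom alternation --config run.yaml --out out/
```

write per-medium composition and BLA/BOA TSV reports plus the
classification JSON. Exit codes are stable: 0 success, 2 validation or
parse error, 3 numerical failure.

As a library:

```python
from phenochrom import (Fragment, TwoFragmentSpec, make_two_fragment_bundle,
                        mo_fragment_composition, ct_percent)

bundle = make_two_fragment_bundle(TwoFragmentSpec(theta_homo=60, theta_lumo=30))
comp = mo_fragment_composition(bundle, [Fragment("X", {0}), Fragment("Y", {1})], "npa")
print(ct_percent(comp, "Y"))   # 50.0  (= 100·(sin²60° − sin²30°))
```

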