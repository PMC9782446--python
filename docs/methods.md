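# Methods

## Scope and model

`phenochrom` analyses *given* closed-shell restricted wavefunctions; it
never runs SCF/DFT or implicit-solvation calculations itself. The intended
input is one converged wavefunction per dielectric medium — in the
benchmark setting, B3LYP/6-31G(d) with a polarizable-continuum solvent at
ε = 1 (gas), 4.71 (chloroform), 46.83 (dimethyl sulfoxide) and 78.36
(water) — exported as a Molden file. The analysis chain is:

1. ingest geometry, basis, MO coefficients and occupations (`qcio`);
2. build the AO overlap S and density P = C·diag(occ)·Cᵀ;
3. partition P and the frontier MOs over atoms and the X/Y fragments
   (`populations`);
4. measure bond-length/bond-order alternation along declared pathways
   (`alternation`);
5. map CT(%) or BLA/BOA sign patterns across the ε series to a
   solvatochromism call (`solvatochromism`).

## Overlap integrals

Primitive Cartesian Gaussian overlaps are evaluated with the standard
Obara–Saika 1-D recurrence (product of three 1-D factors with the
Gaussian-product prefactor), supporting s–f shells. Pure (spherical)
d and f functions are formed as fixed real-solid-harmonic combinations of
Cartesian monomials in the Molden m-order. Each contracted AO is built
from normalized primitives — the α-dependent axis normalization
(2α/π)^¾(4α)^{l/2}/√((2l−1)!!) fixes the relative primitive weights — and
then rescaled so its self-overlap is exactly 1. This per-AO
renormalization makes the result independent of the per-monomial
normalization convention of the emitting engine, for both Cartesian and
pure shells. The oracle for this machinery in the test suite is
brute-force grid quadrature of the AO products, plus the same-exponent
closed form S = exp(−αR²/2).

Angular momenta above f raise an unsupported-feature error; g-function
wavefunctions are out of scope. When a bundle carries both a basis and an
explicit overlap matrix the explicit matrix wins (a warning is logged):
this lets exactly constructed fixtures coexist with label-only bases.

## Partition schemes

With S the AO overlap, C the MO matrix and F a fragment's AO set:

* **mulliken**: 100·Σ_{a∈F}Σ_b C_ai S_ab C_bi. May leave [0, 100] for
  strongly overlapping bases; a warning is logged when it does.
* **lowdin**: 100·Σ_{a∈F} ((S^½C)_ai)². Bounded in [0, 100].
* **scpa**: 100·Σ_{a∈F} C_ai² / Σ_b C_bi² (coefficient-squared shares).
* **npa** (default): MO weights in an orthonormal natural-atomic-orbital
  basis, C′ = TᵀSC, percentages 100·Σ_{a∈F}(C′_ai)².

The NAO construction diagonalizes the per-atom, per-angular-momentum
blocks of the density in the atomic overlap metric (generalized
eigenproblem P_block v = λ S_block v) to obtain pre-NAOs with occupancies
λ, then orthogonalizes all pre-NAOs at once by occupancy-weighted
symmetric orthogonalization, T = N·W(W S′ W)^{−1/2} with W = diag(λ)
floored at 10⁻⁴ to keep the weighting nonsingular. High-occupancy
(core/lone-pair-like) orbitals are therefore distorted least, which is the
defining property of the natural-population construction. No separate
natural-minimal/Rydberg refinement loop is performed; against full NBO
software, deviations of order one electron-percent in fragment
compositions are expected, which is far below the CT sign structure the
classification uses. In the orthonormal limit S = I the construction
reduces exactly to the Löwdin partition — a property test pins this.

Natural populations conserve the electron count by construction
(TᵀST = I); Mulliken and Löwdin conservation are asserted to 10⁻⁶.

An overlap with condition number above 10¹⁰ aborts the NAO construction
with a numerical error advising basis review, rather than returning
silently garbage populations.

## Frontier orbitals

HOMO = highest-energy MO with occupation ≥ 1, LUMO = lowest-energy MO
with occupation < 1 (closed-shell inputs only, so the threshold is
uncritical). When MO energies are absent the MO index order is trusted.
If another occupied MO lies within 10⁻⁶ hartree of the HOMO *and* its
fragment composition differs by more than one percentage point, the
frontier assignment is ambiguous and an error is raised — a deliberate
refusal to guess, since a swapped HOMO could flip the CT sign.

## Alternation indices

Bonds along a declared pathway are enumerated from the phenolate C–O
bond. BLA is the mean of even-position bond lengths minus the mean of
odd-position lengths; BOA is the same functional on Mayer bond orders.
This is the unique mean-difference convention under which a quinoid
ground state (short C=O first, alternating) gives BLA > 0 and BOA < 0
while a zwitterionic state (long C–O single bond first) gives BLA < 0 and
BOA > 0. Two exact invariants are tested: shifting the enumeration parity
negates both indices, and uniform series give zero.

Pathways are *user input*, never auto-detected: which atoms are included
(phenolate→pyridinium-ring "P–P" vs phenolate→nitrogen "P–N") can change
the predicted solvatochromism for the same wavefunction — that
sensitivity is a finding the tool must expose, not hide. Validation only
guards against typos: consecutive pathway atoms must lie within 1.3 × the
sum of their Cordero covalent radii, and the first atom must be oxygen.
Config files use 1-based atom indices (molecular-viewer convention),
converted once at the CLI boundary. The example config shipped under
`examples/` is a schematic illustration of the format on a synthetic
fixture, not a transcription of any published dye's pathway.

## Classification

Per medium, the state is **zwitterionic** if CT > τ, **quinoid** if
CT < −τ, **indeterminate** otherwise; τ defaults to 0 (strict sign, the
benchmark convention) and is user-overridable. For BLA/BOA series the
state requires *both* signs to agree with one mesomer (BLA > 0 ∧ BOA < 0
quinoid; BLA < 0 ∧ BOA > 0 zwitterionic), anything else being
indeterminate. The series call is:

* all zwitterionic → **negative**;
* all quinoid → **positive**;
* any indeterminate → **borderline**;
* exactly one quinoid→zwitterionic switch, none back → **inverted**, with
  the inversion medium = first zwitterionic medium (an endpoint switch,
  e.g. gas→first solvent, qualifies);
* anything else (e.g. zwitterionic→quinoid) → **anomalous**.

Media are sorted by ε internally, so classification is invariant to input
order; gas phase participates as ε = 1 and sorts first. The
quinoid↔positive and zwitterionic↔negative mappings are hard-wired; what
the user controls is which fragment is the donor Y.

The character series reported for plotting is −CT (quinoid-minus-
zwitterionic), so quinoid-dominated dyes plot positive.

## Synthetic fixtures

No wavefunctions for real dyes are deposited anywhere, so the test suite
runs on constructions with closed-form answers:

* **two-fragment bundle** — two atoms, four orthonormal AOs, HOMO/LUMO
  mixing angles θ_H, θ_L; guarantees %Y_HOMO = 100·sin²θ_H,
  %Y_LUMO = 100·sin²θ_L and hence CT = 100(sin²θ_H − sin²θ_L) under all
  four schemes simultaneously. A seeded "skewed" variant installs a random
  SPD overlap and re-orthonormalizes the MOs, breaking the scheme
  degeneracy; the defining sums, written as explicit loops, are the oracle
  there.
* **alternating chains** — collinear O(C)ₙ geometries with bond lengths
  d_short/d_long; the tight-binding variant assigns larger hoppings to
  shorter bonds and doubly occupies the lowest ⌊n/2⌋ orbitals, so Mayer
  orders alternate opposite to lengths (sign(BLA) = −sign(BOA)) whenever
  the pattern admits a consistent Kekulé structure.
* **minimal-basis H₂** — one s Gaussian (α = 1.24) per atom; the overlap
  is analytic, the Mayer bond order is exactly 1 at any separation, and
  populations are (1, 1) by symmetry.

These fixtures pin the algebra exactly but are deliberately unphysical:
they contain no real dye geometry, no solvent response and no
electron-correlation content. Passing them demonstrates that the
partition/index/classification machinery is correct, not that any
particular DFT protocol reproduces experiment. The published benchmark
CT and BLA/BOA tables for the thirteen-dye library (shipped as reference
inputs) close part of that gap: classifying them end-to-end reproduces
the published calls, including the one documented misprediction (a
strongly twisted dye whose high X–Y interplanar angle biases CT toward
the zwitterionic side). Regenerating those tables from scratch requires
an external DFT/PCM engine at B3LYP/6-31G(d) emitting Molden files — a
documented recipe, not something this package automates.

## Numerical choices

* Lengths in Å, 1 bohr = 0.529177210903 Å; exponents in bohr⁻².
* Bundle invariants enforced at 10⁻⁶ (occupation sum, occupied-MO
  orthonormality), overlap diagonal at 10⁻¹⁰.
* Pre-NAO occupancy floor 10⁻⁴; overlap condition-number guard 10¹⁰.
* Classification τ default 0; the degeneracy guard 10⁻⁶ hartree / 1 %.
* Acceptance measurements use 8 seeded skewed fixtures × 4 schemes —
  small enough to run in seconds, large enough to exercise every scheme
  off the orthonormal limit.

## Known limitations

Closed-shell restricted wavefunctions only (no open-shell spin
populations); s–f shells, no effective-core potentials; no NBO bond/lone-
pair search or Wiberg indices; no prediction of absorption wavelengths or
of *where* (in solvent-polarity terms) an inversion occurs beyond the
supplied media grid; implicit-solvent inputs ignore specific
solute–solvent interactions such as hydrogen bonds, and dyes with large
donor–acceptor interplanar twists are systematically biased toward the
zwitterionic (negative-solvatochromism) call.
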