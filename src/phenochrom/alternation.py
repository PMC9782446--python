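"""Conjugation pathways and the bond-length / bond-order alternation indices.

A pathway is a user-declared ordered chain of atoms starting at the
phenolate oxygen — conventionally the P–P path (phenolate to pyridinium
ring) or the P–N path (phenolate to the quaternary nitrogen only).  Along
a validated pathway of m bonds, with bonds enumerated from the phenolate
C–O bond:

    BLA = mean(d at even bond positions 2,4,…) − mean(d at odd positions)
    BOA = the same mean difference on Mayer bond orders

Under this oxygen-first convention a quinoid ground state (short C=O
first) gives BLA > 0 and BOA < 0, while a zwitterionic, charge-separated
ground state (long C–O single bond first) gives BLA < 0 and BOA > 0 —
the sign semantics the solvatochromism classifier relies on.

Pathways are never auto-detected: which atoms are included changes the
prediction, so the chain is explicit user input and validation only
guards against typos (consecutive atoms must sit within 1.3 × the sum of
their covalent radii).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .qcio import Geometry, WavefunctionBundle
from .populations import density_matrix, mayer_bond_orders

#: Single-bond covalent radii (Å), Cordero et al. consensus values.
COVALENT_RADII = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76,
    "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58, "Na": 1.66, "Mg": 1.41,
    "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Fe": 1.32, "Zn": 1.22, "Se": 1.20, "Br": 1.20,
    "I": 1.39,
}

BOND_CUTOFF_FACTOR = 1.3


@dataclass(frozen=True)
class Pathway:
    """Ordered conjugation path; the first atom must be the phenolate oxygen."""

    name: str
    atom_indices: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "atom_indices", tuple(int(i) for i in self.atom_indices))
        if len(self.atom_indices) < 3:
            raise ValidationError(
                f"pathway {self.name!r} needs at least 3 atoms, "
                f"got {len(self.atom_indices)}"
            )
        if len(set(self.atom_indices)) != len(self.atom_indices):
            raise ValidationError(f"pathway {self.name!r} repeats an atom")

    @property
    def n_bonds(self) -> int:
        return len(self.atom_indices) - 1

    def bonds(self) -> list[tuple[int, int]]:
        idx = self.atom_indices
        return [(idx[k], idx[k + 1]) for k in range(self.n_bonds)]


@dataclass(frozen=True)
class AlternationProfile:
    """Per-bond lengths and Mayer orders along a pathway, with BLA and BOA."""

    pathway: Pathway
    bond_lengths: tuple[float, ...]   # Å, first entry is the O–C bond
    bond_orders: tuple[float, ...]    # Mayer, dimensionless
    bla: float                        # Å
    boa: float                        # dimensionless

    def __post_init__(self):
        m = self.pathway.n_bonds
        if len(self.bond_lengths) != m or len(self.bond_orders) != m:
            raise ValidationError("profile lists must match the pathway bond count")
        if any(d <= 0 for d in self.bond_lengths):
            raise ValidationError("bond lengths must be positive")
        if not (np.isfinite(self.bla) and np.isfinite(self.boa)):
            raise ValidationError("BLA/BOA must be finite")


def validate_pathway(geometry: Geometry, pathway: Pathway) -> Pathway:
    """Check oxygen-first convention and bonded consecutive pairs."""
    for i in pathway.atom_indices:
        if not 0 <= i < geometry.n_atoms:
            raise ValidationError(
                f"pathway {pathway.name!r} references atom {i} outside the "
                f"{geometry.n_atoms}-atom geometry"
            )
    first = geometry.elements[pathway.atom_indices[0]]
    if first != "O":
        raise ValidationError(
            f"pathway {pathway.name!r} must start at the phenolate oxygen; "
            f"first atom is {first}"
        )
    for i, j in pathway.bonds():
        d = geometry.distance(i, j)
        ri = COVALENT_RADII.get(geometry.elements[i])
        rj = COVALENT_RADII.get(geometry.elements[j])
        if ri is None or rj is None:
            raise ValidationError(
                f"no covalent radius tabulated for "
                f"{geometry.elements[i]}/{geometry.elements[j]}"
            )
        cutoff = BOND_CUTOFF_FACTOR * (ri + rj)
        if d > cutoff:
            raise ValidationError(
                f"pathway {pathway.name!r}: atoms {i} and {j} are {d:.3f} Å "
                f"apart, beyond the bonding cutoff {cutoff:.3f} Å"
            )
    return pathway


def _alternation(values: Sequence[float]) -> float:
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("alternation index needs at least 2 bonds")
    # bond 1 is v[0]; odd positions are v[0::2], even positions v[1::2]
    return float(v[1::2].mean() - v[0::2].mean())


def compute_bla(bond_lengths: Sequence[float]) -> float:
    """Bond-length alternation (Å), oxygen-first bond enumeration."""
    return _alternation(bond_lengths)


def compute_boa(bond_orders: Sequence[float]) -> float:
    """Bond-order alternation (dimensionless), same enumeration as BLA."""
    return _alternation(bond_orders)


def alternation_profile(
    bundle: WavefunctionBundle, pathway: Pathway
) -> AlternationProfile:
    """Measure bond lengths and Mayer orders along a validated pathway."""
    validate_pathway(bundle.geometry, pathway)
    if bundle.ao_map is None:
        raise ValidationError("bundle has no AO index map for Mayer orders")
    lengths = tuple(bundle.geometry.distance(i, j) for i, j in pathway.bonds())
    P = density_matrix(bundle)
    S = bundle.overlap_matrix()
    B = mayer_bond_orders(P, S, bundle.ao_map)
    orders = tuple(B.order(i, j) for i, j in pathway.bonds())
    return AlternationProfile(
        pathway=pathway,
        bond_lengths=lengths,
        bond_orders=orders,
        bla=compute_bla(lengths),
        boa=compute_boa(orders),
    )


def profile_table(profile: AlternationProfile, medium=None) -> str:
    """Render a profile as the per-medium TSV report."""
    lines = []
    if medium is not None:
        lines.append(f"# medium\t{medium.label}")
        lines.append(f"# epsilon\t{medium.epsilon}")
    lines.append(f"# pathway\t{profile.pathway.name}")
    lines.append("bond_index\tatom_i\tatom_j\tlength_angstrom\tmayer_order")
    for k, (i, j) in enumerate(profile.pathway.bonds(), start=1):
        lines.append(
            f"{k}\t{i}\t{j}\t{profile.bond_lengths[k - 1]:.6f}"
            f"\t{profile.bond_orders[k - 1]:.6f}"
        )
    lines.append(f"bla={profile.bla:.6f}")
    lines.append(f"boa={profile.boa:.6f}")
    return "\n".join(lines) + "\n"
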