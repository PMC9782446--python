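"""Synthetic wavefunctions and geometries with closed-form expected values.

No deposited wavefunctions exist for the dye library, so every analysis
operation is exercised on constructions whose answers are known exactly:

* a two-atom, four-AO "two-fragment" bundle with an identity overlap,
  where the HOMO/LUMO mixing angles fix the fragment compositions to
  %Y_HOMO = 100·sin²θ_H and %Y_LUMO = 100·sin²θ_L under every partition
  scheme, hence CT = 100·(sin²θ_H − sin²θ_L);
* collinear alternating-bond chains (oxygen first) whose BLA is the
  half-difference pattern by construction;
* minimal-basis H₂ (one s primitive per atom, exponent 1.24), whose
  overlap has the same-exponent closed form exp(−αR²/2) and whose Mayer
  bond order is exactly 1 for any separation.

These fixtures deliberately do not attempt chemical realism; they pin
down the algebra, not the chemistry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .qcio import (
    BOHR_TO_ANGSTROM,
    Geometry,
    Medium,
    GAS_PHASE,
    Shell,
    ShellBasis,
    WavefunctionBundle,
)
from .alternation import Pathway


@dataclass(frozen=True)
class TwoFragmentSpec:
    """Mixing angles (degrees) and options for the two-fragment toy bundle."""

    theta_homo: float = 60.0
    theta_lumo: float = 30.0
    n_spectator_mos: int = 0
    seed: int = 0

    def __post_init__(self):
        for name, v in (("theta_homo", self.theta_homo),
                        ("theta_lumo", self.theta_lumo)):
            if not 0.0 <= v <= 90.0:
                raise ValidationError(f"{name} must lie in [0, 90] degrees, got {v}")
        if not 0 <= self.n_spectator_mos <= 2:
            raise ValidationError("n_spectator_mos must be 0, 1 or 2")


@dataclass(frozen=True)
class ChainSpec:
    """Geometry of a collinear alternating-bond chain, oxygen first."""

    n_atoms: int = 5
    d_short: float = 1.34
    d_long: float = 1.46
    first_bond: str = "short"
    elements: tuple[str, ...] = ()

    def __post_init__(self):
        if self.n_atoms < 3:
            raise ValidationError("chain needs at least 3 atoms")
        if not (0 < self.d_short <= self.d_long):
            raise ValidationError("need 0 < d_short ≤ d_long")
        if self.first_bond not in ("short", "long"):
            raise ValidationError("first_bond must be 'short' or 'long'")


def make_two_fragment_bundle(
    spec: TwoFragmentSpec = TwoFragmentSpec(),
    medium: Medium = GAS_PHASE,
) -> WavefunctionBundle:
    """Two-fragment toy bundle with scheme-independent closed forms.

    Atom 0 (fragment X) carries orthonormal AOs {0, 1}; atom 1 (fragment Y)
    carries AOs {2, 3}.  HOMO = cosθ_H·φ0 + sinθ_H·φ2 (occupation 2),
    LUMO = cosθ_L·φ1 + sinθ_L·φ3 (occupation 0); the overlap is the
    identity, so Mulliken, Löwdin, SCPA and NAO compositions coincide.
    Spectator MOs span the orthogonal complement and are left virtual.
    """
    th = math.radians(spec.theta_homo)
    tl = math.radians(spec.theta_lumo)
    cols = [
        [math.cos(th), 0.0, math.sin(th), 0.0],   # HOMO
        [0.0, math.cos(tl), 0.0, math.sin(tl)],   # LUMO
    ]
    occupations = [2.0, 0.0]
    energies = [-0.30, 0.05]
    complements = [
        [-math.sin(th), 0.0, math.cos(th), 0.0],
        [0.0, -math.sin(tl), 0.0, math.cos(tl)],
    ]
    for k in range(spec.n_spectator_mos):
        cols.append(complements[k])
        occupations.append(0.0)
        energies.append(0.2 + 0.1 * k)

    geometry = Geometry(("C", "O"), np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]]))
    # label basis: two s shells per atom, giving the AO map and angular-
    # momentum labels NAO needs; the explicit identity overlap takes
    # precedence over anything this basis would integrate to.
    basis = ShellBasis(tuple(
        Shell(atom, "s", (expnt,), (1.0,))
        for atom in (0, 1) for expnt in (1.0, 0.5)
    ))
    bundle = WavefunctionBundle(
        geometry=geometry,
        basis=basis,
        mo_coefficients=np.array(cols, dtype=float).T,
        occupations=np.array(occupations),
        mo_energies=np.array(energies),
        overlap=np.eye(4),
        medium=medium,
    )
    bundle.validate()
    return bundle


def skew_overlap(bundle: WavefunctionBundle, seed: int = 0,
                 strength: float = 0.3) -> WavefunctionBundle:
    """Replace the overlap by a random SPD matrix and re-orthonormalize MOs.

    Breaks the orthonormal-limit degeneracy between the partition schemes
    while keeping every bundle invariant intact; the brute-force defining
    sums remain the oracle for compositions on the result.
    """
    rng = np.random.default_rng(seed)
    n = bundle.n_ao
    A = rng.normal(size=(n, n))
    S = np.eye(n) + strength * (A @ A.T) / n
    # symmetric orthonormalization of the MO columns in the S metric
    C = bundle.mo_coefficients
    G = C.T @ S @ C
    w, V = np.linalg.eigh(G)
    C_new = C @ (V / np.sqrt(w)) @ V.T
    out = WavefunctionBundle(
        geometry=bundle.geometry,
        basis=bundle.basis,
        mo_coefficients=C_new,
        occupations=bundle.occupations.copy(),
        mo_energies=(bundle.mo_energies.copy()
                     if bundle.mo_energies is not None else None),
        overlap=S,
        medium=bundle.medium,
    )
    out.validate()
    return out


def make_alternating_chain(spec: ChainSpec = ChainSpec()) -> tuple[Geometry, Pathway]:
    """Collinear chain with alternating bond lengths and a full-span pathway."""
    elements = spec.elements or ("O",) + ("C",) * (spec.n_atoms - 1)
    if len(elements) != spec.n_atoms:
        raise ValidationError("elements length must equal n_atoms")
    pair = ((spec.d_short, spec.d_long) if spec.first_bond == "short"
            else (spec.d_long, spec.d_short))
    x = [0.0]
    for k in range(spec.n_atoms - 1):
        x.append(x[-1] + pair[k % 2])
    coords = np.column_stack([x, np.zeros(spec.n_atoms), np.zeros(spec.n_atoms)])
    geometry = Geometry(tuple(elements), coords)
    pathway = Pathway("custom", tuple(range(spec.n_atoms)))
    return geometry, pathway


def make_chain_bundle(spec: ChainSpec = ChainSpec()) -> tuple[WavefunctionBundle, Pathway]:
    """Alternating chain with a tight-binding π wavefunction (one AO/atom).

    Bond strengths follow the geometry — shorter bonds get the larger
    hopping — so the Mayer orders alternate oppositely to the lengths and
    the profile shows the physical sign coupling sign(BLA) = −sign(BOA).
    The AO basis is orthonormal (identity overlap) with one s-labelled
    function per atom; the lowest ⌊n/2⌋ orbitals are doubly occupied.
    """
    geometry, pathway = make_alternating_chain(spec)
    n = spec.n_atoms
    H = np.zeros((n, n))
    for k in range(n - 1):
        d = geometry.distance(k, k + 1)
        beta = -1.0 - 0.5 * (spec.d_long - d) / max(spec.d_long - spec.d_short, 1e-12)
        H[k, k + 1] = H[k + 1, k] = beta
    w, V = np.linalg.eigh(H)
    n_occ = n // 2
    occupations = np.array([2.0] * n_occ + [0.0] * (n - n_occ))
    basis = ShellBasis(tuple(Shell(a, "s", (1.0,), (1.0,)) for a in range(n)))
    bundle = WavefunctionBundle(
        geometry=geometry,
        basis=basis,
        mo_coefficients=V,
        occupations=occupations,
        mo_energies=w,
        overlap=np.eye(n),
        medium=GAS_PHASE,
    )
    bundle.validate()
    return bundle, pathway


H2_EXPONENT = 1.24  # bohr⁻², the classic single-Gaussian 1s exponent for H


def make_h2_minimal(separation: float = 0.74) -> WavefunctionBundle:
    """Minimal-basis H₂: one normalized s Gaussian per atom, bonding MO.

    ``separation`` is in Å.  The normalized same-exponent overlap is
    s = exp(−α R²/2) with R in bohr, and the doubly occupied bonding MO
    (t, t) with t = 1/√(2(1+s)) gives Mulliken populations (1, 1) and a
    Mayer bond order of exactly 1 at any separation.
    """
    if separation <= 0:
        raise ValidationError("separation must be positive")
    geometry = Geometry(
        ("H", "H"), np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]])
    )
    basis = ShellBasis((
        Shell(0, "s", (H2_EXPONENT,), (1.0,)),
        Shell(1, "s", (H2_EXPONENT,), (1.0,)),
    ))
    r_bohr = separation / BOHR_TO_ANGSTROM
    s = math.exp(-H2_EXPONENT * r_bohr ** 2 / 2.0)
    t_b = 1.0 / math.sqrt(2.0 * (1.0 + s))
    t_a = 1.0 / math.sqrt(2.0 * (1.0 - s))
    C = np.array([[t_b, t_a], [t_b, -t_a]])
    S = np.array([[1.0, s], [s, 1.0]])
    bundle = WavefunctionBundle(
        geometry=geometry,
        basis=basis,
        mo_coefficients=C,
        occupations=np.array([2.0, 0.0]),
        mo_energies=np.array([-0.5, 0.3]),
        overlap=S,
        medium=GAS_PHASE,
    )
    bundle.validate()
    return bundle
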