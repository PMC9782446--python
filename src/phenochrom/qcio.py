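"""Wavefunction ingestion and analytic Gaussian overlap integrals.

This module defines the in-memory containers consumed by every analysis
step — molecular geometry, contracted Gaussian shell basis, medium, and the
:class:`WavefunctionBundle` tying geometry, basis, MO coefficients and
occupations together — plus three I/O surfaces:

* ``read_molden`` / ``write_molden``: the Molden interchange format emitted
  by most quantum-chemistry engines ([Atoms], [GTO], [MO] sections, with
  the [5D]/[7F] spherical-harmonic dialect flags).
* ``write_bundle`` / ``read_bundle``: a documented JSON bundle used for
  fixtures and caching.
* ``compute_overlap``: the AO overlap matrix from the shell basis, via the
  Obara–Saika 1-D recurrence on Cartesian primitives with real
  solid-harmonic contraction for pure d/f shells.

Internal conventions: lengths in Å (1 bohr = 0.529177210903 Å), AO order
follows the Molden convention (shells as listed; p as x,y,z; Cartesian d as
xx,yy,zz,xy,xz,yz; pure shells in Molden m-order), all indices 0-based.
Only closed-shell restricted wavefunctions are accepted.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    ParseError,
    UnsupportedFeatureError,
    ValidationError,
)

logger = logging.getLogger(__name__)

BOHR_TO_ANGSTROM = 0.529177210903

_ANGULAR_MOMENTUM = {"s": 0, "p": 1, "d": 2, "f": 3}
_L_LETTER = {v: k for k, v in _ANGULAR_MOMENTUM.items()}

# Molden component orders for Cartesian shells, as (lx, ly, lz).
_CARTESIAN_COMPONENTS = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1)],
    3: [
        (3, 0, 0), (0, 3, 0), (0, 0, 3), (1, 2, 0), (2, 1, 0),
        (2, 0, 1), (1, 0, 2), (0, 1, 2), (0, 2, 1), (1, 1, 1),
    ],
}

# Real solid harmonics as monomial combinations, Molden m-order
# (m = 0, +1, -1, +2, -2, ...).  Only relative coefficients matter: every
# contracted AO is renormalized to unit self-overlap afterwards.
_SPHERICAL_COMBOS = {
    2: [
        [((0, 0, 2), 2.0), ((2, 0, 0), -1.0), ((0, 2, 0), -1.0)],   # d0
        [((1, 0, 1), 1.0)],                                          # d+1
        [((0, 1, 1), 1.0)],                                          # d-1
        [((2, 0, 0), 1.0), ((0, 2, 0), -1.0)],                       # d+2
        [((1, 1, 0), 1.0)],                                          # d-2
    ],
    3: [
        [((0, 0, 3), 2.0), ((2, 0, 1), -3.0), ((0, 2, 1), -3.0)],    # f0
        [((1, 0, 2), 4.0), ((3, 0, 0), -1.0), ((1, 2, 0), -1.0)],    # f+1
        [((0, 1, 2), 4.0), ((0, 3, 0), -1.0), ((2, 1, 0), -1.0)],    # f-1
        [((2, 0, 1), 1.0), ((0, 2, 1), -1.0)],                       # f+2
        [((1, 1, 1), 1.0)],                                          # f-2
        [((3, 0, 0), 1.0), ((1, 2, 0), -3.0)],                       # f+3
        [((2, 1, 0), 3.0), ((0, 3, 0), -1.0)],                       # f-3
    ],
}

_ELEMENT_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Br": 35, "I": 53,
    "Se": 34, "Zn": 30, "Fe": 26,
}
_NUMBER_ELEMENTS = {v: k for k, v in _ELEMENT_NUMBERS.items()}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Geometry:
    """Molecular geometry: element symbols and Cartesian coordinates in Å."""

    elements: tuple[str, ...]
    coordinates: np.ndarray  # (n_atoms, 3), Å

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "elements", tuple(self.elements))
        if len(self.elements) < 1:
            raise ValidationError("geometry must contain at least one atom")
        if coords.shape != (len(self.elements), 3):
            raise ValidationError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.elements)} elements"
            )
        if not np.all(np.isfinite(coords)):
            raise ValidationError("geometry contains non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coordinates[i] - self.coordinates[j]))


@dataclass(frozen=True)
class Shell:
    """One contracted Gaussian shell attached to an atom.

    Exponents are in bohr⁻²; contraction coefficients refer to normalized
    primitives.  ``spherical`` selects pure (2l+1) vs Cartesian components
    and is ignored for s and p shells.
    """

    atom_index: int
    l: str
    exponents: tuple[float, ...]
    coefficients: tuple[float, ...]
    spherical: bool = False

    def __post_init__(self):
        if self.l not in _ANGULAR_MOMENTUM:
            raise UnsupportedFeatureError(
                f"angular momentum '{self.l}' not supported (s through f only)"
            )
        object.__setattr__(self, "exponents", tuple(float(e) for e in self.exponents))
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))
        if len(self.exponents) == 0:
            raise ValidationError("shell must contain at least one primitive")
        if len(self.exponents) != len(self.coefficients):
            raise ValidationError("exponent/coefficient count mismatch in shell")
        if any(e <= 0 for e in self.exponents):
            raise ValidationError("shell exponents must be strictly positive")

    @property
    def l_value(self) -> int:
        return _ANGULAR_MOMENTUM[self.l]

    @property
    def n_components(self) -> int:
        lv = self.l_value
        if lv <= 1 or not self.spherical:
            return len(_CARTESIAN_COMPONENTS[lv])
        return 2 * lv + 1


@dataclass(frozen=True)
class ShellBasis:
    """Ordered list of contracted shells; AO order follows shell order."""

    shells: tuple[Shell, ...]

    def __post_init__(self):
        object.__setattr__(self, "shells", tuple(self.shells))
        if not self.shells:
            raise ValidationError("basis must contain at least one shell")

    def validate_against(self, geometry: Geometry) -> None:
        for sh in self.shells:
            if not 0 <= sh.atom_index < geometry.n_atoms:
                raise ValidationError(
                    f"shell references atom {sh.atom_index} outside geometry "
                    f"of {geometry.n_atoms} atoms"
                )

    @property
    def n_ao(self) -> int:
        return sum(sh.n_components for sh in self.shells)

    def ao_labels(self) -> list[tuple[int, str]]:
        """Per-AO (atom_index, angular-momentum letter), in AO order."""
        labels = []
        for sh in self.shells:
            labels.extend([(sh.atom_index, sh.l)] * sh.n_components)
        return labels

    def ao_map(self, n_atoms: Optional[int] = None) -> dict[int, list[int]]:
        """Mapping atom index → list of AO indices (the AOIndexMap)."""
        n = n_atoms if n_atoms is not None else (
            max(sh.atom_index for sh in self.shells) + 1
        )
        amap: dict[int, list[int]] = {a: [] for a in range(n)}
        for idx, (atom, _l) in enumerate(self.ao_labels()):
            amap[atom].append(idx)
        return amap


def validate_ao_map(ao_map: dict[int, list[int]], n_ao: int) -> None:
    """Check that the per-atom AO lists are disjoint and cover 0..n_ao-1."""
    seen: list[int] = []
    for indices in ao_map.values():
        seen.extend(indices)
    if sorted(seen) != list(range(n_ao)):
        raise ValidationError(
            "AO index map must partition 0..n_AO-1 into disjoint per-atom lists"
        )


@dataclass(frozen=True)
class Medium:
    """A dielectric environment: label and relative permittivity ε ≥ 1."""

    label: str
    epsilon: float

    def __post_init__(self):
        if not np.isfinite(self.epsilon) or self.epsilon < 1.0:
            raise ValidationError(
                f"relative permittivity must be ≥ 1 (gas phase = 1.0), "
                f"got {self.epsilon}"
            )


GAS_PHASE = Medium("gas", 1.0)


@dataclass
class WavefunctionBundle:
    """A closed-shell restricted wavefunction plus its medium.

    ``mo_coefficients`` is (n_AO × n_MO) with MOs in columns, expressed in
    the AO basis.  ``overlap`` may be supplied explicitly; when both a basis
    and an explicit overlap are present the explicit matrix wins.
    """

    geometry: Geometry
    mo_coefficients: np.ndarray
    occupations: np.ndarray
    medium: Medium = GAS_PHASE
    basis: Optional[ShellBasis] = None
    overlap: Optional[np.ndarray] = None
    mo_energies: Optional[np.ndarray] = None
    ao_map: Optional[dict[int, list[int]]] = None

    def __post_init__(self):
        self.mo_coefficients = np.asarray(self.mo_coefficients, dtype=float)
        self.occupations = np.asarray(self.occupations, dtype=float)
        if self.mo_energies is not None:
            self.mo_energies = np.asarray(self.mo_energies, dtype=float)
        if self.overlap is not None:
            self.overlap = np.asarray(self.overlap, dtype=float)
        if self.ao_map is None:
            if self.basis is not None:
                self.ao_map = self.basis.ao_map(self.geometry.n_atoms)
        if self.basis is not None and self.overlap is not None:
            logger.warning(
                "bundle carries both a basis and an explicit overlap matrix; "
                "the explicit matrix takes precedence"
            )

    @property
    def n_ao(self) -> int:
        return self.mo_coefficients.shape[0]

    @property
    def n_mo(self) -> int:
        return self.mo_coefficients.shape[1]

    @property
    def n_electrons(self) -> int:
        return int(round(float(self.occupations.sum())))

    def overlap_matrix(self) -> np.ndarray:
        """Resolve the AO overlap: explicit matrix wins over the basis."""
        if self.overlap is not None:
            return self.overlap
        if self.basis is not None:
            self.overlap = compute_overlap(self.geometry, self.basis)
            return self.overlap
        raise ConfigurationError(
            "bundle has neither an explicit overlap matrix nor a basis "
            "to compute one from"
        )

    def validate(self, tol: float = 1e-6) -> None:
        """Enforce the closed-shell bundle invariants."""
        if self.mo_coefficients.ndim != 2:
            raise ValidationError("mo_coefficients must be a 2-D matrix")
        if self.occupations.shape != (self.n_mo,):
            raise ValidationError(
                f"occupation vector length {self.occupations.shape} does not "
                f"match {self.n_mo} MOs"
            )
        occ = self.occupations
        if np.any(occ < -tol) or np.any(occ > 2 + tol):
            raise ValidationError("occupations must lie in [0, 2]")
        fractional = (occ > tol) & (occ < 2 - tol)
        if np.any(fractional):
            raise ValidationError(
                "fractional occupations found: only closed-shell restricted "
                "wavefunctions are supported"
            )
        total = float(occ.sum())
        nearest = round(total)
        if abs(total - nearest) > tol or nearest % 2 != 0:
            raise ValidationError(
                f"occupation sum {total} is not an even integer electron count"
            )
        if self.mo_energies is not None and self.mo_energies.shape != (self.n_mo,):
            raise ValidationError("mo_energies length does not match MO count")
        if self.overlap is not None or self.basis is not None:
            S = self.overlap_matrix()
            if S.shape != (self.n_ao, self.n_ao):
                raise ValidationError("overlap dimension does not match AO count")
            occ_cols = self.mo_coefficients[:, occ > 1.0]
            if occ_cols.size:
                gram = occ_cols.T @ S @ occ_cols
                if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-6):
                    raise ValidationError(
                        "occupied MOs are not orthonormal under the overlap "
                        "metric (CᵀSC ≠ I)"
                    )
        if self.ao_map is not None:
            validate_ao_map(self.ao_map, self.n_ao)


# ---------------------------------------------------------------------------
# Overlap integrals
# ---------------------------------------------------------------------------

def _overlap_1d(la: int, lb: int, pa: float, pb: float, p: float) -> np.ndarray:
    """Obara–Saika table of 1-D overlap factors E(i,j) up to (la, lb).

    E(0,0) = 1; the Gaussian prefactor is applied by the caller.
    """
    E = np.zeros((la + 1, lb + 1))
    E[0, 0] = 1.0
    inv2p = 1.0 / (2.0 * p)
    for i in range(1, la + 1):
        E[i, 0] = pa * E[i - 1, 0] + (i - 1) * inv2p * E[i - 2, 0] if i >= 2 else pa * E[0, 0]
    for j in range(1, lb + 1):
        for i in range(la + 1):
            term = pb * E[i, j - 1]
            if j >= 2:
                term += (j - 1) * inv2p * E[i, j - 2]
            if i >= 1:
                term += i * inv2p * E[i - 1, j - 1]
            E[i, j] = term
    return E


def _primitive_monomial_overlap(
    alpha: float, lmn_a: tuple[int, int, int], A: np.ndarray,
    beta: float, lmn_b: tuple[int, int, int], B: np.ndarray,
) -> float:
    """Overlap of two unnormalized Cartesian Gaussian monomials (bohr units)."""
    p = alpha + beta
    mu = alpha * beta / p
    AB = A - B
    P = (alpha * A + beta * B) / p
    pref = (math.pi / p) ** 1.5 * math.exp(-mu * float(AB @ AB))
    out = pref
    for dim in range(3):
        la, lb = lmn_a[dim], lmn_b[dim]
        E = _overlap_1d(la, lb, float(P[dim] - A[dim]), float(P[dim] - B[dim]), p)
        out *= E[la, lb]
    return out


def _axis_primitive_norm(alpha: float, l: int) -> float:
    """Normalization constant of an axis Cartesian primitive x^l·exp(-αr²)."""
    df = 1.0
    for k in range(2 * l - 1, 0, -2):
        df *= k
    return (2.0 * alpha / math.pi) ** 0.75 * (4.0 * alpha) ** (l / 2.0) / math.sqrt(df)


def _ao_expansion(shell: Shell) -> list[list[tuple[float, float, tuple[int, int, int]]]]:
    """Expand a shell into per-AO lists of (coefficient, exponent, monomial).

    Coefficients include the primitive normalization (correct α-scaling
    across the contraction); the final per-AO scale is fixed afterwards by
    renormalizing the self-overlap to 1.
    """
    lv = shell.l_value
    if lv <= 1 or not shell.spherical:
        combos = [[(lmn, 1.0)] for lmn in _CARTESIAN_COMPONENTS[lv]]
    else:
        combos = _SPHERICAL_COMBOS[lv]
    aos = []
    for combo in combos:
        terms = []
        for exp_, coef in zip(shell.exponents, shell.coefficients):
            norm = _axis_primitive_norm(exp_, lv)
            for lmn, t in combo:
                terms.append((coef * norm * t, exp_, lmn))
        aos.append(terms)
    return aos


def compute_overlap(geometry: Geometry, basis: ShellBasis) -> np.ndarray:
    """AO overlap matrix for a contracted Gaussian basis.

    Contracted AOs are renormalized so the diagonal is exactly 1; the result
    is symmetric positive-definite for any linearly independent basis.
    """
    basis.validate_against(geometry)
    coords_bohr = geometry.coordinates / BOHR_TO_ANGSTROM

    expansions: list[list[tuple[float, float, tuple[int, int, int]]]] = []
    centers: list[np.ndarray] = []
    for sh in basis.shells:
        center = coords_bohr[sh.atom_index]
        for terms in _ao_expansion(sh):
            expansions.append(terms)
            centers.append(center)

    n = len(expansions)
    S = np.empty((n, n))
    for i in range(n):
        for j in range(i + 1):
            acc = 0.0
            for ci, ai, lmn_i in expansions[i]:
                for cj, aj, lmn_j in expansions[j]:
                    acc += ci * cj * _primitive_monomial_overlap(
                        ai, lmn_i, centers[i], aj, lmn_j, centers[j]
                    )
            S[i, j] = S[j, i] = acc
    d = np.sqrt(np.diag(S))
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise ValidationError("basis produced a non-positive AO self-overlap")
    S = S / np.outer(d, d)
    np.fill_diagonal(S, 1.0)
    return S


# ---------------------------------------------------------------------------
# Molden format
# ---------------------------------------------------------------------------

def _molden_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current = None
    for raw in text.splitlines():
        stripped = raw.strip()
        if stripped.startswith("["):
            header = stripped[1:stripped.index("]")].strip().lower()
            tail = stripped[stripped.index("]") + 1:].strip()
            current = header
            sections[current] = [tail] if tail else []
            if not tail:
                sections[current] = []
            else:
                sections[current] = [tail]
            # keep the header-line tail (e.g. "[Atoms] Angs")
        elif current is not None and stripped:
            sections[current].append(raw)
    return sections


def read_molden(path) -> WavefunctionBundle:
    """Parse a Molden file into a :class:`WavefunctionBundle`.

    Coordinates are converted to Å per the [Atoms] Angs/AU flag; pure vs
    Cartesian d/f shells follow the [5D]/[5D7F]/[5D10F]/[7F] tags.  The
    medium defaults to gas phase (ε = 1) and can be overridden afterwards.
    """
    with open(path) as fh:
        text = fh.read()
    sections = _molden_sections(text)

    for required in ("atoms", "gto", "mo"):
        if required not in sections:
            raise ParseError(f"Molden file is missing the [{required.upper()}] section")
    if "9g" in sections:
        raise UnsupportedFeatureError("g shells are not supported")

    sph_d = sph_f = False
    if "5d" in sections or "5d7f" in sections:
        sph_d = sph_f = True
    if "5d10f" in sections:
        sph_d, sph_f = True, False
    if "7f" in sections:
        sph_f = True

    # [Atoms]
    atom_lines = sections["atoms"]
    unit = "angs"
    if atom_lines and atom_lines[0].split() and atom_lines[0].split()[0].lower() in ("angs", "au", "(angs)", "(au)"):
        unit = atom_lines[0].split()[0].lower().strip("()")
        atom_lines = atom_lines[1:]
    elements, coords = [], []
    for line in atom_lines:
        parts = line.split()
        if len(parts) < 6:
            raise ParseError(f"malformed [Atoms] line: {line!r}")
        elements.append(parts[0].capitalize())
        coords.append([float(x) for x in parts[3:6]])
    coords = np.array(coords, dtype=float)
    if unit == "au":
        coords = coords * BOHR_TO_ANGSTROM
    geometry = Geometry(tuple(elements), coords)

    # [GTO]
    shells: list[Shell] = []
    lines = iter(sections["gto"])
    try:
        while True:
            try:
                header = next(lines)
            except StopIteration:
                break
            parts = header.split()
            if not parts:
                continue
            atom_idx = int(parts[0]) - 1
            while True:
                try:
                    shell_line = next(lines)
                except StopIteration:
                    shell_line = None
                if shell_line is None:
                    break
                sparts = shell_line.split()
                if not sparts:
                    break
                letter = sparts[0].lower()
                if letter.isdigit():
                    # next atom block header encountered (blank lines stripped)
                    atom_idx = int(sparts[0]) - 1
                    continue
                nprim = int(sparts[1])
                exps, coefs, coefs_p = [], [], []
                for _ in range(nprim):
                    pparts = next(lines).replace("D", "E").replace("d", "e").split()
                    exps.append(float(pparts[0]))
                    coefs.append(float(pparts[1]))
                    if letter == "sp":
                        coefs_p.append(float(pparts[2]))
                if letter == "sp":
                    shells.append(Shell(atom_idx, "s", tuple(exps), tuple(coefs)))
                    shells.append(Shell(atom_idx, "p", tuple(exps), tuple(coefs_p)))
                elif letter in _ANGULAR_MOMENTUM:
                    spherical = (letter == "d" and sph_d) or (letter == "f" and sph_f)
                    shells.append(Shell(atom_idx, letter, tuple(exps), tuple(coefs), spherical))
                else:
                    raise UnsupportedFeatureError(
                        f"angular momentum '{letter}' not supported (s through f only)"
                    )
    except StopIteration:
        raise ParseError("truncated [GTO] section")
    basis = ShellBasis(tuple(shells))
    n_ao = basis.n_ao

    # [MO]
    mos: dict[str, list[tuple[float, Optional[float], np.ndarray]]] = {"alpha": [], "beta": []}
    occ = ene = None
    spin = "alpha"
    coeff = None

    def _flush():
        nonlocal occ, ene, coeff
        if coeff is not None:
            mos[spin].append((occ if occ is not None else 0.0, ene, coeff))
        occ, ene, coeff = None, None, None

    for line in sections["mo"]:
        stripped = line.strip()
        low = stripped.lower()
        if low.startswith("sym"):
            _flush()
        elif low.startswith("ene"):
            if coeff is not None:
                _flush()
            ene = float(stripped.split("=")[1])
        elif low.startswith("spin"):
            spin = stripped.split("=")[1].strip().lower()
        elif low.startswith("occup"):
            occ = float(stripped.split("=")[1])
        else:
            parts = stripped.split()
            if len(parts) >= 2:
                if coeff is None:
                    coeff = np.zeros(n_ao)
                idx = int(parts[0]) - 1
                if not 0 <= idx < n_ao:
                    raise ParseError(
                        f"MO coefficient index {idx + 1} outside 1..{n_ao}"
                    )
                coeff[idx] = float(parts[1].replace("D", "E").replace("d", "e"))
    _flush()

    if not mos["alpha"] and not mos["beta"]:
        raise ParseError("no molecular orbitals found in the [MO] section")
    alpha = mos["alpha"]
    if mos["beta"]:
        beta = mos["beta"]
        if len(beta) != len(alpha):
            raise UnsupportedFeatureError(
                "alpha/beta MO counts differ: open-shell wavefunctions are "
                "not supported"
            )
        for (oa, _ea, ca), (ob, _eb, cb) in zip(alpha, beta):
            if abs(oa - ob) > 1e-6 or not np.allclose(ca, cb, atol=1e-8):
                raise UnsupportedFeatureError(
                    "alpha and beta blocks differ: open-shell wavefunctions "
                    "are not supported"
                )
        alpha = [(oa + ob, ea, ca) for (oa, ea, ca), (ob, _eb, _cb) in zip(alpha, beta)]

    occupations = np.array([m[0] for m in alpha])
    energies = [m[1] for m in alpha]
    mo_energies = (
        np.array([e for e in energies], dtype=float)
        if all(e is not None for e in energies) else None
    )
    C = np.column_stack([m[2] for m in alpha])

    total = float(occupations.sum())
    if abs(total - round(total)) > 1e-6 or round(total) % 2 != 0:
        raise ValidationError(
            f"occupation sum {total} is not an even integer electron count"
        )

    bundle = WavefunctionBundle(
        geometry=geometry, basis=basis, mo_coefficients=C,
        occupations=occupations, mo_energies=mo_energies, medium=GAS_PHASE,
        ao_map=basis.ao_map(geometry.n_atoms),
    )
    return bundle


def write_molden(bundle: WavefunctionBundle, path) -> None:
    """Write a bundle (with basis) as a Molden file, coordinates in Å."""
    if bundle.basis is None:
        raise ConfigurationError("cannot write Molden without a shell basis")
    lines = ["[Molden Format]", "[Atoms] Angs"]
    for i, (el, xyz) in enumerate(zip(bundle.geometry.elements, bundle.geometry.coordinates)):
        z = _ELEMENT_NUMBERS.get(el, 0)
        lines.append(f"{el:4s} {i + 1:4d} {z:4d} {xyz[0]:18.10f} {xyz[1]:18.10f} {xyz[2]:18.10f}")
    any_sph_d = any(sh.l == "d" and sh.spherical for sh in bundle.basis.shells)
    any_sph_f = any(sh.l == "f" and sh.spherical for sh in bundle.basis.shells)
    if any_sph_d and any_sph_f:
        lines.append("[5D7F]")
    elif any_sph_d:
        lines.append("[5D10F]")
    elif any_sph_f:
        lines.append("[7F]")
    lines.append("[GTO]")
    by_atom: dict[int, list[Shell]] = {}
    for sh in bundle.basis.shells:
        by_atom.setdefault(sh.atom_index, []).append(sh)
    for atom in sorted(by_atom):
        lines.append(f"{atom + 1:4d} 0")
        for sh in by_atom[atom]:
            lines.append(f" {sh.l} {len(sh.exponents):4d} 1.00")
            for e, c in zip(sh.exponents, sh.coefficients):
                lines.append(f"  {e:20.10E} {c:20.10E}")
        lines.append("")
    lines.append("[MO]")
    for j in range(bundle.n_mo):
        lines.append(" Sym= A")
        ene = bundle.mo_energies[j] if bundle.mo_energies is not None else 0.0
        lines.append(f" Ene= {ene:.10f}")
        lines.append(" Spin= Alpha")
        lines.append(f" Occup= {bundle.occupations[j]:.6f}")
        for a in range(bundle.n_ao):
            lines.append(f" {a + 1:5d} {bundle.mo_coefficients[a, j]:20.12E}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Internal JSON bundle
# ---------------------------------------------------------------------------

_BUNDLE_REQUIRED_KEYS = {
    "elements", "coordinates_angstrom", "mo_coefficients", "occupations", "medium",
}


def write_bundle(bundle: WavefunctionBundle, path) -> None:
    """Serialize a bundle to the documented JSON form (lossless round-trip)."""
    bundle.validate()
    doc: dict = {
        "elements": list(bundle.geometry.elements),
        "coordinates_angstrom": bundle.geometry.coordinates.tolist(),
        "mo_coefficients": bundle.mo_coefficients.tolist(),
        "occupations": bundle.occupations.tolist(),
        "medium": {"label": bundle.medium.label, "epsilon": bundle.medium.epsilon},
    }
    if bundle.basis is not None:
        doc["shells"] = [
            {
                "atom": sh.atom_index, "l": sh.l, "spherical": sh.spherical,
                "exponents": list(sh.exponents), "coefficients": list(sh.coefficients),
            }
            for sh in bundle.basis.shells
        ]
    if bundle.overlap is not None:
        doc["overlap"] = bundle.overlap.tolist()
    if bundle.mo_energies is not None:
        doc["mo_energies"] = bundle.mo_energies.tolist()
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_bundle(path) -> WavefunctionBundle:
    """Read a JSON wavefunction bundle written by :func:`write_bundle`."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"bundle file is not valid JSON: {exc}") from exc
    missing = sorted(_BUNDLE_REQUIRED_KEYS - set(doc))
    if missing:
        raise ValidationError(f"bundle file is missing required keys: {missing}")
    geometry = Geometry(tuple(doc["elements"]), np.array(doc["coordinates_angstrom"]))
    basis = None
    if "shells" in doc:
        basis = ShellBasis(tuple(
            Shell(s["atom"], s["l"], tuple(s["exponents"]), tuple(s["coefficients"]),
                  bool(s.get("spherical", False)))
            for s in doc["shells"]
        ))
    bundle = WavefunctionBundle(
        geometry=geometry,
        basis=basis,
        mo_coefficients=np.array(doc["mo_coefficients"], dtype=float),
        occupations=np.array(doc["occupations"], dtype=float),
        overlap=np.array(doc["overlap"], dtype=float) if "overlap" in doc else None,
        mo_energies=(np.array(doc["mo_energies"], dtype=float)
                     if "mo_energies" in doc else None),
        medium=Medium(doc["medium"]["label"], float(doc["medium"]["epsilon"])),
    )
    bundle.validate()
    return bundle


def with_medium(bundle: WavefunctionBundle, medium: Medium) -> WavefunctionBundle:
    """Return a shallow copy of the bundle tagged with a different medium."""
    return replace(bundle, medium=medium)
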