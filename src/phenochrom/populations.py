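"""Electron-density and molecular-orbital partitioning over atoms and fragments.

Implements the partition schemes the solvatochromism protocol builds on:

* Mulliken and Löwdin atomic populations,
* Mayer bond orders  B_AB = Σ_{a∈A} Σ_{b∈B} (PS)_ab (PS)_ba  from the
  closed-shell density,
* a natural-atomic-orbital (NAO) construction — per-atom, per-angular-
  momentum diagonalization of the atomic density blocks followed by
  occupancy-weighted symmetric orthogonalization — giving natural
  populations and an orthonormal basis for NPA-style MO compositions,
* per-MO fragment composition percentages under four schemes
  (mulliken, lowdin, scpa, npa), the quantities entering the CT(%)
  charge-transfer statistic.

Löwdin, SCPA and NAO percentages are bounded in [0, 100]; Mulliken
percentages may leave those bounds for strongly overlapping bases (a
warning is logged when they do).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .errors import (
    AmbiguityError,
    ConfigurationError,
    NumericalError,
    ValidationError,
)
from .qcio import ShellBasis, WavefunctionBundle, validate_ao_map

logger = logging.getLogger(__name__)

SCHEMES = ("mulliken", "lowdin", "scpa", "npa")

#: Default composition scheme; the NAO-basis decomposition is the
#: protocol's reference scheme, with Löwdin as the fallback when no
#: basis (hence no angular-momentum labels) is available.
DEFAULT_SCHEME = "npa"


@dataclass(frozen=True)
class Fragment:
    """A named set of atoms; conventionally "X" = acceptor heterocycle,
    "Y" = phenolate donor."""

    name: str
    atom_indices: frozenset[int]

    def __post_init__(self):
        object.__setattr__(self, "atom_indices", frozenset(self.atom_indices))
        if not self.atom_indices:
            raise ValidationError(f"fragment {self.name!r} is empty")
        if any(i < 0 for i in self.atom_indices):
            raise ValidationError(f"fragment {self.name!r} has negative atom indices")


@dataclass
class OrbitalComposition:
    """Per-MO fragment percentages under one partition scheme.

    ``percentages`` is (n_MO × n_fragments), columns ordered as
    ``fragment_names``.  For a full partition each row sums to 100.
    """

    scheme: str
    fragment_names: tuple[str, ...]
    percentages: np.ndarray
    homo_index: int
    lumo_index: int
    occupations: np.ndarray
    mo_energies: Optional[np.ndarray] = None

    def fragment_percent(self, name: str, mo_index: int) -> float:
        return float(self.percentages[mo_index, self.fragment_names.index(name)])


@dataclass
class BondOrderMatrix:
    """Symmetric atom × atom Mayer bond orders; the diagonal is zeroed."""

    orders: np.ndarray

    def __post_init__(self):
        B = np.asarray(self.orders, dtype=float)
        if B.ndim != 2 or B.shape[0] != B.shape[1]:
            raise ValidationError("bond-order matrix must be square")
        if not np.all(np.isfinite(B)):
            raise ValidationError("bond-order matrix contains non-finite entries")
        np.fill_diagonal(B, 0.0)
        self.orders = B

    def order(self, i: int, j: int) -> float:
        return float(self.orders[i, j])


# ---------------------------------------------------------------------------
# Densities and atomic populations
# ---------------------------------------------------------------------------

def density_matrix(bundle: WavefunctionBundle) -> np.ndarray:
    """Closed-shell one-particle density P = C · diag(occ) · Cᵀ in the AO basis."""
    C = bundle.mo_coefficients
    return (C * bundle.occupations) @ C.T


def _check_dims(P: np.ndarray, S: np.ndarray, ao_map: dict[int, list[int]]) -> None:
    if P.shape != S.shape or P.shape[0] != P.shape[1]:
        raise ValidationError(
            f"density {P.shape} and overlap {S.shape} must be square and equal"
        )
    validate_ao_map(ao_map, P.shape[0])


def mulliken_atomic_populations(
    P: np.ndarray, S: np.ndarray, ao_map: dict[int, list[int]]
) -> np.ndarray:
    """Mulliken gross atomic populations: per-atom sums of diag(PS)."""
    _check_dims(P, S, ao_map)
    d = np.einsum("ab,ba->a", P, S)
    return np.array([d[ao_map[a]].sum() for a in sorted(ao_map)])


def _sqrtm_spd(S: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(S)
    if w.min() <= 0:
        raise NumericalError("overlap matrix is not positive definite")
    return (V * np.sqrt(w)) @ V.T


def lowdin_atomic_populations(
    P: np.ndarray, S: np.ndarray, ao_map: dict[int, list[int]]
) -> np.ndarray:
    """Löwdin populations: per-atom sums of diag(S½ P S½)."""
    _check_dims(P, S, ao_map)
    Sh = _sqrtm_spd(S)
    d = np.einsum("ab,bc,ca->a", Sh, P, Sh, optimize=True)
    return np.array([d[ao_map[a]].sum() for a in sorted(ao_map)])


def mayer_bond_orders(
    P: np.ndarray, S: np.ndarray, ao_map: dict[int, list[int]]
) -> BondOrderMatrix:
    """Mayer bond orders B_AB = Σ_{a∈A}Σ_{b∈B} (PS)_ab (PS)_ba."""
    _check_dims(P, S, ao_map)
    PS = P @ S
    M = PS * PS.T
    atoms = sorted(ao_map)
    B = np.zeros((len(atoms), len(atoms)))
    for A in atoms:
        ia = ao_map[A]
        for Bm in atoms:
            if Bm <= A:
                continue
            val = M[np.ix_(ia, ao_map[Bm])].sum()
            B[A, Bm] = B[Bm, A] = val
    return BondOrderMatrix(B)


# ---------------------------------------------------------------------------
# Natural atomic orbitals
# ---------------------------------------------------------------------------

_OCCUPANCY_FLOOR = 1e-4  # floor on pre-NAO weights to keep W invertible


def nao_transform(
    P: np.ndarray, S: np.ndarray, ao_map: dict[int, list[int]],
    basis: ShellBasis,
) -> np.ndarray:
    """AO → orthonormal-NAO transformation matrix T (columns are NAOs).

    Pre-NAOs diagonalize the per-atom, per-angular-momentum blocks of the
    density in the atomic overlap metric; they are then orthogonalized
    globally by occupancy-weighted symmetric orthogonalization,
    T = N·W(W S' W)^(-1/2), so high-occupancy orbitals are distorted least.
    NAO i stays attributed to the atom of its pre-NAO block.
    """
    _check_dims(P, S, ao_map)
    cond = np.linalg.cond(S)
    if cond > 1e10:
        raise NumericalError(
            f"overlap matrix is near-singular (condition number {cond:.3g}); "
            "review the basis for linear dependence"
        )
    labels = basis.ao_labels()
    if len(labels) != P.shape[0]:
        raise ValidationError("basis AO count does not match density dimension")

    n = P.shape[0]
    N = np.zeros((n, n))
    weights = np.zeros(n)
    col = 0
    for atom in sorted(ao_map):
        by_l: dict[str, list[int]] = {}
        for idx in ao_map[atom]:
            by_l.setdefault(labels[idx][1], []).append(idx)
        for l in sorted(by_l):
            idxs = by_l[l]
            Pb = P[np.ix_(idxs, idxs)]
            Sb = S[np.ix_(idxs, idxs)]
            # generalized symmetric eigenproblem Pb v = λ Sb v
            w, V = scipy.linalg.eigh(Pb, Sb)
            order = np.argsort(w)[::-1]
            w, V = w[order], V[:, order]
            for k in range(len(idxs)):
                v = V[:, k]
                nrm = float(v @ Sb @ v)
                v = v / np.sqrt(nrm)
                N[idxs, col] = v
                weights[col] = max(float(w[k]), _OCCUPANCY_FLOOR)
                col += 1
    Sp = N.T @ S @ N
    W = np.diag(weights)
    WSW = W @ Sp @ W
    w2, V2 = np.linalg.eigh(WSW)
    if w2.min() <= 0:
        raise NumericalError("occupancy-weighted metric lost positive definiteness")
    WSW_invsqrt = (V2 / np.sqrt(w2)) @ V2.T
    T = N @ W @ WSW_invsqrt
    return T


def _nao_atom_of_column(ao_map: dict[int, list[int]]) -> np.ndarray:
    """Atom attribution of NAO columns (pre-NAO blocks keep AO-count per atom)."""
    n = sum(len(v) for v in ao_map.values())
    owner = np.zeros(n, dtype=int)
    col = 0
    for atom in sorted(ao_map):
        for _ in ao_map[atom]:
            owner[col] = atom
            col += 1
    return owner


def nao_populations(
    P: np.ndarray, S: np.ndarray, ao_map: dict[int, list[int]],
    basis: ShellBasis,
) -> tuple[np.ndarray, np.ndarray]:
    """Natural populations: (T, per-atom populations) with TᵀST = I.

    Populations are the per-atom sums of the diagonal of the density
    expressed in the orthonormal NAO basis; they conserve the electron
    count and reduce to Löwdin populations when S = I.
    """
    T = nao_transform(P, S, ao_map, basis)
    P_nao = T.T @ S @ P @ S @ T
    owner = _nao_atom_of_column(ao_map)
    d = np.diag(P_nao)
    atoms = sorted(ao_map)
    pops = np.array([d[owner == a].sum() for a in atoms])
    return T, pops


# ---------------------------------------------------------------------------
# MO fragment composition
# ---------------------------------------------------------------------------

def _fragment_ao_indices(
    fragments: Sequence[Fragment], ao_map: dict[int, list[int]]
) -> list[np.ndarray]:
    seen: set[int] = set()
    for f in fragments:
        if seen & f.atom_indices:
            raise ValidationError("fragments must be disjoint atom sets")
        seen |= f.atom_indices
    out = []
    for f in fragments:
        idxs: list[int] = []
        for a in sorted(f.atom_indices):
            if a not in ao_map:
                raise ValidationError(
                    f"fragment {f.name!r} references atom {a} outside the system"
                )
            idxs.extend(ao_map[a])
        out.append(np.array(idxs, dtype=int))
    return out


def homo_lumo_indices(
    occupations: np.ndarray,
    mo_energies: Optional[np.ndarray] = None,
    compositions: Optional[np.ndarray] = None,
    degeneracy_tol: float = 1e-6,
) -> tuple[int, int]:
    """Locate the frontier orbitals.

    HOMO = highest-energy MO with occupation ≥ 1, LUMO = lowest-energy MO
    with occupation < 1 (by energy when energies are given, else by index,
    assuming energy order).  If another occupied MO sits within
    ``degeneracy_tol`` hartree of the HOMO *and* the supplied fragment
    compositions of the two differ by more than one percentage point, the
    frontier assignment is ambiguous and an error is raised rather than a
    guess being made.
    """
    occ = np.asarray(occupations, dtype=float)
    occupied = np.flatnonzero(occ >= 1.0)
    virtual = np.flatnonzero(occ < 1.0)
    if occupied.size == 0 or virtual.size == 0:
        raise ValidationError(
            "need at least one occupied and one unoccupied MO to locate "
            "the HOMO and LUMO"
        )
    if mo_energies is None:
        homo = int(occupied.max())
        lumo = int(virtual.min())
    else:
        e = np.asarray(mo_energies, dtype=float)
        homo = int(occupied[np.argmax(e[occupied])])
        lumo = int(virtual[np.argmin(e[virtual])])
        near = occupied[(np.abs(e[occupied] - e[homo]) <= degeneracy_tol)
                        & (occupied != homo)]
        if near.size and compositions is not None:
            for other in near:
                if np.any(np.abs(compositions[homo] - compositions[other]) > 1.0):
                    raise AmbiguityError(
                        f"HOMO (MO {homo}) is degenerate with occupied MO "
                        f"{int(other)} within {degeneracy_tol} hartree and their "
                        "fragment compositions differ by more than 1%; the "
                        "frontier assignment is ambiguous"
                    )
    return homo, lumo


def mo_fragment_composition(
    bundle: WavefunctionBundle,
    fragments: Sequence[Fragment],
    scheme: str = DEFAULT_SCHEME,
) -> OrbitalComposition:
    """Percentage of each MO carried by each fragment under one scheme.

    mulliken:  100·Σ_{a∈F} Σ_b C_ai S_ab C_bi
    lowdin:    100·Σ_{a∈F} ((S½C)_ai)²
    scpa:      100·Σ_{a∈F} C_ai² / Σ_b C_bi²
    npa:       100·Σ_{a∈F} (C'_ai)²  with C' = TᵀSC the MO coefficients in
               the orthonormal NAO basis.
    """
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown composition scheme {scheme!r}; "
                              f"choose from {SCHEMES}")
    if bundle.ao_map is None:
        raise ConfigurationError("bundle has no AO index map")
    C = bundle.mo_coefficients
    frag_aos = _fragment_ao_indices(fragments, bundle.ao_map)

    if scheme == "scpa":
        weights = C ** 2
        weights = weights / weights.sum(axis=0, keepdims=True)
    elif scheme == "mulliken":
        S = bundle.overlap_matrix()
        weights = C * (S @ C)
    elif scheme == "lowdin":
        S = bundle.overlap_matrix()
        weights = (_sqrtm_spd(S) @ C) ** 2
        weights = weights / weights.sum(axis=0, keepdims=True)
    else:  # npa
        if bundle.basis is None:
            raise ConfigurationError(
                "npa compositions require a shell basis (for angular-momentum "
                "labels); use the lowdin scheme when only an overlap is available"
            )
        S = bundle.overlap_matrix()
        P = density_matrix(bundle)
        T = nao_transform(P, S, bundle.ao_map, bundle.basis)
        Cp = T.T @ S @ C
        weights = Cp ** 2
        weights = weights / weights.sum(axis=0, keepdims=True)
        owner = _nao_atom_of_column(bundle.ao_map)
        frag_aos = [
            np.flatnonzero(np.isin(owner, sorted(f.atom_indices)))
            for f in fragments
        ]

    perc = np.column_stack([100.0 * weights[idx].sum(axis=0) for idx in frag_aos])
    if scheme == "mulliken":
        # Mulliken MO norms CᵀSC are 1 for S-normalized MOs; normalize anyway
        norms = weights.sum(axis=0)
        perc = perc / norms[:, None]
        if np.any(perc < -1e-8) or np.any(perc > 100 + 1e-8):
            logger.warning(
                "Mulliken fragment percentages left the [0, 100] interval "
                "(min %.3f, max %.3f); this is a known property of the "
                "Mulliken partition for overlapping bases",
                perc.min(), perc.max(),
            )

    homo, lumo = homo_lumo_indices(bundle.occupations, bundle.mo_energies,
                                   compositions=perc)
    return OrbitalComposition(
        scheme=scheme,
        fragment_names=tuple(f.name for f in fragments),
        percentages=perc,
        homo_index=homo,
        lumo_index=lumo,
        occupations=bundle.occupations.copy(),
        mo_energies=(bundle.mo_energies.copy()
                     if bundle.mo_energies is not None else None),
    )


def composition_table(comp: OrbitalComposition, medium=None) -> str:
    """Render a composition as the TSV report (metadata lines prefixed '#')."""
    lines = [f"# scheme\t{comp.scheme}"]
    if medium is not None:
        lines.append(f"# medium\t{medium.label}")
        lines.append(f"# epsilon\t{medium.epsilon}")
    lines.append(f"# homo_index\t{comp.homo_index}")
    lines.append(f"# lumo_index\t{comp.lumo_index}")
    header = ["mo_index", "energy_hartree", "occupation"] + list(comp.fragment_names)
    lines.append("\t".join(header))
    for i in range(comp.percentages.shape[0]):
        e = comp.mo_energies[i] if comp.mo_energies is not None else float("nan")
        row = [str(i), f"{e:.6f}", f"{comp.occupations[i]:.4f}"]
        row += [f"{comp.percentages[i, j]:.4f}"
                for j in range(len(comp.fragment_names))]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
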