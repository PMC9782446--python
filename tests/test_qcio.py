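"""Wavefunction I/O and analytic overlap integrals."""

import math

import numpy as np
import pytest

from phenochrom import (
    BOHR_TO_ANGSTROM,
    Geometry,
    Medium,
    ParseError,
    Shell,
    ShellBasis,
    UnsupportedFeatureError,
    ValidationError,
    WavefunctionBundle,
    compute_overlap,
    read_bundle,
    read_molden,
    write_bundle,
    write_molden,
)
from phenochrom.qcio import _ao_expansion


# ---------------------------------------------------------------------------
# Overlap integrals
# ---------------------------------------------------------------------------

def test_single_normalized_s_primitive_has_unit_self_overlap():
    geom = Geometry(("H",), np.zeros((1, 3)))
    basis = ShellBasis((Shell(0, "s", (0.7,), (1.0,)),))
    S = compute_overlap(geom, basis)
    assert S.shape == (1, 1)
    assert S[0, 0] == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("alpha,r_bohr", [(1.0, 1.0), (1.24, 1.4), (0.5, 2.3)])
def test_same_exponent_s_overlap_matches_closed_form(alpha, r_bohr):
    """Normalized same-exponent s Gaussians overlap as exp(-αR²/2)."""
    sep = r_bohr * BOHR_TO_ANGSTROM
    geom = Geometry(("H", "H"), np.array([[0.0, 0.0, 0.0], [sep, 0.0, 0.0]]))
    basis = ShellBasis((Shell(0, "s", (alpha,), (1.0,)),
                        Shell(1, "s", (alpha,), (1.0,))))
    S = compute_overlap(geom, basis)
    assert S[0, 1] == pytest.approx(math.exp(-alpha * r_bohr ** 2 / 2), abs=1e-10)


@pytest.mark.parametrize("l2,spherical", [("p", False), ("d", False),
                                          ("d", True), ("f", True)])
def test_overlap_matches_quadrature_oracle(l2, spherical):
    """Analytic recurrences agree with brute-force grid integration."""
    sep = 1.1  # Å
    geom = Geometry(("C", "N"), np.array([[0.0, 0.0, 0.0], [sep, 0.4, -0.2]]))
    basis = ShellBasis((
        Shell(0, "s", (0.9, 0.3), (0.6, 0.5)),
        Shell(1, l2, (0.8,), (1.0,), spherical),
    ))
    S = compute_overlap(geom, basis)
    coords_bohr = geom.coordinates / BOHR_TO_ANGSTROM

    extent, n = 8.0, 121
    axis = np.linspace(-extent, extent, n)
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    dv = (axis[1] - axis[0]) ** 3
    fields = []
    for sh in basis.shells:
        c = coords_bohr[sh.atom_index]
        x, y, z = X - c[0], Y - c[1], Z - c[2]
        r2 = x ** 2 + y ** 2 + z ** 2
        for terms in _ao_expansion(sh):
            f = np.zeros_like(X)
            for coef, alpha, (lx, ly, lz) in terms:
                f += coef * x ** lx * y ** ly * z ** lz * np.exp(-alpha * r2)
            fields.append(f / math.sqrt(float(np.sum(f * f)) * dv))
    for i in range(len(fields)):
        for j in range(i):
            raw = float(np.sum(fields[i] * fields[j]) * dv)
            assert S[i, j] == pytest.approx(raw, abs=2e-4)


@pytest.mark.parametrize("seed", range(3))
def test_overlap_symmetric_positive_definite(seed):
    rng = np.random.default_rng(seed)
    n_atoms = int(rng.integers(2, 4))
    geom = Geometry(
        tuple(rng.choice(["C", "N", "O"], n_atoms)),
        rng.normal(scale=1.5, size=(n_atoms, 3)),
    )
    shells = []
    for a in range(n_atoms):
        for l in rng.choice(["s", "p", "d"], 2):
            shells.append(Shell(a, str(l), tuple(rng.uniform(0.3, 2.0, 2)),
                                (0.7, 0.4), spherical=bool(rng.integers(2))))
    S = compute_overlap(geom, ShellBasis(tuple(shells)))
    assert np.allclose(S, S.T, atol=1e-12)
    assert np.linalg.eigvalsh(S).min() > 0
    assert np.allclose(np.diag(S), 1.0, atol=1e-10)


def test_negative_exponent_rejected():
    with pytest.raises(ValidationError):
        Shell(0, "s", (-1.0,), (1.0,))


def test_g_shell_rejected():
    with pytest.raises(UnsupportedFeatureError):
        Shell(0, "g", (1.0,), (1.0,))


# ---------------------------------------------------------------------------
# Molden
# ---------------------------------------------------------------------------

MINIMAL_H2_MOLDEN = """[Molden Format]
[Atoms] AU
H 1 1 0.0 0.0 0.0
H 2 1 1.4 0.0 0.0
[GTO]
1 0
 s 1 1.00
  1.24 1.0
2 0
 s 1 1.00
  1.24 1.0

[MO]
 Sym= A
 Ene= -0.5
 Spin= Alpha
 Occup= 2.0
 1 0.548
 2 0.548
 Sym= A
 Ene= 0.3
 Spin= Alpha
 Occup= 0.0
 1 1.212
 2 -1.212
"""


def test_minimal_molden_parses(tmp_path):
    path = tmp_path / "h2.molden"
    path.write_text(MINIMAL_H2_MOLDEN)
    bundle = read_molden(path)
    assert bundle.n_ao == 2
    assert bundle.occupations.tolist() == [2.0, 0.0]
    assert bundle.geometry.coordinates[1, 0] == pytest.approx(1.4 * BOHR_TO_ANGSTROM)
    assert bundle.medium.epsilon == 1.0


def test_molden_au_and_angs_variants_agree(tmp_path):
    au = tmp_path / "au.molden"
    au.write_text(MINIMAL_H2_MOLDEN)
    angs = tmp_path / "angs.molden"
    angs.write_text(
        MINIMAL_H2_MOLDEN.replace("[Atoms] AU", "[Atoms] Angs").replace(
            "H 2 1 1.4 0.0 0.0", f"H 2 1 {1.4 * BOHR_TO_ANGSTROM:.12f} 0.0 0.0"
        )
    )
    ba, bb = read_molden(au), read_molden(angs)
    assert np.allclose(ba.geometry.coordinates, bb.geometry.coordinates, atol=1e-10)
    assert np.allclose(ba.mo_coefficients, bb.mo_coefficients, atol=1e-12)


def test_molden_missing_mo_section_is_parse_error(tmp_path):
    text = MINIMAL_H2_MOLDEN[: MINIMAL_H2_MOLDEN.index("[MO]")]
    path = tmp_path / "broken.molden"
    path.write_text(text)
    with pytest.raises(ParseError, match=r"\[MO\]"):
        read_molden(path)


def test_molden_odd_electron_count_rejected(tmp_path):
    path = tmp_path / "odd.molden"
    path.write_text(MINIMAL_H2_MOLDEN.replace("Occup= 2.0", "Occup= 1.0"))
    with pytest.raises(ValidationError, match="even integer"):
        read_molden(path)


def test_molden_round_trip(h2_bundle, tmp_path):
    path = tmp_path / "h2.molden"
    write_molden(h2_bundle, path)
    back = read_molden(path)
    assert back.geometry.elements == h2_bundle.geometry.elements
    assert np.allclose(back.geometry.coordinates, h2_bundle.geometry.coordinates,
                       atol=1e-9)
    assert np.allclose(back.mo_coefficients, h2_bundle.mo_coefficients, atol=1e-10)
    assert np.allclose(back.occupations, h2_bundle.occupations, atol=1e-12)
    assert np.allclose(back.overlap_matrix(), h2_bundle.overlap, atol=1e-10)


# ---------------------------------------------------------------------------
# JSON bundle
# ---------------------------------------------------------------------------

def test_bundle_json_round_trip(two_fragment_bundle, tmp_path):
    path = tmp_path / "bundle.json"
    write_bundle(two_fragment_bundle, path)
    back = read_bundle(path)
    assert back.geometry.elements == two_fragment_bundle.geometry.elements
    for attr in ("mo_coefficients", "occupations", "mo_energies", "overlap"):
        assert np.allclose(getattr(back, attr),
                           getattr(two_fragment_bundle, attr), atol=1e-12)
    assert back.medium == two_fragment_bundle.medium


def test_bundle_without_energies_round_trips_absent(h2_bundle, tmp_path):
    import dataclasses
    stripped = dataclasses.replace(h2_bundle, mo_energies=None)
    path = tmp_path / "b.json"
    write_bundle(stripped, path)
    assert read_bundle(path).mo_energies is None


def test_bundle_invalid_occupation_rejected_on_write(two_fragment_bundle, tmp_path):
    import dataclasses
    bad = dataclasses.replace(
        two_fragment_bundle,
        occupations=np.array([3.0, 0.0]),
    )
    with pytest.raises(ValidationError):
        write_bundle(bad, tmp_path / "bad.json")


def test_bundle_missing_keys_reported(tmp_path):
    path = tmp_path / "broken.json"
    path.write_text('{"elements": ["H"]}')
    with pytest.raises(ValidationError, match="coordinates_angstrom"):
        read_bundle(path)


def test_medium_requires_epsilon_at_least_one():
    with pytest.raises(ValidationError):
        Medium("vacuum-ish", 0.5)
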