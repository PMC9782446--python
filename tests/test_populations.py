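"""Population analysis: densities, Mayer orders, NAO, fragment compositions."""

import math

import numpy as np
import pytest

from phenochrom import (
    AmbiguityError,
    ConfigurationError,
    Fragment,
    TwoFragmentSpec,
    ValidationError,
    density_matrix,
    homo_lumo_indices,
    lowdin_atomic_populations,
    make_two_fragment_bundle,
    mayer_bond_orders,
    mo_fragment_composition,
    mulliken_atomic_populations,
    nao_populations,
)
from phenochrom.populations import SCHEMES


def brute_force_mayer(P, S, ao_map, A, B):
    """Explicit quadruple-loop Mayer double sum — the independent oracle."""
    PS = P @ S
    total = 0.0
    for a in ao_map[A]:
        for b in ao_map[B]:
            total += PS[a, b] * PS[b, a]
    return total


def brute_force_composition(C, S, ao_indices, mo, scheme):
    """Defining sums of the composition schemes, written out explicitly."""
    c = C[:, mo]
    if scheme == "mulliken":
        num = sum(c[a] * S[a, b] * c[b] for a in ao_indices for b in range(len(c)))
        den = float(c @ S @ c)
    elif scheme == "scpa":
        num = sum(c[a] ** 2 for a in ao_indices)
        den = float(c @ c)
    elif scheme == "lowdin":
        w, V = np.linalg.eigh(S)
        Sh = (V * np.sqrt(w)) @ V.T
        v = Sh @ c
        num = sum(v[a] ** 2 for a in ao_indices)
        den = float(v @ v)
    else:
        raise ValueError(scheme)
    return 100.0 * num / den


def test_density_trace_equals_electron_count(h2_bundle, skewed_bundles):
    for bundle in [h2_bundle, *skewed_bundles]:
        P = density_matrix(bundle)
        S = bundle.overlap_matrix()
        assert np.trace(P @ S) == pytest.approx(bundle.n_electrons, abs=1e-10)
        assert np.allclose(P, P.T, atol=1e-12)


def test_h2_mulliken_populations_symmetric(h2_bundle):
    P = density_matrix(h2_bundle)
    S = h2_bundle.overlap_matrix()
    pops = mulliken_atomic_populations(P, S, h2_bundle.ao_map)
    assert pops == pytest.approx([1.0, 1.0], abs=1e-10)


def test_orthonormal_toy_mulliken_closed_form():
    """Occupied MO (cos30°, sin30°) on orthonormal AOs → populations (1.5, 0.5)."""
    theta = math.radians(30.0)
    c = np.array([[math.cos(theta)], [math.sin(theta)]])
    P = 2.0 * (c @ c.T)
    S = np.eye(2)
    pops = mulliken_atomic_populations(P, S, {0: [0], 1: [1]})
    assert pops == pytest.approx([1.5, 0.5], abs=1e-12)


@pytest.mark.parametrize("separation", [0.5, 0.74, 1.2, 2.5])
def test_h2_mayer_bond_order_is_one(separation):
    from phenochrom import make_h2_minimal

    bundle = make_h2_minimal(separation)
    P = density_matrix(bundle)
    B = mayer_bond_orders(P, bundle.overlap_matrix(), bundle.ao_map)
    assert B.order(0, 1) == pytest.approx(1.0, abs=1e-10)


@pytest.mark.parametrize("theta_deg,expected", [(45.0, 1.0), (30.0, 0.75)])
def test_orthonormal_toy_mayer_closed_form(theta_deg, expected):
    """Two-AO toy with occupied MO (cosθ, sinθ): B = sin²(2θ)."""
    theta = math.radians(theta_deg)
    c = np.array([[math.cos(theta)], [math.sin(theta)]])
    P = 2.0 * (c @ c.T)
    S = np.eye(2)
    ao_map = {0: [0], 1: [1]}
    B = mayer_bond_orders(P, S, ao_map)
    assert B.order(0, 1) == pytest.approx(expected, abs=1e-12)
    assert B.order(0, 1) == pytest.approx(
        brute_force_mayer(P, S, ao_map, 0, 1), abs=1e-12
    )


def test_mayer_matrix_matches_brute_force_on_skewed_fixtures(skewed_bundles):
    for bundle in skewed_bundles:
        P = density_matrix(bundle)
        S = bundle.overlap_matrix()
        B = mayer_bond_orders(P, S, bundle.ao_map)
        for A in bundle.ao_map:
            for Bm in bundle.ao_map:
                if A < Bm:
                    assert B.order(A, Bm) == pytest.approx(
                        brute_force_mayer(P, S, bundle.ao_map, A, Bm), abs=1e-10
                    )


def test_nao_equals_lowdin_when_overlap_is_identity(two_fragment_bundle):
    P = density_matrix(two_fragment_bundle)
    S = two_fragment_bundle.overlap_matrix()
    assert np.allclose(S, np.eye(4))
    _T, nao = nao_populations(P, S, two_fragment_bundle.ao_map,
                              two_fragment_bundle.basis)
    lowdin = lowdin_atomic_populations(P, S, two_fragment_bundle.ao_map)
    assert nao == pytest.approx(lowdin, abs=1e-8)


def test_nao_basis_orthonormal_and_conserving(skewed_bundles, h2_bundle):
    for bundle in [*skewed_bundles, h2_bundle]:
        P = density_matrix(bundle)
        S = bundle.overlap_matrix()
        T, pops = nao_populations(P, S, bundle.ao_map, bundle.basis)
        assert np.allclose(T.T @ S @ T, np.eye(bundle.n_ao), atol=1e-8)
        assert pops.sum() == pytest.approx(bundle.n_electrons, abs=1e-6)


def test_population_sums_conserve_electron_count(skewed_bundles):
    for bundle in skewed_bundles:
        P = density_matrix(bundle)
        S = bundle.overlap_matrix()
        n = bundle.n_electrons
        assert mulliken_atomic_populations(P, S, bundle.ao_map).sum() == \
            pytest.approx(n, abs=1e-6)
        assert lowdin_atomic_populations(P, S, bundle.ao_map).sum() == \
            pytest.approx(n, abs=1e-6)


@pytest.mark.parametrize("scheme", SCHEMES)
def test_composition_closed_form_on_toy(two_fragment_bundle, xy_fragments, scheme):
    """θ_H = 60° → %Y_HOMO = 75 under every scheme on the orthonormal toy."""
    comp = mo_fragment_composition(two_fragment_bundle, xy_fragments, scheme)
    assert comp.fragment_percent("Y", comp.homo_index) == pytest.approx(75.0, abs=1e-8)
    assert comp.fragment_percent("Y", comp.lumo_index) == pytest.approx(25.0, abs=1e-8)


@pytest.mark.parametrize("scheme", SCHEMES)
def test_full_fragment_gets_100_percent(two_fragment_bundle, scheme):
    comp = mo_fragment_composition(
        two_fragment_bundle, [Fragment("all", {0, 1})], scheme
    )
    assert np.allclose(comp.percentages, 100.0, atol=1e-8)


@pytest.mark.parametrize("scheme", SCHEMES)
def test_partition_sums_to_100_on_skewed_fixtures(skewed_bundles, xy_fragments, scheme):
    for bundle in skewed_bundles:
        comp = mo_fragment_composition(bundle, xy_fragments, scheme)
        assert np.allclose(comp.percentages.sum(axis=1), 100.0, atol=1e-6)
        if scheme != "mulliken":
            assert np.all(comp.percentages >= -1e-9)
            assert np.all(comp.percentages <= 100 + 1e-9)


@pytest.mark.parametrize("scheme", ("mulliken", "lowdin", "scpa"))
def test_composition_matches_brute_force_sums(skewed_bundles, xy_fragments, scheme):
    for bundle in skewed_bundles:
        C = bundle.mo_coefficients
        S = bundle.overlap_matrix()
        comp = mo_fragment_composition(bundle, xy_fragments, scheme)
        for mo in range(bundle.n_mo):
            for k, frag in enumerate(xy_fragments):
                idxs = [i for a in sorted(frag.atom_indices)
                        for i in bundle.ao_map[a]]
                expected = brute_force_composition(C, S, idxs, mo, scheme)
                assert comp.percentages[mo, k] == pytest.approx(expected, abs=1e-8)


def test_h2_bonding_mo_splits_evenly(h2_bundle):
    comp = mo_fragment_composition(
        h2_bundle, [Fragment("A", {0}), Fragment("B", {1})], "mulliken"
    )
    assert comp.percentages[0] == pytest.approx([50.0, 50.0], abs=1e-10)


def test_overlapping_fragments_rejected(two_fragment_bundle):
    with pytest.raises(ValidationError):
        mo_fragment_composition(
            two_fragment_bundle,
            [Fragment("X", {0, 1}), Fragment("Y", {1})],
            "lowdin",
        )


def test_npa_without_basis_is_configuration_error(two_fragment_bundle):
    import dataclasses
    bare = dataclasses.replace(two_fragment_bundle, basis=None)
    with pytest.raises(ConfigurationError):
        mo_fragment_composition(
            bare, [Fragment("X", {0}), Fragment("Y", {1})], "npa"
        )


# ---------------------------------------------------------------------------
# Frontier orbitals
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("occ,expected", [
    ([2, 2, 0, 0], (1, 2)),
    ([2, 0], (0, 1)),
    ([2, 0, 2, 0], (2, 1)),  # index order stands in for energy order
])
def test_homo_lumo_by_index(occ, expected):
    assert homo_lumo_indices(np.array(occ, dtype=float)) == expected


def test_homo_lumo_uses_energies_when_present():
    occ = np.array([2.0, 2.0, 0.0, 0.0])
    e = np.array([-0.2, -0.9, 0.4, 0.1])
    assert homo_lumo_indices(occ, e) == (0, 3)


def test_all_occupied_is_error():
    with pytest.raises(ValidationError):
        homo_lumo_indices(np.array([2.0, 2.0, 2.0]))


def test_degenerate_homo_with_differing_composition_is_ambiguous():
    occ = np.array([2.0, 2.0, 0.0])
    e = np.array([-0.5, -0.5, 0.1])
    comps = np.array([[90.0, 10.0], [10.0, 90.0], [50.0, 50.0]])
    with pytest.raises(AmbiguityError):
        homo_lumo_indices(occ, e, compositions=comps)
    # same compositions → no ambiguity
    same = np.array([[60.0, 40.0], [60.0, 40.0], [50.0, 50.0]])
    homo, lumo = homo_lumo_indices(occ, e, compositions=same)
    assert lumo == 2
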