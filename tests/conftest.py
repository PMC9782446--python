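import numpy as np
import pytest

from phenochrom import (
    Fragment,
    TwoFragmentSpec,
    make_h2_minimal,
    make_two_fragment_bundle,
    skew_overlap,
)


@pytest.fixture
def two_fragment_bundle():
    """θ_H = 60°, θ_L = 30° toy: %Y_HOMO = 75, %Y_LUMO = 25, CT = 50."""
    return make_two_fragment_bundle(TwoFragmentSpec(theta_homo=60.0, theta_lumo=30.0))


@pytest.fixture
def xy_fragments():
    return [Fragment("X", {0}), Fragment("Y", {1})]


@pytest.fixture
def h2_bundle():
    return make_h2_minimal(0.74)


@pytest.fixture
def skewed_bundles():
    """Seeded bundles with random SPD overlaps, for scheme-divergent checks."""
    return [
        skew_overlap(
            make_two_fragment_bundle(
                TwoFragmentSpec(theta_homo=th, theta_lumo=tl, n_spectator_mos=2)
            ),
            seed=seed,
        )
        for seed, (th, tl) in enumerate([(60.0, 30.0), (10.0, 80.0), (45.0, 45.0)])
    ]
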