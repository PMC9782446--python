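"""The CT(%) charge-transfer statistic and solvatochromism classification.

For a donor–acceptor dye X–Y with Y the phenolate donor, the charge
transferred in the HOMO→LUMO transition is quantified as

    CT(%) = 100 · (P_Y^g − P_Y^e)  =  %Y_HOMO − %Y_LUMO

where %Y_MO is the percentage of the MO carried by fragment Y.  A
positive CT means the donor holds more frontier-occupied density — a
zwitterionic, charge-separated ground state — and predicts negative
solvatochromism; a negative CT means a quinoid ground state and positive
solvatochromism.  An inverted dye switches sign exactly once (quinoid →
zwitterionic) as the medium permittivity ε increases.

The same sign logic applies to BLA/BOA series: quinoid ⇔ BLA > 0 and
BOA < 0, zwitterionic ⇔ BLA < 0 and BOA > 0; disagreeing or vanishing
signs leave the medium indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .qcio import Medium, WavefunctionBundle
from .populations import Fragment, OrbitalComposition, mo_fragment_composition

CALLS = ("negative", "positive", "inverted", "borderline", "anomalous")
STATES = ("zwitterionic", "quinoid", "indeterminate")


@dataclass
class CTProfile:
    """CT(%) per medium for one dye, sorted by ascending permittivity."""

    dye: str
    entries: list[tuple[Medium, float]]
    scheme: str = "npa"
    fragment_y: str = "Y"

    def __post_init__(self):
        if len(self.entries) < 2:
            raise ValidationError("a CT profile needs at least 2 media")
        self.entries = sorted(self.entries, key=lambda e: e[0].epsilon)
        eps = [m.epsilon for m, _ in self.entries]
        if len(set(eps)) != len(eps):
            raise ValidationError("media permittivities must be distinct")
        labels = [m.label for m, _ in self.entries]
        if len(set(labels)) != len(labels):
            raise ValidationError("media labels must be unique within a profile")
        if not all(np.isfinite(ct) for _, ct in self.entries):
            raise ValidationError("CT values must be finite")

    @property
    def media(self) -> list[Medium]:
        return [m for m, _ in self.entries]

    @property
    def ct_values(self) -> list[float]:
        return [ct for _, ct in self.entries]


@dataclass
class SolvatochromismCall:
    """Classification of one dye from a per-medium state sequence."""

    call: str
    states: list[str]                    # per medium, ascending ε
    media: list[Medium]
    inversion_medium: Optional[str] = None
    evidence: str = ""

    def __post_init__(self):
        if self.call not in CALLS:
            raise ValidationError(f"unknown call {self.call!r}")
        if any(s not in STATES for s in self.states):
            raise ValidationError("unknown per-medium state")
        qz = sum(1 for a, b in zip(self.states, self.states[1:])
                 if a == "quinoid" and b == "zwitterionic")
        zq = sum(1 for a, b in zip(self.states, self.states[1:])
                 if a == "zwitterionic" and b == "quinoid")
        is_single_switch = (
            qz == 1 and zq == 0 and "indeterminate" not in self.states
        )
        if self.call == "inverted" and not is_single_switch:
            raise ValidationError(
                "inverted call requires exactly one quinoid→zwitterionic "
                "transition along ascending permittivity"
            )


@dataclass(frozen=True)
class CharacterSeries:
    """Quinoid-minus-zwitterionic character (= −CT) per medium."""

    dye: str
    media: tuple[Medium, ...]
    values: tuple[float, ...]


def ct_from_state_densities(p_y_ground: float, p_y_excited: float) -> float:
    """CT(%) from fractional fragment densities of ground and excited state."""
    for name, v in (("p_y_ground", p_y_ground), ("p_y_excited", p_y_excited)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1], got {v}")
    return 100.0 * (p_y_ground - p_y_excited)


def ct_percent(composition: OrbitalComposition, fragment_y: Fragment | str) -> float:
    """CT(%) = %Y_HOMO − %Y_LUMO from a fragment composition."""
    name = fragment_y.name if isinstance(fragment_y, Fragment) else fragment_y
    if name not in composition.fragment_names:
        raise ValidationError(
            f"composition has no fragment {name!r}; "
            f"available: {composition.fragment_names}"
        )
    return (composition.fragment_percent(name, composition.homo_index)
            - composition.fragment_percent(name, composition.lumo_index))


def ct_profile_from_bundles(
    dye: str,
    bundles: Sequence[WavefunctionBundle],
    fragment_x: Fragment,
    fragment_y: Fragment,
    scheme: str = "npa",
) -> CTProfile:
    """Assemble a CT profile by analysing one bundle per medium."""
    entries = []
    for b in bundles:
        comp = mo_fragment_composition(b, [fragment_x, fragment_y], scheme)
        entries.append((b.medium, ct_percent(comp, fragment_y)))
    return CTProfile(dye=dye, entries=entries, scheme=scheme,
                     fragment_y=fragment_y.name)


def _series_call(states: list[str], media: list[Medium]) -> SolvatochromismCall:
    """Map a per-medium state sequence to the five-way call."""
    evidence = " → ".join(
        f"{m.label}(ε={m.epsilon:g}):{s}" for m, s in zip(media, states)
    )
    if all(s == "zwitterionic" for s in states):
        call, inv = "negative", None
    elif all(s == "quinoid" for s in states):
        call, inv = "positive", None
    elif "indeterminate" in states:
        call, inv = "borderline", None
    else:
        qz = sum(1 for a, b in zip(states, states[1:])
                 if a == "quinoid" and b == "zwitterionic")
        zq = sum(1 for a, b in zip(states, states[1:])
                 if a == "zwitterionic" and b == "quinoid")
        if qz == 1 and zq == 0:
            call = "inverted"
            inv = media[states.index("zwitterionic")].label
        else:
            call, inv = "anomalous", None
    return SolvatochromismCall(call=call, states=states, media=list(media),
                               inversion_medium=inv, evidence=evidence)


def classify_ct_profile(profile: CTProfile, tau: float = 0.0) -> SolvatochromismCall:
    """Classify a CT series: zwitterionic if CT > τ, quinoid if CT < −τ.

    τ defaults to 0 (strict sign); a positive τ opens an indeterminate band
    that maps any ambiguous medium to a borderline call.
    """
    if tau < 0:
        raise ValidationError("tolerance τ must be non-negative")
    states = []
    for ct in profile.ct_values:
        if ct > tau:
            states.append("zwitterionic")
        elif ct < -tau:
            states.append("quinoid")
        else:
            states.append("indeterminate")
    return _series_call(states, profile.media)


def classify_alternation_series(
    bla_series: Sequence[float],
    boa_series: Sequence[float],
    media: Sequence[Medium],
) -> SolvatochromismCall:
    """Classify a BLA/BOA series by the quinoid/zwitterionic sign rules."""
    if not (len(bla_series) == len(boa_series) == len(media)):
        raise ValidationError("BLA, BOA and media series must have equal length")
    if len(media) < 2:
        raise ValidationError("need at least 2 media to classify a series")
    order = np.argsort([m.epsilon for m in media])
    media = [media[i] for i in order]
    bla = [float(bla_series[i]) for i in order]
    boa = [float(boa_series[i]) for i in order]
    states = []
    for l, o in zip(bla, boa):
        if l > 0 and o < 0:
            states.append("quinoid")
        elif l < 0 and o > 0:
            states.append("zwitterionic")
        else:
            states.append("indeterminate")
    return _series_call(states, media)


def character_series(profile: CTProfile) -> CharacterSeries:
    """Quinoid-minus-zwitterionic percentage per medium (the −CT series)."""
    return CharacterSeries(
        dye=profile.dye,
        media=tuple(profile.media),
        values=tuple(-ct for ct in profile.ct_values),
    )


def classification_report(profile: CTProfile, result: SolvatochromismCall) -> dict:
    """JSON-serializable classification report."""
    return {
        "dye": profile.dye,
        "scheme": profile.scheme,
        "fragment_Y": profile.fragment_y,
        "media": [
            {"label": m.label, "epsilon": m.epsilon, "ct": ct, "state": s}
            for (m, ct), s in zip(profile.entries, result.states)
        ],
        "call": result.call,
        "inversion_medium": result.inversion_medium,
        "evidence": result.evidence,
    }


def plot_character_series(series: CharacterSeries, path) -> None:
    """Plot quinoid-minus-zwitterionic character against permittivity."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    eps = [m.epsilon for m in series.media]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(eps, series.values, "o-")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xscale("log")
    ax.set_xlabel("relative permittivity ε")
    ax.set_ylabel("quinoid − zwitterionic character (%)")
    ax.set_title(series.dye)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
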