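"""Published benchmark series for the thirteen-dye phenolate library.

Literature B3LYP/6-31G(d)/PCM results for the standard benchmark set of
pyridinium phenolate solvatochromic dyes (Brooker's merocyanine is dye 1,
its azo analogue dye 2, Reichardt's betaine dye 10), tabulated over the
four-medium polarity series gas → chloroform → dimethyl sulfoxide →
water.  These numbers are *inputs* to the classifier — the published CT(%)
values per medium and the published BLA/BOA series along the two
conjugation pathways — together with each dye's experimentally observed
solvatochromism, used for regression-testing the classification protocol.

Dyes flagged ``borderline_footnote`` show a parabolic solvent response
without a clear inversion point experimentally; the conventional
three-way experimental label kept here is "negative".
"""

from __future__ import annotations

from .qcio import Medium

#: The four-medium polarity series (relative permittivities).
MEDIA = (
    Medium("gas", 1.0),
    Medium("CHCl3", 4.71),
    Medium("Me2SO", 46.83),
    Medium("H2O", 78.36),
)

#: dye label → (experimental solvatochromism, CT(%) per medium, borderline footnote)
CT_TABLE: dict[str, tuple[str, tuple[float, float, float, float], bool]] = {
    "1":  ("inverted", (-1.0, 5.5, 9.8, 9.3), False),
    "2":  ("positive", (-18.5, -10.5, -6.3, -6.0), False),
    "3":  ("positive", (-37.7, -33.0, -30.6, -30.4), False),
    "4":  ("negative", (4.9, 13.2, 17.4, 17.7), False),
    "5":  ("negative", (6.3, 15.5, 21.0, 21.3), True),
    "6":  ("inverted", (-4.5, 3.5, 7.5, 9.9), False),
    "7":  ("negative", (38.6, 44.2, 47.3, 47.5), True),
    "8":  ("negative", (41.7, 48.2, 52.5, 52.8), False),
    "9":  ("inverted", (27.6, 31.9, 34.1, 34.4), False),
    "10": ("negative", (66.0, 71.5, 74.5, 74.6), False),
    "11": ("negative", (51.4, 57.0, 59.7, 59.8), True),
    "12": ("negative", (33.4, 37.1, 38.7, 38.8), True),
    "13": ("negative", (21.6, 25.9, 28.2, 28.3), True),
}

#: (dye, pathway) → BLA series (Å) per medium, oxygen-first convention.
BLA_TABLE: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("1", "P-P"): (0.064, 0.044, 0.032, 0.034),
    ("1", "P-N"): (0.083, -0.062, -0.049, -0.051),
    ("2", "P-P"): (0.074, 0.058, 0.049, 0.049),
    ("2", "P-N"): (-0.098, -0.082, -0.072, -0.072),
    ("10", "P-P"): (-0.027, -0.017, -0.013, -0.013),
    ("10", "P-N"): (0.088, 0.069, 0.062, 0.062),
}

#: (dye, pathway) → BOA series (dimensionless) per medium.
BOA_TABLE: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("1", "P-P"): (-0.302, -0.266, -0.240, -0.244),
    ("1", "P-N"): (-0.408, 0.369, 0.341, 0.345),
    ("2", "P-P"): (-0.317, -0.290, -0.273, -0.272),
    ("2", "P-N"): (0.421, 0.391, 0.373, 0.372),
    ("10", "P-P"): (0.051, 0.033, 0.025, 0.025),
    ("10", "P-N"): (-0.144, -0.112, -0.097, -0.096),
}
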