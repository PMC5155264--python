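"""Monoisotopic mass arithmetic for dansylation labeling.

Dansylation tags amine/phenol groups with a dansyl group (net addition
C12H11NO2S per tag).  The heavy reagent carries two 13C substitutions per
tag, so each heavy tag weighs ``DELTA_TAG`` more than its light
counterpart.  Bis-dansylated ammonia is a ubiquitous reagent by-product
whose ions serve as internal mass calibrants.
"""

from __future__ import annotations

# CODATA / IUPAC monoisotopic atomic masses (Da)
MASS_C12 = 12.0
MASS_C13 = 13.0033548378
MASS_H = 1.00782503207
MASS_N = 14.0030740048
MASS_O = 15.9949146196
MASS_S = 31.97207100

#: mass of a proton (Da); charge carrier in positive-mode ESI
PROTON = 1.007276

#: net monoisotopic mass added per light dansyl tag (C12H11NO2S)
TAG_LIGHT = 12 * MASS_C12 + 11 * MASS_H + MASS_N + 2 * MASS_O + MASS_S

#: mass excess of one heavy (13C2) dansyl tag over the light tag
DELTA_TAG = 2 * (MASS_C13 - MASS_C12)

#: neutral monoisotopic mass of bis-dansylated ammonia, all-light (C24H25N3O4S2)
_DANSYL_AMINE_NEUTRAL = 24 * MASS_C12 + 25 * MASS_H + 3 * MASS_N + 4 * MASS_O + 2 * MASS_S


def formula_mass(counts: dict[str, int]) -> float:
    """Monoisotopic mass of a neutral formula given as {element: count}."""
    table = {"C": MASS_C12, "H": MASS_H, "N": MASS_N, "O": MASS_O, "S": MASS_S}
    try:
        return sum(table[el] * n for el, n in counts.items())
    except KeyError as exc:  # pragma: no cover - guard
        raise ValueError(f"unsupported element {exc}") from None


def mz_from_neutral(neutral_mass: float, charge: int) -> float:
    """m/z of a neutral species protonated ``charge`` times."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + charge * PROTON) / charge


def calibrant_mz(tags_light: int, tags_heavy: int = 0, charge: int = 1,
                 dimer: bool = False) -> float:
    """Theoretical m/z of a bis-dansylated-ammonia calibrant ion.

    The monomer carries exactly two dansyl tags (``tags_light`` light +
    ``tags_heavy`` heavy); each heavy tag adds :data:`DELTA_TAG`.  With
    ``dimer=True`` the ion is the singly protonated proton-bound dimer of
    the all-light monomer and a monomer carrying ``tags_heavy`` heavy tags.

    Parameters
    ----------
    tags_light, tags_heavy : int
        Tag composition of the (non-dimer) monomer, must sum to 2.
    charge : int
        Protonation state, 1 or 2 (dimer supports only 1).
    dimer : bool
        Proton-bound light+heavy dimer instead of a monomer ion.
    """
    if dimer:
        if charge != 1:
            raise ValueError("dimer calibrant is only observed singly charged")
        if not 0 <= tags_heavy <= 2:
            raise ValueError("dimer heavy monomer carries 0-2 heavy tags")
        light = _DANSYL_AMINE_NEUTRAL
        heavy = _DANSYL_AMINE_NEUTRAL + tags_heavy * DELTA_TAG
        return mz_from_neutral(light + heavy, 1)
    if tags_light + tags_heavy != 2 or tags_light < 0 or tags_heavy < 0:
        raise ValueError("monomer calibrant carries exactly two dansyl tags")
    if charge not in (1, 2):
        raise ValueError("supported charge states are 1 and 2")
    neutral = _DANSYL_AMINE_NEUTRAL + tags_heavy * DELTA_TAG
    return mz_from_neutral(neutral, charge)


def default_calibrant_mzs() -> list[float]:
    """The three dansyl-amine calibrant ions observed in every run:
    doubly charged all-light monomer, singly charged all-light monomer,
    and the proton-bound dimer of the light monomer with the 2-heavy-tag
    monomer."""
    return [
        calibrant_mz(2, 0, charge=2),
        calibrant_mz(2, 0, charge=1),
        calibrant_mz(0, 2, charge=1, dimer=True),
    ]


def light_mz(mass_1tag_z1: float, n_tags: int, charge: int) -> float:
    """m/z of the light (12C) ion with ``n_tags`` tags and ``charge``
    protons, given the m/z of its singly tagged, singly protonated form."""
    neutral_1tag = mass_1tag_z1 - PROTON
    neutral = neutral_1tag + (n_tags - 1) * TAG_LIGHT
    return mz_from_neutral(neutral, charge)


def heavy_mz(mz_light: float, n_tags: int, charge: int) -> float:
    """m/z of the heavy (13C) partner of a light ion."""
    return mz_light + n_tags * DELTA_TAG / charge


def to_1tag_z1(mz_light: float, n_tags: int, charge: int) -> float:
    """Reduce an observed light m/z to its 1-tag, z=1 equivalent for
    library matching."""
    neutral = mz_light * charge - charge * PROTON
    neutral_1tag = neutral - (n_tags - 1) * TAG_LIGHT
    return neutral_1tag + PROTON
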