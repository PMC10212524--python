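"""Monoisotopic atomic masses and adduct bookkeeping.

Masses are IUPAC/CODATA monoisotopic values in Da. Only the elements that
occur in polyisoprenoid alcohols, phytosterols and the supported ESI adducts
are listed; extend ``MONOISOTOPIC_MASS`` for other analytes.
"""

from __future__ import annotations

from .errors import ConfigurationError

MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "P": 30.97376163,
    "S": 31.97207100,
}

ELECTRON_MASS: float = 0.000548579909

#: adduct name -> (extra formula, charge); m/z = (M + extra - charge * e) / charge
_ADDUCTS: dict[str, tuple[dict[str, int], int]] = {
    "M+": ({}, 1),
    "[M+H]+": ({"H": 1}, 1),
    "[M+Na]+": ({"Na": 1}, 1),
    "[M+K]+": ({"K": 1}, 1),
    "[M+NH4]+": ({"N": 1, "H": 4}, 1),
}

SUPPORTED_ADDUCTS = tuple(_ADDUCTS)


def formula_mass(formula: dict[str, int]) -> float:
    """Monoisotopic mass (Da) of a neutral molecule given as element -> count."""
    try:
        return sum(MONOISOTOPIC_MASS[el] * count for el, count in formula.items())
    except KeyError as exc:  # pragma: no cover - defensive
        raise ConfigurationError(f"no monoisotopic mass tabulated for element {exc}") from exc


def adduct_mz(neutral_formula: dict[str, int], adduct: str) -> float:
    """m/z of the monoisotopic ion formed from ``neutral_formula`` via ``adduct``.

    Supported adducts: molecular cation M+ and the protonated, sodiated,
    potassiated and ammoniated species. The electron mass is subtracted for
    each positive charge.
    """
    if adduct not in _ADDUCTS:
        raise ConfigurationError(
            f"unknown adduct {adduct!r}; supported: {', '.join(SUPPORTED_ADDUCTS)}"
        )
    extra, charge = _ADDUCTS[adduct]
    mass = formula_mass(neutral_formula) + formula_mass(extra) - charge * ELECTRON_MASS
    return mass / charge
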