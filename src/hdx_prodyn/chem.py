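"""Elemental masses, peptide compositions, and isotopic envelopes.

Everything downstream that touches a mass goes through this module: average
and monoisotopic molecular masses for formulas, peptides and a few named
ligands, plus natural isotopic envelopes computed exactly from elemental
composition (no averagine approximation -- peptides here are short and their
compositions are known).
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Iterable, Mapping

__all__ = [
    "AVERAGE_ATOMIC_MASS",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "DEUTERIUM_MASS_SHIFT",
    "RESIDUE_FORMULAS",
    "WATER",
    "NAMED_COMPOUNDS",
    "parse_formula",
    "peptide_composition",
    "formula_mass",
    "molecular_mass",
    "isotopic_envelope",
    "envelope_centroid_mass",
]

# CIAAW standard atomic weights (abridged, 2021).
AVERAGE_ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}

# Principal (most abundant) isotope masses, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376199,
}

PROTON_MASS = 1.007276466812

#: mass(2H) - mass(1H), Da; the spacing added per incorporated deuteron.
DEUTERIUM_MASS_SHIFT = 2.0141017781 - 1.0078250319  # 1.00628 Da

# Isotope tables: element -> list of (extra neutrons, exact mass, abundance).
_ISOTOPES: dict[str, list[tuple[int, float, float]]] = {
    "H": [(0, 1.0078250319, 0.999885), (1, 2.0141017781, 0.000115)],
    "C": [(0, 12.0, 0.9893), (1, 13.0033548351, 0.0107)],
    "N": [(0, 14.0030740052, 0.99636), (1, 15.0001088989, 0.00364)],
    "O": [
        (0, 15.9949146221, 0.99757),
        (1, 16.9991317565, 0.00038),
        (2, 17.9991596129, 0.00205),
    ],
    "S": [
        (0, 31.97207069, 0.9499),
        (1, 32.9714589098, 0.0075),
        (2, 33.967867004, 0.0425),
        (4, 35.96708071, 0.0001),
    ],
    "P": [(0, 30.97376199, 1.0)],
}

# Amino-acid *residue* compositions (free amino acid minus one water).
RESIDUE_FORMULAS: dict[str, Mapping[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

WATER: Mapping[str, int] = {"H": 2, "O": 1}

# Named small molecules accepted by molecular_mass().  Xylohexaose is six
# beta-1,4-linked xylose units: 6 x C5H10O5 condensed with loss of 5 waters.
NAMED_COMPOUNDS: dict[str, Mapping[str, int]] = {
    "water": WATER,
    "xylose": {"C": 5, "H": 10, "O": 5},
    "xylohexaose": {"C": 30, "H": 50, "O": 25},
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Counter:
    """Parse an elemental formula like ``C4H8N2O3`` into element counts.

    Raises ``ValueError`` on unknown elements or malformed input.
    """
    if not formula or not formula.strip():
        raise ValueError("empty formula")
    counts: Counter = Counter()
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"malformed formula {formula!r} at position {pos}")
        element, digits = match.groups()
        if element not in AVERAGE_ATOMIC_MASS:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        counts[element] += int(digits) if digits else 1
        pos = match.end()
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r} at position {pos}")
    return counts


def peptide_composition(sequence: str) -> Counter:
    """Elemental composition of a peptide: residue formulas plus one water."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    counts: Counter = Counter(WATER)
    for i, letter in enumerate(sequence):
        try:
            counts.update(RESIDUE_FORMULAS[letter])
        except KeyError:
            raise ValueError(
                f"unknown residue {letter!r} at position {i + 1} in {sequence!r}"
            ) from None
    return counts


def formula_mass(composition: Mapping[str, int], kind: str = "average") -> float:
    """Mass of an elemental composition in Da.

    ``kind`` selects standard atomic weights (``"average"``) or principal
    isotope masses (``"monoisotopic"``).
    """
    if kind == "average":
        table = AVERAGE_ATOMIC_MASS
    elif kind == "monoisotopic":
        table = MONOISOTOPIC_MASS
    else:
        raise ValueError(f"kind must be 'average' or 'monoisotopic', got {kind!r}")
    try:
        return sum(table[el] * n for el, n in composition.items())
    except KeyError as exc:
        raise ValueError(f"unknown element {exc.args[0]!r}") from None


def molecular_mass(what: str | Mapping[str, int], kind: str = "average") -> float:
    """Molecular mass in g/mol (Da) of a formula, peptide, or named compound.

    Dispatch order for strings: named compound (case-insensitive), then
    one-letter peptide sequence (any string made only of residue letters,
    e.g. ``"GG"`` or ``"C"``), then elemental formula (``"C4H8N2O3"``).  A
    mapping is taken as an elemental composition directly.
    """
    if isinstance(what, Mapping):
        return formula_mass(what, kind)
    name = what.strip()
    lowered = name.lower()
    if lowered in NAMED_COMPOUNDS:
        return formula_mass(NAMED_COMPOUNDS[lowered], kind)
    if name and all(c in RESIDUE_FORMULAS for c in name):
        return formula_mass(peptide_composition(name), kind)
    try:
        composition = parse_formula(name)
    except ValueError:
        raise ValueError(
            f"cannot interpret {what!r} as compound, formula, or peptide"
        ) from None
    return formula_mass(composition, kind)


# ---------------------------------------------------------------------------
# Isotopic envelopes
# ---------------------------------------------------------------------------

# A distribution is a dict: extra-neutron count -> (probability, expected mass
# of that aggregated peak).  Peaks within one nominal bin are merged with an
# abundance-weighted mass, which preserves the overall centroid exactly.
_Dist = dict[int, tuple[float, float]]


def _convolve(a: _Dist, b: _Dist, prune: float) -> _Dist:
    out: dict[int, list[float]] = {}
    for ka, (pa, ma) in a.items():
        for kb, (pb, mb) in b.items():
            p = pa * pb
            if p < prune:
                continue
            acc = out.setdefault(ka + kb, [0.0, 0.0])
            acc[0] += p
            acc[1] += p * (ma + mb)
    return {k: (p, m / p) for k, (p, m) in sorted(out.items())}


def _element_envelope(element: str, count: int, prune: float) -> _Dist:
    base: _Dist = {k: (p, m) for k, m, p in _ISOTOPES[element]}
    result: _Dist = {0: (1.0, 0.0)}
    power = base
    n = count
    while n:
        if n & 1:
            result = _convolve(result, power, prune)
        n >>= 1
        if n:
            power = _convolve(power, power, prune)
    return result


def isotopic_envelope(
    composition: Mapping[str, int], prune: float = 1e-12
) -> list[tuple[float, float]]:
    """Natural isotopic envelope of a neutral molecule.

    Returns a list of ``(mass, abundance)`` aggregated by nominal isotope
    peak (extra-neutron count), sorted by mass, abundances summing to ~1.
    Each peak's mass is the abundance-weighted exact mass within its bin.
    """
    total: _Dist = {0: (1.0, 0.0)}
    for element, count in sorted(composition.items()):
        if count < 0:
            raise ValueError(f"negative count for element {element!r}")
        if count == 0:
            continue
        if element not in _ISOTOPES:
            raise ValueError(f"no isotope table for element {element!r}")
        total = _convolve(total, _element_envelope(element, count, prune), prune)
    norm = sum(p for p, _ in total.values())
    return [(m, p / norm) for _, (p, m) in sorted(total.items())]


def envelope_centroid_mass(envelope: Iterable[tuple[float, float]]) -> float:
    """Abundance-weighted mean mass of an envelope."""
    peaks = list(envelope)
    weight = sum(p for _, p in peaks)
    if weight <= 0:
        raise ValueError("envelope has no abundance")
    return sum(m * p for m, p in peaks) / weight
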