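"""Molecular formulas, monoisotopic masses, isotope patterns and formula search.

The exact-mass conventions here follow common natural-product dereplication
practice for singly protonated / metallated cations measured on TOF
instruments: an ion's m/z is the plain sum of neutral atomic monoisotopic
masses of its atomic composition (no electron-mass subtraction), which is the
convention the reference HRMS "calcd" values in this package's regression
suite were produced with.  An opt-in electron correction is available for
users who prefer the physically exact cation mass.

Atomic masses and isotopic abundances are embedded as a fixed snapshot of the
IUPAC/CIAAW tables so that results are bit-stable across environments.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

__all__ = [
    "ElementCount",
    "IonSpec",
    "IsotopePattern",
    "ELECTRON_MASS",
    "MONOISOTOPIC_MASS",
    "ISOTOPES",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "ion_mz",
    "isotope_pattern",
    "rdbe",
    "formula_search",
    "PROTONATED",
    "FERRIC",
    "FERRIC_ACN",
    "STANDARD_IONS",
]

# --------------------------------------------------------------------------
# Embedded IUPAC/CIAAW isotope table (snapshot; masses in Da, abundances as
# mole fractions summing to 1 per element).  Only elements that occur in the
# porphyrin/hemin chemistry handled here, plus S and P for generality.
# --------------------------------------------------------------------------

#: (isotope mass, natural abundance) per element, most abundant first not
#: required; kept in mass order.
ISOTOPES: Dict[str, Tuple[Tuple[float, float], ...]] = {
    "H": ((1.00782503207, 0.999885), (2.01410177785, 0.000115)),
    "C": ((12.0, 0.9893), (13.0033548378, 0.0107)),
    "N": ((14.0030740048, 0.99636), (15.0001088982, 0.00364)),
    "O": (
        (15.9949146196, 0.99757),
        (16.9991317012, 0.00038),
        (17.9991610070, 0.00205),
    ),
    "P": ((30.9737616320, 1.0),),
    "S": (
        (31.9720710015, 0.9499),
        (32.9714587600, 0.0075),
        (33.9678669000, 0.0425),
        (35.9670808800, 0.0001),
    ),
    "Fe": (
        (53.9396105000, 0.05845),
        (55.9349363000, 0.91754),
        (56.9353940000, 0.02119),
        (57.9332756000, 0.00282),
    ),
}

#: Mass of the most abundant isotope per element (⁵⁶Fe for iron).
MONOISOTOPIC_MASS: Dict[str, float] = {
    el: max(isos, key=lambda p: p[1])[0] for el, isos in ISOTOPES.items()
}

ELECTRON_MASS = 0.00054857990907  # Da (CODATA)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown element symbols."""


@dataclass(frozen=True)
class ElementCount:
    """A molecular formula as an element → count multiset.

    Counts are non-negative; zero-count entries are dropped so that equal
    compositions compare equal.  The empty formula is allowed (mass 0).
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if not isinstance(n, int):
                raise FormulaError(f"count for {el!r} must be an integer, got {n!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {el!r}: {n}")
            if el not in ISOTOPES:
                raise FormulaError(f"unknown element symbol {el!r}")
            if n:
                clean[el] = n
        object.__setattr__(self, "counts", dict(clean))

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __iter__(self):
        return iter(self.counts.items())

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "ElementCount") -> "ElementCount":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementCount(merged)

    def add_delta(self, delta: Mapping[str, int]) -> "ElementCount":
        """Apply a signed element-count change; negative results are errors."""
        merged = dict(self.counts)
        for el, n in delta.items():
            new = merged.get(el, 0) + n
            if new < 0:
                raise FormulaError(
                    f"applying delta leaves negative count for {el!r} "
                    f"({merged.get(el, 0)} + {n})"
                )
            merged[el] = new
        return ElementCount(merged)

    def __str__(self) -> str:
        return format_formula(self)


def parse_formula(text: str) -> ElementCount:
    """Parse a Hill-style formula string ("C24H23N4") into an :class:`ElementCount`.

    Counts default to 1; repeated symbols accumulate.  Unknown element symbols
    and zero-prefixed or explicit-zero counts raise :class:`FormulaError`.
    """
    text = text.strip()
    if not text:
        return ElementCount({})
    pos = 0
    counts: Dict[str, int] = {}
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"unparseable formula {text!r} at position {pos}")
        pos = match.end()
        el, digits = match.groups()
        if el not in ISOTOPES:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        if digits == "":
            n = 1
        else:
            if digits[0] == "0":
                raise FormulaError(
                    f"zero or zero-prefixed count {digits!r} for {el!r} in {text!r}"
                )
            n = int(digits)
        counts[el] = counts.get(el, 0) + n
    if pos != len(text):
        raise FormulaError(f"unparseable formula {text!r} at position {pos}")
    return ElementCount(counts)


def format_formula(f: ElementCount) -> str:
    """Canonical Hill-order writer: C, H, then other elements alphabetically."""
    parts = []
    order = [el for el in ("C", "H") if f[el]]
    order += sorted(el for el in f.counts if el not in ("C", "H"))
    for el in order:
        n = f[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def monoisotopic_mass(f: ElementCount) -> float:
    """Sum of count × most-abundant-isotope mass over the formula's elements."""
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in f)


@dataclass(frozen=True)
class IonSpec:
    """An ionization/adduct transformation applied to a neutral formula.

    ``delta_counts`` is the signed element change, e.g. ``{"H": 1}`` for
    [M+H]⁺ or ``{"H": -2, "Fe": 1}`` for the ferric hemin ion.  Only singly
    charged cations are supported.
    """

    name: str
    delta_counts: Mapping[str, int]
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge != 1:
            raise ValueError("only singly charged cations are supported")
        object.__setattr__(self, "delta_counts", dict(self.delta_counts))

    def apply(self, neutral: ElementCount) -> ElementCount:
        return neutral.add_delta(self.delta_counts)


PROTONATED = IonSpec("[M+H]+", {"H": 1})
FERRIC = IonSpec("[M-2H+Fe]+", {"H": -2, "Fe": 1})
FERRIC_ACN = IonSpec("[M-2H+Fe+ACN]+", {"H": 1, "Fe": 1, "C": 2, "N": 1})

STANDARD_IONS: Tuple[IonSpec, ...] = (PROTONATED, FERRIC, FERRIC_ACN)


def ion_mz(
    neutral: ElementCount, ion: IonSpec, *, electron_correction: bool = False
) -> float:
    """m/z of ``neutral`` under the given ion transformation.

    By default the cation mass is the plain atomic-mass sum (the reference
    "calcd" convention); with ``electron_correction`` the electron mass times
    the charge is subtracted.
    """
    mass = monoisotopic_mass(ion.apply(neutral))
    if electron_correction:
        mass -= ELECTRON_MASS * ion.charge
    return mass / ion.charge


# --------------------------------------------------------------------------
# Isotope-pattern convolution
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IsotopePattern:
    """Aggregated-isotopologue pattern: (mass, relative abundance) peaks.

    Masses are strictly increasing.  ``relative`` abundances are normalized to
    the most intense peak = 1; ``fractions`` keep the absolute mole fractions
    (summing to ≤ 1 after pruning, ≥ 0.99 of the total retained).
    """

    peaks: Tuple[Tuple[float, float], ...]
    fractions: Tuple[float, ...]

    @property
    def masses(self) -> Tuple[float, ...]:
        return tuple(m for m, _ in self.peaks)

    @property
    def base_peak_mass(self) -> float:
        return max(self.peaks, key=lambda p: p[1])[0]


def _merge(dist: List[Tuple[float, float]], width: float) -> List[Tuple[float, float]]:
    """Merge peaks closer than ``width`` Da (abundance-weighted centroid)."""
    dist.sort(key=lambda p: p[0])
    merged: List[Tuple[float, float]] = []
    for m, a in dist:
        if merged and m - merged[-1][0] < width:
            pm, pa = merged[-1]
            tot = pa + a
            merged[-1] = ((pm * pa + m * a) / tot, tot)
        else:
            merged.append((m, a))
    return merged


def _element_distribution(el: str, n: int, width: float, floor: float) -> List[Tuple[float, float]]:
    # multinomial expansion over the element's isotopes; exact for small k
    isos = ISOTOPES[el]
    if len(isos) == 1:
        return [(isos[0][0] * n, 1.0)]
    dist = [(0.0, 1.0)]
    remaining = n
    # repeated squaring-style doubling keeps the list short
    single = [(m, a) for m, a in isos]
    power = single
    out = [(0.0, 1.0)]
    while remaining:
        if remaining & 1:
            out = _convolve(out, power, width, floor)
        remaining >>= 1
        if remaining:
            power = _convolve(power, power, width, floor)
    return out


def _convolve(
    a: List[Tuple[float, float]],
    b: List[Tuple[float, float]],
    width: float,
    floor: float,
) -> List[Tuple[float, float]]:
    dist = [(ma + mb, pa * pb) for ma, pa in a for mb, pb in b]
    dist = _merge(dist, width)
    return [(m, p) for m, p in dist if p >= floor]


def isotope_pattern(
    f: ElementCount,
    prune_threshold: float = 1e-4,
    *,
    merge_width: float = 0.01,
) -> IsotopePattern:
    """Natural-abundance isotope pattern of a formula.

    Convolves each element's isotope distribution, merging aggregated peaks
    within ``merge_width`` Da (0.01 Da default — adequate for the
    unit-resolved TOF clusters this package targets).  Peaks are pruned below
    ``prune_threshold`` relative to the base peak; the retained peaks always
    carry ≥ 99% of the total abundance.

    Raises ``ValueError`` for an empty formula or a threshold outside (0, 1).
    """
    if not f:
        raise ValueError("isotope_pattern requires a non-empty formula")
    if not 0.0 < prune_threshold < 1.0:
        raise ValueError("prune_threshold must lie in (0, 1)")
    floor = 1e-12
    dist = [(0.0, 1.0)]
    for el, n in f:
        dist = _convolve(dist, _element_distribution(el, n, merge_width, floor), merge_width, floor)
    dist = _merge(dist, merge_width)
    total = sum(p for _, p in dist)
    base = max(p for _, p in dist)
    kept = [(m, p) for m, p in dist if p / base >= prune_threshold]
    # pruning must never discard more than 1% of the abundance
    while sum(p for _, p in kept) < 0.99 * total:
        dropped = sorted((p for _, p in dist if (p / base) < prune_threshold), reverse=True)
        prune_threshold = dropped[0] / base if dropped else 0.0
        kept = [(m, p) for m, p in dist if p / base >= prune_threshold]
    kept.sort(key=lambda p: p[0])
    return IsotopePattern(
        peaks=tuple((m, p / base) for m, p in kept),
        fractions=tuple(p / total for _, p in kept),
    )


# --------------------------------------------------------------------------
# Formula search (bounded exhaustive decomposition)
# --------------------------------------------------------------------------

def rdbe(f: ElementCount, *, fe_valence: int = 0) -> float:
    """Ring-plus-double-bond equivalents; Fe contributes ``fe_valence`` (default 0).

    RDBE = 1 + C + N/2 − H/2 (O, S neutral); half-integral values occur for
    cation compositions such as protonated species.
    """
    return (
        1.0
        + f["C"]
        + 0.5 * f["N"]
        + 0.5 * f["P"]
        - 0.5 * f["H"]
        + 0.5 * fe_valence * f["Fe"]
    )


DEFAULT_BOUNDS: Dict[str, Tuple[int, int]] = {
    "C": (0, 40),
    "H": (0, 60),
    "N": (0, 8),
    "O": (0, 8),
    "Fe": (0, 1),
}


@dataclass(frozen=True)
class FormulaHit:
    """One candidate cation composition from :func:`formula_search`."""

    formula: ElementCount
    calc_mz: float
    ppm_error: float
    rdbe: float

    def to_dict(self) -> dict:
        return {
            "formula": format_formula(self.formula),
            "calc_mz": self.calc_mz,
            "ppm_error": self.ppm_error,
            "rdbe": self.rdbe,
        }


def formula_search(
    mz: float,
    tol_ppm: float = 5.0,
    bounds: Mapping[str, Tuple[int, int]] | None = None,
    rdbe_range: Tuple[float, float] = (0.0, 25.0),
    *,
    electron_correction: bool = False,
) -> List[FormulaHit]:
    """Enumerate every cation composition within ``tol_ppm`` of ``mz``.

    The search is exhaustive over the per-element (min, max) ``bounds``
    (default C≤40 H≤60 N≤8 O≤8 Fe≤1) with depth-first mass pruning, then
    filtered by the RDBE window (Fe treated as contributing 0 ring/double-bond
    equivalents so metal complexes are not excluded).  Hits are sorted by
    absolute ppm error, ties by formula string.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if bounds is None:
        bounds = DEFAULT_BOUNDS
    for el, (lo, hi) in bounds.items():
        if el not in ISOTOPES:
            raise FormulaError(f"unknown element symbol {el!r} in bounds")
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid bounds for {el!r}: ({lo}, {hi})")

    correction = ELECTRON_MASS if electron_correction else 0.0
    target = mz + correction
    tol_da = mz * tol_ppm * 1e-6
    elements = sorted(bounds, key=lambda el: -MONOISOTOPIC_MASS[el])
    hits: List[FormulaHit] = []

    def descend(idx: int, counts: Dict[str, int], mass: float, min_rest: float) -> None:
        if idx == len(elements):
            if abs(mass - target) <= tol_da:
                f = ElementCount(dict(counts))
                r = rdbe(f)
                if rdbe_range[0] <= r <= rdbe_range[1]:
                    calc = mass - correction
                    hits.append(
                        FormulaHit(f, calc, (mz - calc) / calc * 1e6 if calc else 0.0, r)
                    )
            return
        el = elements[idx]
        lo, hi = bounds[el]
        m_el = MONOISOTOPIC_MASS[el]
        rest_min = sum(bounds[e][0] * MONOISOTOPIC_MASS[e] for e in elements[idx + 1 :])
        for n in range(lo, hi + 1):
            new_mass = mass + n * m_el
            if new_mass + rest_min > target + tol_da:
                break
            counts[el] = n
            descend(idx + 1, counts, new_mass, 0.0)
        counts.pop(el, None)

    descend(0, {}, 0.0, 0.0)
    hits.sort(key=lambda h: (abs(h.ppm_error), format_formula(h.formula)))
    return hits
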