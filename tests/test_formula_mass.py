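"""Formula parsing, exact masses, isotope patterns and formula search."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from porphyrintools.formula_mass import (
    DEFAULT_BOUNDS,
    ELECTRON_MASS,
    ElementCount,
    FormulaError,
    ISOTOPES,
    MONOISOTOPIC_MASS,
    FERRIC,
    FERRIC_ACN,
    PROTONATED,
    format_formula,
    formula_search,
    ion_mz,
    isotope_pattern,
    monoisotopic_mass,
    parse_formula,
    rdbe,
)

from conftest import CALCD_VALUES


# ---------------------------------------------------------------- parsing

@pytest.mark.parametrize(
    "text,expected",
    [
        ("C24H23N4", {"C": 24, "H": 23, "N": 4}),
        ("H", {"H": 1}),
        ("C26H23N5Fe", {"C": 26, "H": 23, "N": 5, "Fe": 1}),
        ("", {}),
        ("CHN", {"C": 1, "H": 1, "N": 1}),
    ],
)
def test_parse_formula(text, expected):
    assert dict(parse_formula(text).counts) == expected


@pytest.mark.parametrize("bad", ["Xx4", "C24H0", "C24H05", "24C", "C-2"])
def test_parse_formula_rejects(bad):
    with pytest.raises(FormulaError):
        parse_formula(bad)


formula_strategy = st.dictionaries(
    st.sampled_from(sorted(ISOTOPES)), st.integers(1, 60), min_size=0, max_size=5
)


@settings(max_examples=100, derandomize=True)
@given(formula_strategy)
def test_parse_format_roundtrip(counts):
    f = ElementCount(counts)
    assert parse_formula(format_formula(f)) == f


# ---------------------------------------------------------------- masses

@pytest.mark.parametrize("formula,calcd", CALCD_VALUES)
def test_reference_calcd_values(formula, calcd):
    """All twelve published calcd cation m/z reproduced to ±0.0005 Da."""
    assert monoisotopic_mass(parse_formula(formula)) == pytest.approx(calcd, abs=5e-4)


def test_water_mass():
    # 2×1.0078250 + 15.9949146
    assert monoisotopic_mass(parse_formula("H2O")) == pytest.approx(18.0106, abs=5e-4)


def test_empty_formula_mass_zero():
    assert monoisotopic_mass(ElementCount({})) == 0.0


@settings(max_examples=100, derandomize=True)
@given(formula_strategy, formula_strategy)
def test_mass_additivity(a, b):
    fa, fb = ElementCount(a), ElementCount(b)
    assert monoisotopic_mass(fa + fb) == pytest.approx(
        monoisotopic_mass(fa) + monoisotopic_mass(fb), abs=1e-9
    )


def test_mass_against_pyteomics():
    """Independent cross-check of the embedded mass table."""
    pyteomics_mass = pytest.importorskip("pyteomics.mass")
    for formula, _ in CALCD_VALUES:
        f = parse_formula(formula)
        ref = pyteomics_mass.calculate_mass(
            composition=dict(f.counts), absolute=True
        )
        assert monoisotopic_mass(f) == pytest.approx(ref, abs=2e-4)


# ---------------------------------------------------------------- ion m/z

@pytest.mark.parametrize(
    "neutral,ion,expected",
    [
        ("C24H22N4", PROTONATED, 367.1923),
        ("C24H22N4", FERRIC, 420.1037),
        ("C24H22N4", FERRIC_ACN, 461.1303),
        ("C30H30N4O4", FERRIC, 564.1460),
    ],
)
def test_ion_mz(neutral, ion, expected):
    assert ion_mz(parse_formula(neutral), ion) == pytest.approx(expected, abs=5e-4)


def test_ion_mz_electron_correction_flag():
    plain = ion_mz(parse_formula("C24H22N4"), PROTONATED)
    corrected = ion_mz(parse_formula("C24H22N4"), PROTONATED, electron_correction=True)
    assert plain - corrected == pytest.approx(ELECTRON_MASS, abs=1e-12)


def test_ion_mz_negative_count_error():
    with pytest.raises(FormulaError):
        ion_mz(parse_formula("C2O2"), FERRIC)  # no H to remove


# ---------------------------------------------------------------- isotope patterns

def brute_force_pattern(f: ElementCount, merge_width=0.01):
    """Oracle: explicit enumeration over all isotopologues (small formulas)."""
    atoms = [el for el, n in f for _ in range(n)]
    agg = {}
    for combo in itertools.product(*(ISOTOPES[el] for el in atoms)):
        mass = sum(m for m, _ in combo)
        ab = math.prod(a for _, a in combo)
        agg[round(mass, 6)] = agg.get(round(mass, 6), 0.0) + ab
    # merge within width
    merged = []
    for m in sorted(agg):
        if merged and m - merged[-1][0] < merge_width:
            pm, pa = merged[-1]
            tot = pa + agg[m]
            merged[-1] = ((pm * pa + m * agg[m]) / tot, tot)
        else:
            merged.append((m, agg[m]))
    return merged


@pytest.mark.parametrize("formula", ["Fe", "C", "H", "CH4", "C2HN", "FeO", "C3H2"])
def test_pattern_matches_brute_force(formula):
    f = parse_formula(formula)
    oracle = brute_force_pattern(f)
    got = isotope_pattern(f, prune_threshold=1e-9)
    base = max(a for _, a in oracle)
    oracle_kept = [(m, a / base) for m, a in oracle if a / base >= 1e-9]
    assert len(got.peaks) == len(oracle_kept)
    for (gm, ga), (om, oa) in zip(got.peaks, oracle_kept):
        assert gm == pytest.approx(om, abs=1e-4)
        assert ga == pytest.approx(oa, rel=1e-6)


def test_fe_pattern_ratios():
    p = isotope_pattern(parse_formula("Fe"), 1e-3)
    rel = {round(m): a for m, a in p.peaks}
    assert rel[54] == pytest.approx(0.0637, abs=2e-3)
    assert rel[56] == 1.0
    assert rel[57] == pytest.approx(0.0231, abs=2e-3)
    assert rel[58] == pytest.approx(0.0031, abs=1e-3)


def test_c_pattern_ratio():
    p = isotope_pattern(parse_formula("C"), 1e-3)
    assert len(p.peaks) == 2
    assert p.peaks[1][1] == pytest.approx(0.0107 / 0.9893, abs=1e-4)


def test_pattern_fractions_sum_and_retention():
    for formula in ("H", "C24H20N4Fe", "C32H34N4O4"):
        p = isotope_pattern(parse_formula(formula), prune_threshold=1e-2)
        assert sum(p.fractions) >= 0.99
        assert all(0 < a <= 1 for _, a in p.peaks)
        masses = p.masses
        assert all(b > a for a, b in zip(masses, masses[1:]))


def test_pattern_rejects_bad_input():
    with pytest.raises(ValueError):
        isotope_pattern(ElementCount({}))
    with pytest.raises(ValueError):
        isotope_pattern(parse_formula("C"), prune_threshold=1.5)


# ---------------------------------------------------------------- formula search

def brute_force_search(mz, tol_ppm, bounds, rdbe_range=(0.0, 25.0)):
    """Oracle: full nested enumeration over the bounds."""
    els = sorted(bounds)
    out = set()
    for counts in itertools.product(
        *(range(bounds[el][0], bounds[el][1] + 1) for el in els)
    ):
        f = ElementCount(dict(zip(els, counts)))
        mass = monoisotopic_mass(f)
        if mass == 0:
            continue
        if abs(mass - mz) <= mz * tol_ppm * 1e-6:
            if rdbe_range[0] <= rdbe(f) <= rdbe_range[1]:
                out.add(format_formula(f))
    return out


@pytest.mark.parametrize(
    "mz,bounds",
    [
        (95.0, {"C": (0, 8), "H": (0, 12), "N": (0, 3), "O": (0, 3)}),
        (130.05, {"C": (0, 10), "H": (0, 14), "N": (0, 2), "O": (0, 4), "Fe": (0, 1)}),
        (180.1, {"C": (0, 12), "H": (0, 20), "O": (0, 6)}),
    ],
)
def test_search_matches_brute_force(mz, bounds):
    got = {format_formula(h.formula) for h in formula_search(mz, 20.0, bounds)}
    assert got == brute_force_search(mz, 20.0, bounds)


def test_search_finds_reference_compositions():
    hits = {format_formula(h.formula) for h in formula_search(367.1924, 5.0)}
    assert "C24H23N4" in hits
    hits = {format_formula(h.formula) for h in formula_search(420.1032, 5.0)}
    assert "C24H20FeN4" in hits


def test_search_carbon_identity():
    # 12.0000 is exact by definition; only a single carbon matches
    hits = formula_search(12.0, 5.0, {"C": (0, 2)})
    assert [format_formula(h.formula) for h in hits] == ["C"]


def test_search_never_outside_tolerance():
    for h in formula_search(439.2133, 5.0):
        assert abs(h.ppm_error) <= 5.0
    # results sorted by |ppm|
    errs = [abs(h.ppm_error) for h in formula_search(439.2133, 5.0)]
    assert errs == sorted(errs)


def test_search_rejects_bad_bounds():
    with pytest.raises(ValueError):
        formula_search(100.0, -1.0)
    with pytest.raises(ValueError):
        formula_search(100.0, 5.0, {"C": (5, 2)})
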