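"""Macrocycle symmetry, uroporphyrinogen types and isomer enumeration."""

import itertools
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from porphyrintools.formula_mass import format_formula
from porphyrintools.porphyrin_model import (
    PatternError,
    SUBSTITUENTS,
    SYMMETRY_GROUP,
    UroType,
    apply_permutation,
    canonicalize,
    derives_from,
    enumerate_isomers,
    format_pattern,
    orbit,
    parse_pattern,
    pattern_formula,
    uro_pattern,
)

pattern_strategy = st.tuples(*([st.sampled_from(sorted(SUBSTITUENTS))] * 8))


# ---------------------------------------------------------------- symmetry group

def test_group_order_and_closure():
    assert len(set(SYMMETRY_GROUP)) == 8
    perms = set(SYMMETRY_GROUP)
    for g in perms:
        for h in perms:
            composed = tuple(g[h[k]] for k in range(8))
            assert composed in perms


def test_group_maps_ring_pairs_to_ring_pairs():
    for g in SYMMETRY_GROUP:
        for i in range(4):
            a, b = g[2 * i], g[2 * i + 1]
            assert a // 2 == b // 2 and a != b


@settings(max_examples=100, derandomize=True)
@given(pattern_strategy)
def test_orbit_times_stabilizer_is_group_order(p):
    stab = sum(1 for g in SYMMETRY_GROUP if apply_permutation(p, g) == p)
    assert len(orbit(p)) * stab == 8


@settings(max_examples=100, derandomize=True)
@given(pattern_strategy)
def test_canonicalize_idempotent_and_orbit_invariant(p):
    c = canonicalize(p)
    assert canonicalize(c) == c
    assert all(canonicalize(q) == c for q in orbit(p))


def test_rotations_share_canonical_form():
    p = parse_pattern("MP|MH|MH|MH")
    rots = [apply_permutation(p, SYMMETRY_GROUP[2 * r]) for r in range(4)]
    assert len({canonicalize(q) for q in rots}) == 1


# ---------------------------------------------------------------- uro types

def test_uro_base_patterns():
    assert format_pattern(uro_pattern("I")) == "AP|AP|AP|AP"
    assert format_pattern(uro_pattern("III")) == "AP|AP|AP|PA"
    with pytest.raises(PatternError):
        uro_pattern("V")


def test_uro_types_partition_ring_orientations():
    """The 16 one-A-per-ring strings fall into exactly 4 symmetry classes,
    one per uroporphyrinogen type."""
    all_strings = {
        tuple(itertools.chain.from_iterable(("AP" if up else "PA") for up in flips))
        for flips in itertools.product([True, False], repeat=4)
    }
    classes = {canonicalize(s) for s in all_strings}
    assert len(classes) == 4
    type_canon = {canonicalize(uro_pattern(t)) for t in UroType.ALL}
    assert type_canon == classes


# ---------------------------------------------------------------- derivability

@pytest.mark.parametrize(
    "pattern,uro,expected",
    [
        ("MH|MH|MH|MH", "I", True),   # fully reduced type-I porphyrin
        ("MH|MH|MH|MH", "III", False),
        ("AP|AP|AP|AP", "I", True),   # unmodified precursor
        ("MH|MH|MP|PM", "III", True),  # deuteroporphyrin-like
        ("MH|MH|MP|PM", "I", False),
        ("MP|MH|MH|MH", "I", True),
    ],
)
def test_derives_from(pattern, uro, expected):
    assert derives_from(parse_pattern(pattern), uro) is expected


@settings(max_examples=50, derandomize=True)
@given(pattern_strategy, st.sampled_from(UroType.ALL))
def test_derivability_invariant_under_canonicalization(p, t):
    assert derives_from(p, t) == derives_from(canonicalize(p), t)


# ---------------------------------------------------------------- enumeration

def oracle_isomer_count(t, multiset):
    """Independent oracle: explicit orbit reduction of all placements."""
    letters = [s for s, n in sorted(multiset.items()) for _ in range(n)]
    placements = set(itertools.permutations(letters))
    orbits = set()
    while placements:
        p = placements.pop()
        ob = orbit(p)
        placements -= ob
        if derives_from(p, t):
            orbits.add(min(ob))
    return orbits


@pytest.mark.parametrize(
    "uro,multiset,expected_count",
    [
        ("I", {"M": 4, "P": 1, "H": 3}, 1),
        ("III", {"M": 4, "P": 1, "H": 3}, 4),
        ("I", {"M": 4, "H": 4}, 1),
        ("I", {"M": 5, "P": 1, "H": 2}, 0),  # only 4 acetate sites exist
        ("III", {"M": 4, "P": 2, "H": 2}, 6),  # computed by the oracle below
    ],
)
def test_enumerate_isomer_counts(uro, multiset, expected_count):
    got = enumerate_isomers(uro, multiset)
    assert len(got) == expected_count
    assert got == oracle_isomer_count(uro, multiset)


@pytest.mark.parametrize(
    "multiset",
    [
        {"M": 4, "H": 4},
        {"M": 4, "P": 1, "H": 3},
        {"M": 4, "P": 2, "H": 2},
        {"M": 4, "P": 2, "E": 1, "H": 1},
        {"M": 2, "V": 2, "E": 2, "H": 2},
    ],
)
def test_enumeration_agrees_with_oracle_all_types(multiset):
    for t in UroType.ALL:
        assert enumerate_isomers(t, multiset) == oracle_isomer_count(t, multiset)


def test_enumerate_output_is_canonical():
    for p in enumerate_isomers("III", {"M": 4, "P": 1, "H": 3}):
        assert canonicalize(p) == p
        assert derives_from(p, "III")


def test_enumerate_rejects_bad_multiset():
    with pytest.raises(PatternError):
        enumerate_isomers("I", {"M": 4})
    with pytest.raises(PatternError):
        enumerate_isomers("I", {"M": 8, "X": 0})


# ---------------------------------------------------------------- formulas

@pytest.mark.parametrize(
    "pattern,formula",
    [
        ("MH|MH|MH|MH", "C24H22N4"),
        ("MP|MH|MH|MH", "C27H26N4O2"),
        ("HH|HH|HH|HH", "C20H14N4"),
        ("ME|MH|MP|PM", "C32H34N4O4"),
        ("MH|MH|MP|PM", "C30H30N4O4"),
    ],
)
def test_pattern_formula(pattern, formula):
    assert format_formula(pattern_formula(parse_pattern(pattern))) == formula


def test_enumerated_isomers_share_the_multiset_formula():
    """Every enumerated isomer of a compound's multiset has that compound's formula."""
    cases = [
        ({"M": 4, "H": 4}, "C24H22N4"),
        ({"M": 4, "P": 1, "H": 3}, "C27H26N4O2"),
        ({"M": 4, "P": 2, "E": 1, "H": 1}, "C32H34N4O4"),
        ({"M": 4, "P": 2, "H": 2}, "C30H30N4O4"),
    ]
    for multiset, formula in cases:
        for t in ("I", "III"):
            for p in enumerate_isomers(t, multiset):
                assert format_formula(pattern_formula(p)) == formula


def test_parse_pattern_rejects():
    with pytest.raises(PatternError):
        parse_pattern("MP|MP|MP")
    with pytest.raises(PatternError):
        parse_pattern("XP|MP|MP|PM")
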