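"""Porphyrin β-substitution patterns, macrocycle symmetry and isomer enumeration.

An etio-type porphyrin is modelled by its 8 β-substituents, grouped as 4
ordered pyrrole-ring pairs and serialized ``"XY|XY|XY|XY"`` (rings in
clockwise order, site1 then site2 within each ring).  The substituent
alphabet is closed:

    A acetate (−CH2COOH)     P propionate (−CH2CH2COOH)
    M methyl                 V vinyl
    E ethyl                  H hydrogen

Two patterns describe the same constitutional isomer when one maps onto the
other under the macrocycle's dihedral symmetry: 4 ring rotations × an
optional flip (the macrocycle is planar and two-sided; the flip reverses the
cyclic ring order and swaps the two sites within each ring).  That group has
order 8 and is what reduces raw substituent placements to constitutional
isomers.

Biosynthetic derivability encodes the classical tetrapyrrole pathway: every
β-substituent descends from the acetate/propionate pairs of a
uroporphyrinogen precursor — acetate decarboxylates to methyl; propionate is
oxidised to vinyl, which may be reduced to ethyl or lost to H.  A pattern
"derives from" uroporphyrinogen type t when some symmetry image aligns it
with t's A/P skeleton such that A-sites hold {A, M} and P-sites hold
{P, V, E, H}.
"""

from __future__ import annotations

import itertools
from collections import Counter
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple

from .formula_mass import ElementCount

__all__ = [
    "SUBSTITUENTS",
    "SUBSTITUENT_INCREMENT",
    "PORPHINE_CORE",
    "SYMMETRY_GROUP",
    "UroType",
    "parse_pattern",
    "format_pattern",
    "uro_pattern",
    "apply_permutation",
    "canonicalize",
    "orbit",
    "derives_from",
    "enumerate_isomers",
    "pattern_formula",
]

SUBSTITUENTS = frozenset("APMVEH")

#: element increments over the porphine core, per substituent symbol
SUBSTITUENT_INCREMENT: Dict[str, Dict[str, int]] = {
    "H": {},
    "M": {"C": 1, "H": 2},
    "E": {"C": 2, "H": 4},
    "V": {"C": 2, "H": 2},
    "A": {"C": 2, "H": 2, "O": 2},
    "P": {"C": 3, "H": 4, "O": 2},
}

#: unsubstituted porphine scaffold (meso positions always H)
PORPHINE_CORE = ElementCount({"C": 20, "H": 14, "N": 4})

Pattern = Tuple[str, ...]  # length 8; sites (2i, 2i+1) form ring i


class PatternError(ValueError):
    """Raised for malformed substitution patterns."""


def parse_pattern(text: str) -> Pattern:
    """Parse ``"MP|MP|MP|PM"`` (or the bare 8-letter string) into a site tuple."""
    compact = text.replace("|", "").replace(" ", "").upper()
    if len(compact) != 8:
        raise PatternError(f"pattern must have exactly 8 sites, got {text!r}")
    bad = set(compact) - SUBSTITUENTS
    if bad:
        raise PatternError(f"unknown substituent symbols {sorted(bad)} in {text!r}")
    return tuple(compact)


def format_pattern(p: Pattern) -> str:
    return "|".join("".join(p[2 * i : 2 * i + 2]) for i in range(4))


def _build_symmetry_group() -> Tuple[Tuple[int, ...], ...]:
    # rotations by r rings: site k -> k+2r (mod 8)
    # flip: reverse cyclic order with within-ring site swap: k -> 1-k (mod 8)
    perms = []
    for r in range(4):
        rot = tuple((k + 2 * r) % 8 for k in range(8))
        perms.append(rot)
        perms.append(tuple((1 - rot[k]) % 8 for k in range(8)))
    return tuple(perms)


#: the 8 site permutations (4 rotations × optional flip); closed, order 8
SYMMETRY_GROUP: Tuple[Tuple[int, ...], ...] = _build_symmetry_group()


def apply_permutation(p: Pattern, perm: Sequence[int]) -> Pattern:
    """Image of ``p`` under a site permutation: site k of the image reads p[perm[k]]."""
    return tuple(p[perm[k]] for k in range(8))


def orbit(p: Pattern) -> FrozenSet[Pattern]:
    return frozenset(apply_permutation(p, g) for g in SYMMETRY_GROUP)


def canonicalize(p: Pattern) -> Pattern:
    """Lexicographically minimal symmetry image; idempotent."""
    return min(orbit(p))


# --------------------------------------------------------------------------
# Uroporphyrinogen types
# --------------------------------------------------------------------------

class UroType:
    """The four Fischer uroporphyrinogen types (cyclic A/P arrangements).

    Each pyrrole ring of a uroporphyrinogen carries one acetate and one
    propionate; the four distinct cyclic arrangements up to macrocycle
    symmetry are the classical types I–IV.  Type I is the fully symmetric
    APAPAPAP skeleton; type III inverts the D ring (APAPAPPA); type II
    inverts alternate rings; type IV inverts two adjacent rings.
    """

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"

    ALL = ("I", "II", "III", "IV")


_URO_PATTERNS: Dict[str, Pattern] = {
    "I": parse_pattern("AP|AP|AP|AP"),
    "II": parse_pattern("AP|PA|AP|PA"),
    "III": parse_pattern("AP|AP|AP|PA"),
    "IV": parse_pattern("AP|AP|PA|PA"),
}


def uro_pattern(t: str) -> Pattern:
    """Canonical A/P skeleton of uroporphyrinogen type ``t`` ∈ {I, II, III, IV}."""
    try:
        return _URO_PATTERNS[t]
    except KeyError:
        raise PatternError(f"unknown uroporphyrinogen type {t!r}") from None


#: allowed products at an acetate site / a propionate site of the precursor
_A_PRODUCTS = frozenset("AM")
_P_PRODUCTS = frozenset("PVEH")


def derives_from(p: Pattern, t: str) -> bool:
    """True iff ``p`` is biosynthetically derivable from uroporphyrinogen ``t``.

    Checks every symmetry alignment of ``p`` against the type's A/P skeleton;
    A-sites must hold {A, M} (decarboxylation) and P-sites {P, V, E, H}
    (oxidation / reduction / devinylation).
    """
    skeleton = uro_pattern(t)
    for g in SYMMETRY_GROUP:
        image = apply_permutation(p, g)
        if all(
            (image[k] in _A_PRODUCTS) if skeleton[k] == "A" else (image[k] in _P_PRODUCTS)
            for k in range(8)
        ):
            return True
    return False


def enumerate_isomers(t: str, multiset: Mapping[str, int]) -> Set[Pattern]:
    """All canonical patterns with the given substituent multiset derivable from ``t``.

    ``multiset`` maps substituent symbols to counts totalling 8.  Impossible
    multisets (e.g. five methyls, since only four acetate sites exist) yield
    the empty set.  Distinctness is constitutional: patterns are reduced
    under the order-8 macrocycle symmetry.
    """
    total = sum(multiset.values())
    if total != 8:
        raise PatternError(f"substituent multiset must total 8 sites, got {total}")
    bad = set(multiset) - SUBSTITUENTS
    if bad:
        raise PatternError(f"unknown substituent symbols {sorted(bad)}")
    letters = [s for s, n in sorted(multiset.items()) for _ in range(n)]
    out: Set[Pattern] = set()
    for placement in set(itertools.permutations(letters)):
        if derives_from(placement, t):
            out.add(canonicalize(placement))
    return out


def pattern_formula(p: Pattern, *, allow_precursor: bool = True) -> ElementCount:
    """Molecular formula: porphine core plus per-substituent increments."""
    if not allow_precursor and any(s in "AP" for s in p):
        raise PatternError(f"pattern {format_pattern(p)!r} contains precursor A/P sites")
    f = PORPHINE_CORE
    for s in p:
        try:
            f = f.add_delta(SUBSTITUENT_INCREMENT[s])
        except KeyError:
            raise PatternError(f"unknown substituent symbol {s!r}") from None
    return f
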