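# Methods

## The problem

Etio-type porphyrins — tetrapyrrole macrocycles with four meso (bridge) CH
positions and eight β-pyrrole positions carrying only alkyl, H or
carboxyalkyl substituents — occur in biological extracts both as free bases
and as iron(III) hemin complexes. Recognising these compound families in an
LC-HRMS run, inferring their molecular formulas, and deciding between the
biosynthetically possible substitution isomers from minimal NMR evidence
are the three computations this package automates. All stages operate on
centroided peak lists (delimited text) and presence/absence NOE tables; no
raw vendor or profile data handling is attempted.

## Exact-mass conventions

Monoisotopic masses are sums of most-abundant-isotope masses (⁵⁶Fe for
iron) from an embedded, versioned snapshot of the IUPAC/CIAAW table, so
results are bit-stable across environments. Cation m/z is the plain atomic
sum of the ion's composition with **no electron-mass subtraction**. This
matches the convention behind the reference HRMS "calcd" values the
regression suite pins (verified on all twelve: the largest deviation is
4 × 10⁻⁵ Da); an electron correction (−0.00055 Da per charge) is available
behind a flag for users who want the physically exact cation mass. Only
singly charged positive ions are supported; the three ion species handled
are `[M+H]⁺`, `[M−2H+Fe(III)]⁺` and `[M−2H+Fe(III)+ACN]⁺`.

Formula decomposition is an exhaustive depth-first enumeration over
per-element bounds (default C ≤ 40, H ≤ 60, N ≤ 8, O ≤ 8, Fe ≤ 1) with mass
pruning, filtered by ring-plus-double-bond equivalents in [0, 25]. Iron is
assigned RDBE valence 0 so that metal complexes are not excluded while
absurd compositions still are. The default match tolerance is 5 ppm —
roughly twice the observed accuracy of lock-mass-calibrated TOF data —
and is configurable everywhere it appears. The element bounds and RDBE
window are this package's own defaults, chosen to cover metallated
tetrapyrroles comfortably; they are not taken from any instrument vendor.

## Isotope patterns

Patterns are aggregated-isotopologue convolutions: each element's
multinomial distribution is built by repeated squaring and the per-element
results convolved, merging peaks closer than 0.01 Da (adequate for
unit-resolved TOF clusters; fine isotope structure is out of scope).
Abundances are normalized to the base peak for reporting; pruning never
discards more than 1% of total abundance. A brute-force isotopologue
enumeration (≤ 5 atoms) serves as the test oracle.

## Hemin pair mining

The free base and its hemin differ by a fixed composition change
(−3H +Fe on the cation), giving the offset Δ(Fe) = m(Fe) − 3·m(H) =
52.91146 Da; the ACN adduct adds Δ(ACN) = m(C₂H₃N) = 41.02655 Da. Both are
derived from the mass table at import time, never hard-coded. Pair mining
considers every peak pair at Δ(Fe) within a tolerance that combines the two
peaks' ppm errors in quadrature (symmetric error model for TOF data).
Co-elution is deliberately **not** required: free porphyrins and hemins
elute at different retention times under acidic reversed-phase conditions,
so retention time is only used (window 0.1 min, when present) to group
isotope clusters.

Pairs anchored on isotope satellites are suppressed: a peak with a more
intense peak one ¹³C spacing (1.00336 Da) below it is a satellite, and its
apparent Δ(Fe) partner is the satellite of the real hemin. Without this
filter every planted pair appears 3–4 times (once per satellite channel).
The known limitation is a genuine compound whose monoisotopic peak sits one
¹³C spacing above a more intense unrelated peak; at 4-decimal TOF accuracy
this coincidence is rare.

The Fe-isotope score is a cosine similarity between observed intensities
(aligned at the theoretical aggregated positions of the candidate hemin
formula, closest-peak matching within 0.02 Da) and theoretical abundances,
multiplied by a weight `0.3 + 0.7 × ratio_factor` where `ratio_factor`
measures agreement of the observed M−2 : M ratio with the theoretical
⁵⁴Fe/⁵⁶Fe satellite (≈ 0.064). The heavy (M+1, M+2) side of an Fe-free
organic pattern is nearly identical to the Fe-containing one, so the cosine
alone separates poorly; the M−2 channel is the discriminating feature, and
the weighting caps a cluster with no M−2 peak at 0.3. The pipeline accepts
hemin candidates at score ≥ 0.7.

The acid-demetallation differential encodes the qualitative observation
that concentrated H₂SO₄ strips Fe(III): a pair is confirmed when the hemin
(and its ACN adduct) drops ≥ 10-fold between runs while the free base
retains ≥ 50% of its intensity (guarding against global signal loss). The
10× threshold is this package's own quantitative default for a criterion
that is qualitative at source; it is configurable, as is optional
total-ion-current rescaling between runs (off by default).

## Substitution model and isomer counting

A pattern is an ordered 4-tuple of ordered site pairs over the alphabet
{A, P, M, V, E, H}, serialized `"XY|XY|XY|XY"`. Two patterns are the same
constitutional isomer iff related by the macrocycle symmetry group: 4 ring
rotations × an optional flip (reversal of cyclic order with within-ring
site swap), order 8, dihedral. The flip is included because the macrocycle
is planar and two-sided; with rotations alone the tetramethyl-monopropionate
type-III count would be 8 (mirror pairs counted separately) instead of the
correct 4, and the type-I count 2 instead of 1 — the brute-force orbit
oracle in the test suite pins both groups' counts. Canonical forms are the
lexicographic minimum over the orbit; ring labels (A–D) carry no chemical
meaning here.

Uroporphyrinogen types I–IV are the four orbits of the 16 one-A-per-ring
A/P arrangements: I = AP|AP|AP|AP, III = AP|AP|AP|PA (D-ring inversion),
II = alternating inversions, IV = two adjacent inversions. Derivability
from type t requires a symmetry alignment in which every acetate site holds
{A, M} (stepwise decarboxylation) and every propionate site holds
{P, V, E, H} (oxidation to vinyl, then reduction to ethyl or devinylation
to H) — the minimal rule set consistent with the tetrapyrrole pathway.
Meso positions are always unsubstituted.

Isomer enumeration generates all distinct placements of a substituent
multiset (≤ 8!/symmetry ≈ thousands, instantaneous), filters by
derivability, and reduces to canonical forms.

## NOE decision rule

Meso proton i lies between site 2 of ring i and site 1 of ring i+1
(cyclic); its predicted methyl contact is true iff either flanking β-site
is a methyl. The rule is purely topological — no distances, no intensities —
because the evidence it formalises is presence/absence of NOESY
cross-peaks. For four-methyl patterns the exhaustive prediction over all
enumerated isomers gives a clean signature: type I → 4/4 contacts,
types III and IV → exactly 3/4, type II → exactly 2/4. Since type-II (and
type-IV) porphyrins do not occur naturally, the classifier maps 4/4 to
TYPE_I, 3/4 to TYPE_III_OR_IV (deliberately not resolved further), and
everything else to INCONSISTENT. It refuses observations that do not have
exactly four methyls or that contain unresolved contacts, rather than
guessing. Observed meso/methyl indices are treated as unassignable labels,
so candidate filtering compares unordered contact multisets. NOEs from
propionate α-CH₂ protons to meso protons are ignored by the classifier.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
chromatography: per compound it emits the chosen ion species with full
aggregated isotope clusters (satellites scaled by theoretical abundance
from a log-uniform monoisotopic intensity — no intensities are available to
fit), jitters every m/z by a Gaussian ppm-scale error (default σ = 1 ppm),
and adds decoy peaks uniform over 300–700 Th, resampled so no decoy lands
within 20 ppm of any true peak or of any position one Δ(Fe)/Δ(ACN) offset
from a true peak — which makes false-positive counts interpretable. NOE
observations start from the topological prediction and flip contacts with
independent dropout/spurious probabilities. Everything is driven by one
integer seed; identical configuration gives identical output.

What the simulation does **not** model: chromatographic peak shapes and
co-elution structure, adduct-suppression chemistry, matrix effects,
intensity-dependent mass error, and real centroiding artifacts. Passing the
closed-loop tests therefore demonstrates correctness of the mass
arithmetic, offset mining, scoring and classification logic under the
stated noise model — not robustness to every artifact of real LC-MS data.

The four planted reference compounds are the free bases C24H22N4 and
C27H26N4O2 (type-I derived; the first fully reduced, the second with one
propionate) and C32H34N4O4, C30H30N4O4 (type-III derived). The type-III
patterns used are `ME|MH|MP|PM` and `MH|MH|MP|PM`; for the
ethyl-bearing compound the published evidence fixes the multiset
{4M, 2P, 1E, 1H} and the type but not which propionate-derived site carries
the ethyl, so the fixture uses one representative derivable pattern.

## Problem sizes and determinism

The default test suite and the acceptance script simulate runs of ~113
peaks (4 compounds × 3 ions × isotope clusters + 50 decoys) and enumerate
isomers over ≤ 40 320 placements; the whole suite runs in well under a
minute. All randomness flows through `numpy.random.default_rng` seeded from
a single integer; reports contain no timestamps and serialize
deterministically.

## Known limitations

- Charge states > 1, negative mode, in-source fragmentation and fine
  isotope structure are out of scope.
- The formula searcher is exhaustive, not knapsack-optimised; with the
  default bounds it is instantaneous, but very wide bounds scale
  combinatorially.
- The NOE rule presumes all four meso protons and all methyl singlets are
  resolved; overlapping signals must be marked unresolved, which the
  classifier refuses.
- Pattern serialization fixes an arbitrary clockwise ring order; canonical
  forms, not raw strings, are the stable identifiers.
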