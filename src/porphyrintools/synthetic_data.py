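"""Seeded synthetic LC-MS peak lists and NOE tables with ground-truth manifests.

The generator emulates what a positive-mode LC-HRMS run of a sponge crude
extract looks like to the pairing pipeline: for each porphyrin it emits the
protonated free-base ion and, when the hemin is present, the ferric ion and
its acetonitrile adduct, each with its aggregated isotope cluster, all m/z
values jittered by a Gaussian ppm-scale error; decoy peaks are drawn
uniformly in m/z, rejected near any true peak or any position one valid
offset (Δ_Fe, Δ_ACN) away from a true peak so that false-positive counts
are interpretable.  Intensities are log-uniform (the study reports none);
isotope satellites scale from the monoisotopic peak by theoretical
abundance.  NOE observations start from the topological contact prediction
and flip contacts with independent dropout/spurious probabilities.

Everything is driven by an integer seed; identical configuration and seed
give identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .formula_mass import (
    ElementCount,
    IonSpec,
    STANDARD_IONS,
    ion_mz,
    isotope_pattern,
    parse_formula,
)
from .hemin_pairing import DELTA_ACN, DELTA_FE, Peak
from .noe_inference import NOEObservation, predict_meso_contacts
from .porphyrin_model import Pattern, parse_pattern

__all__ = [
    "SimulationConfig",
    "CompoundSpec",
    "fixture_compounds",
    "simulate_peaklist",
    "simulate_noe_table",
]


@dataclass(frozen=True)
class CompoundSpec:
    """One compound to plant: neutral formula, which ions to emit, base intensity."""

    name: str
    neutral: ElementCount
    ions: Tuple[IonSpec, ...] = STANDARD_IONS
    base_intensity: float = 1000.0


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic LC-MS/NOE generator.

    ppm_sigma is the Gaussian m/z error scale (1 ppm default, matching the
    sub-2.5 ppm accuracy of the lock-mass-calibrated TOF data the pipeline
    targets); decoys default to 50 over the 300–700 Th porphyrin window.
    """

    compounds: Tuple[CompoundSpec, ...] = ()
    ppm_sigma: float = 1.0
    n_decoys: int = 50
    decoy_mz_range: Tuple[float, float] = (300.0, 700.0)
    intensity_range: Tuple[float, float] = (10.0, 10000.0)
    seed: int = 0
    noe_dropout: float = 0.0
    noe_spurious: float = 0.0
    isotope_prune: float = 5e-3
    decoy_exclusion_ppm: float = 20.0

    def __post_init__(self) -> None:
        if self.ppm_sigma < 0:
            raise ValueError("ppm_sigma must be >= 0")
        for p in (self.noe_dropout, self.noe_spurious):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be >= 0")


# --------------------------------------------------------------------------
# Reference fixture compounds (four free-base/hemin pairs)
# --------------------------------------------------------------------------

_FIXTURES: Tuple[Tuple[str, str, Optional[str]], ...] = (
    # (name, neutral free-base formula, substitution pattern or None)
    ("isabellin A", "C24H22N4", "MH|MH|MH|MH"),          # type I, fully reduced
    ("isabellin B", "C27H26N4O2", "MP|MH|MH|MH"),        # type I, one propionate
    ("corallistin D", "C32H34N4O4", "ME|MH|MP|PM"),      # type III
    ("deuteroporphyrin IX", "C30H30N4O4", "MH|MH|MP|PM"),  # type III
)


def fixture_compounds() -> List[Tuple[str, ElementCount, Optional[Pattern]]]:
    """The four free-porphyrin/hemin reference pairs.

    Returns (name, neutral free-base formula, β-substitution pattern); the
    first two are type-I derived, the last two type-III derived.
    """
    return [
        (name, parse_formula(formula), parse_pattern(pat) if pat else None)
        for name, formula, pat in _FIXTURES
    ]


def fixture_config(
    seed: int = 0,
    *,
    ppm_sigma: float = 1.0,
    n_decoys: int = 50,
    **overrides,
) -> SimulationConfig:
    """A SimulationConfig planting all four fixture compounds with all ions."""
    compounds = tuple(
        CompoundSpec(name=name, neutral=neutral)
        for name, neutral, _ in fixture_compounds()
    )
    return SimulationConfig(
        compounds=compounds,
        ppm_sigma=ppm_sigma,
        n_decoys=n_decoys,
        seed=seed,
        **overrides,
    )


# --------------------------------------------------------------------------
# Peak-list simulation
# --------------------------------------------------------------------------

def _jitter(mz: float, ppm_sigma: float, rng: np.random.Generator) -> float:
    return mz * (1.0 + rng.normal(0.0, ppm_sigma) * 1e-6) if ppm_sigma > 0 else mz


def simulate_peaklist(cfg: SimulationConfig) -> Tuple[List[Peak], Dict]:
    """Generate a centroided peak list plus a ground-truth manifest.

    For every compound and ion species the full aggregated isotope cluster is
    emitted (satellites scaled from a log-uniform monoisotopic intensity);
    decoy peaks avoid the ``decoy_exclusion_ppm`` window around every true
    peak and around every position one Δ_Fe or Δ_ACN offset away from a true
    peak (bounded resampling; exhaustion raises).  The manifest records the
    theoretical and emitted m/z of every planted ion, sufficient to score
    precision/recall of downstream pair mining.
    """
    rng = np.random.default_rng(cfg.seed)
    peaks: List[Peak] = []
    manifest: Dict = {"seed": cfg.seed, "ppm_sigma": cfg.ppm_sigma, "compounds": [], "decoys": []}

    true_mzs: List[float] = []
    for comp in cfg.compounds:
        entry = {"name": comp.name, "neutral": str(comp.neutral), "ions": []}
        for ion in comp.ions:
            theo_mz = ion_mz(comp.neutral, ion)
            # log-uniform spread of a factor 100 around the compound's base level
            base_intensity = float(
                comp.base_intensity * np.exp(rng.uniform(np.log(0.1), np.log(10.0)))
            )
            pattern = isotope_pattern(ion.apply(comp.neutral), cfg.isotope_prune)
            emitted = []
            for (mass, rel) in pattern.peaks:
                # satellites sit at their aggregated-mass offset from the base peak
                mz_theo = theo_mz + (mass - pattern.base_peak_mass)
                mz_obs = _jitter(mz_theo, cfg.ppm_sigma, rng)
                peaks.append(Peak(mz=mz_obs, intensity=base_intensity * rel))
                emitted.append({"theoretical_mz": mz_theo, "observed_mz": mz_obs, "rel_abundance": rel})
                true_mzs.append(mz_theo)
            entry["ions"].append(
                {"ion": ion.name, "monoisotopic_mz": theo_mz, "peaks": emitted}
            )
        manifest["compounds"].append(entry)

    # decoys: uniform, rejected near true peaks and near valid-offset images
    exclusion: List[float] = list(true_mzs)
    for m in true_mzs:
        exclusion += [m + DELTA_FE, m - DELTA_FE, m + DELTA_ACN, m - DELTA_ACN]
    exclusion_arr = np.array(sorted(exclusion)) if exclusion else np.empty(0)
    lo_mz, hi_mz = cfg.decoy_mz_range
    width_ppm = max(cfg.decoy_exclusion_ppm, 3.0 * cfg.ppm_sigma)
    ilo, ihi = cfg.intensity_range
    for k in range(cfg.n_decoys):
        for _ in range(1000):
            mz = float(rng.uniform(lo_mz, hi_mz))
            if exclusion_arr.size:
                idx = np.searchsorted(exclusion_arr, mz)
                near = [
                    exclusion_arr[i]
                    for i in (idx - 1, idx)
                    if 0 <= i < exclusion_arr.size
                ]
                if any(abs(mz - m) <= m * width_ppm * 1e-6 for m in near):
                    continue
            break
        else:
            raise RuntimeError("decoy resampling exhausted; widen decoy_mz_range")
        intensity = float(np.exp(rng.uniform(np.log(ilo), np.log(ihi))))
        peaks.append(Peak(mz=mz, intensity=intensity))
        manifest["decoys"].append({"mz": mz, "intensity": intensity})

    peaks.sort(key=lambda p: p.mz)
    return peaks, manifest


def simulate_acid_treated(
    peaks: Sequence[Peak],
    manifest: Mapping,
    *,
    seed: int = 0,
    residual: float = 0.0,
) -> List[Peak]:
    """Peak list after simulated H2SO4 demetallation.

    Ferric-ion and ACN-adduct peaks drop to ``residual`` of their intensity
    (0 removes them); free-base and decoy peaks are unchanged.
    """
    hemin_mzs: List[float] = []
    for comp in manifest["compounds"]:
        for ion in comp["ions"]:
            if "Fe" in ion["ion"]:
                hemin_mzs += [pk["observed_mz"] for pk in ion["peaks"]]
    out: List[Peak] = []
    for p in peaks:
        if any(abs(p.mz - m) < 1e-9 for m in hemin_mzs):
            if residual > 0:
                out.append(Peak(p.mz, p.intensity * residual, p.rt))
        else:
            out.append(p)
    return out


# --------------------------------------------------------------------------
# NOE-table simulation
# --------------------------------------------------------------------------

def simulate_noe_table(p: Pattern, cfg: SimulationConfig) -> NOEObservation:
    """Noisy NOE observation for a fully derivatized pattern.

    Starts from the topological contact prediction, then flips true→false
    with probability ``noe_dropout`` (missed correlation) and false→true with
    ``noe_spurious`` (artifact), independently per meso proton; seeded.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = predict_meso_contacts(p)
    observed = []
    for c in truth:
        u = rng.uniform()
        if c:
            observed.append(u >= cfg.noe_dropout)
        else:
            observed.append(u < cfg.noe_spurious)
    n_methyls = sum(1 for s in p if s == "M")
    return NOEObservation(n_methyls=n_methyls, meso_contacts=tuple(observed))


def write_peaklist(path, peaks: Sequence[Peak]) -> None:
    """Write a peak list as tab-separated text (mz, intensity[, rt])."""
    has_rt = any(p.rt is not None for p in peaks)
    with open(path, "w") as fh:
        fh.write("mz\tintensity" + ("\trt" if has_rt else "") + "\n")
        for p in peaks:
            row = f"{p.mz:.6f}\t{p.intensity:.4f}"
            if has_rt:
                row += f"\t{p.rt if p.rt is not None else ''}"
            fh.write(row + "\n")


def write_manifest(path, manifest: Mapping) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
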