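"""Readers/writers and the end-to-end dereplicate-and-assign pipeline.

Peak lists are delimited text with a header (``mz``, ``intensity``
[, ``rt``]); NOE tables are delimited text with columns ``meso_id``,
``partner_type`` (methyl/other) and ``observed`` (0/1, or ``na`` for an
unresolved contact).  The pipeline wires the stages together:

    peaks → hemin pair mining → formula candidates → substituent multisets
          → isomer enumeration per uroporphyrinogen type → NOE verdict
          → report (JSON / TSV)

Reports are deterministic given identical inputs and configuration: no
timestamps, stable ordering, fixed float formatting.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .formula_mass import ElementCount, format_formula, formula_search
from .hemin_pairing import (
    PairHit,
    Peak,
    acid_differential,
    extract_cluster,
    fe_isotope_score,
    find_pairs,
)
from .noe_inference import NOEObservation, Verdict, classify, consistent_isomers
from .porphyrin_model import (
    PORPHINE_CORE,
    SUBSTITUENT_INCREMENT,
    UroType,
    enumerate_isomers,
    format_pattern,
)

__all__ = [
    "InputError",
    "ConfigError",
    "PipelineConfig",
    "read_peaklist",
    "read_noe_table",
    "substituent_multisets",
    "run_pipeline",
    "write_report_json",
    "write_report_tsv",
]


class InputError(ValueError):
    """Unreadable or malformed input data (CLI exit code 2)."""


class ConfigError(ValueError):
    """Invalid or conflicting configuration (CLI exit code 3)."""


@dataclass(frozen=True)
class PipelineConfig:
    """Tolerances and thresholds of the end-to-end pipeline."""

    tol_ppm: float = 5.0
    require_acn: bool = False
    fold_drop: float = 10.0
    fe_score_threshold: float = 0.7
    rt_window: Optional[float] = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0:
            raise ConfigError("tol_ppm must be positive")
        if self.fold_drop <= 1:
            raise ConfigError("fold_drop must exceed 1")
        if not 0.0 <= self.fe_score_threshold <= 1.0:
            raise ConfigError("fe_score_threshold must lie in [0, 1]")

    @classmethod
    def from_toml(cls, path, **overrides) -> "PipelineConfig":
        """Load a flat TOML config file; keyword overrides take precedence."""
        try:
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


# --------------------------------------------------------------------------
# Readers
# --------------------------------------------------------------------------

def read_peaklist(path) -> List[Peak]:
    """Read a delimited peak list (header: mz, intensity[, rt])."""
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:
        raise InputError(f"cannot read peak list {path}: {exc}") from exc
    cols = {c.strip().lower(): c for c in df.columns}
    if "mz" not in cols or "intensity" not in cols:
        raise InputError(
            f"peak list {path} needs 'mz' and 'intensity' columns, got {list(df.columns)}"
        )
    peaks = []
    for idx, row in df.iterrows():
        try:
            rt = float(row[cols["rt"]]) if "rt" in cols and pd.notna(row[cols["rt"]]) else None
            peaks.append(
                Peak(float(row[cols["mz"]]), float(row[cols["intensity"]]), rt)
            )
        except (TypeError, ValueError) as exc:
            raise InputError(f"{path}, line {idx + 2}: {exc}") from exc
    return peaks


_TRUTHY = {"1", "true", "yes"}
_FALSY = {"0", "false", "no"}
_UNRESOLVED = {"na", "nan", "unresolved", "?", ""}


def read_noe_table(path, n_methyls: Optional[int] = None) -> NOEObservation:
    """Read a delimited NOE table (meso_id, partner_type, observed).

    A meso proton's contact is True when any of its rows with
    ``partner_type == methyl`` is observed; ``na``/``unresolved`` entries make
    the contact unresolved (None) unless another methyl row resolves it.
    ``n_methyls`` may come from a ``# n_methyls: 4`` comment line or the
    argument (argument wins); defaults to 4.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise InputError(f"cannot read NOE table {path}: {exc}") from exc
    comment_n = None
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("#") and "n_methyls" in line:
            try:
                comment_n = int(line.split(":", 1)[1].strip())
            except (IndexError, ValueError) as exc:
                raise InputError(f"{path}: malformed n_methyls comment {line!r}") from exc
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:
        raise InputError(f"cannot parse NOE table {path}: {exc}") from exc
    needed = {"meso_id", "partner_type", "observed"}
    have = {c.strip().lower() for c in df.columns}
    if not needed <= have:
        raise InputError(f"NOE table {path} needs columns {sorted(needed)}")
    df.columns = [c.strip().lower() for c in df.columns]

    contacts: Dict[int, Optional[bool]] = {}
    for idx, row in df.iterrows():
        try:
            meso = int(row["meso_id"])
        except (TypeError, ValueError) as exc:
            raise InputError(f"{path}, line {idx + 2}: bad meso_id {row['meso_id']!r}") from exc
        if str(row["partner_type"]).strip().lower() != "methyl":
            continue  # the classifier only uses meso↔methyl contacts
        raw = str(row["observed"]).strip().lower()
        if raw in _TRUTHY:
            val: Optional[bool] = True
        elif raw in _FALSY:
            val = False
        elif raw in _UNRESOLVED:
            val = None
        else:
            raise InputError(f"{path}, line {idx + 2}: bad observed value {row['observed']!r}")
        prev = contacts.get(meso)
        if val is True or prev is True:
            contacts[meso] = True
        elif val is False and prev is None:
            contacts[meso] = False
        elif meso not in contacts:
            contacts[meso] = val
    if len(contacts) != 4:
        raise InputError(
            f"NOE table {path} must cover exactly 4 meso protons, got {sorted(contacts)}"
        )
    ordered = tuple(contacts[k] for k in sorted(contacts))
    n = n_methyls if n_methyls is not None else (comment_n if comment_n is not None else 4)
    return NOEObservation(n_methyls=n, meso_contacts=ordered)


# --------------------------------------------------------------------------
# Formula → substituent multisets
# --------------------------------------------------------------------------

def substituent_multisets(neutral: ElementCount) -> List[Dict[str, int]]:
    """All 8-substituent multisets whose formula equals ``neutral``.

    Decomposes ``neutral − porphine core`` into 8 substituents drawn from the
    closed alphabet; returns each viable multiset (sorted canonically).  An
    empty list means the formula is not an etio-type porphyrin composition.
    """
    symbols = sorted(SUBSTITUENT_INCREMENT)
    target = {
        el: neutral[el] - PORPHINE_CORE[el] for el in set(neutral.counts) | {"C", "H", "N", "O"}
    }
    if any(v < 0 for v in target.values()) or target.get("N", 0) != 0:
        return []
    out = []
    for combo in itertools.combinations_with_replacement(symbols, 8):
        totals: Dict[str, int] = {}
        for s in combo:
            for el, n in SUBSTITUENT_INCREMENT[s].items():
                totals[el] = totals.get(el, 0) + n
        if all(totals.get(el, 0) == v for el, v in target.items() if el != "N"):
            counts: Dict[str, int] = {}
            for s in combo:
                counts[s] = counts.get(s, 0) + 1
            out.append(counts)
    return out


# --------------------------------------------------------------------------
# End-to-end pipeline
# --------------------------------------------------------------------------

def run_pipeline(
    peaks: Sequence[Peak],
    noe_tables: Mapping[str, NOEObservation] | None = None,
    config: PipelineConfig | None = None,
    *,
    acid_treated: Optional[Sequence[Peak]] = None,
) -> Dict:
    """Dereplicate a peak list and assign porphyrin types.

    Mines (free, hemin[, ACN]) groups, searches formulas for the free-base
    ion, scores each hemin's Fe isotope signature, enumerates the candidate
    constitutional isomers per uroporphyrinogen type for every viable
    substituent multiset, and — when an NOE observation is supplied for a
    compound entry (keyed by free-ion m/z printed to 4 dp, or "all") —
    applies the NOE verdict and filters the candidates.

    Returns the report as a plain dict (see write_report_json/tsv).
    """
    config = config or PipelineConfig()
    noe_tables = noe_tables or {}
    hits = find_pairs(
        list(peaks),
        tol_ppm=config.tol_ppm,
        require_acn=config.require_acn,
        rt_window=config.rt_window,
    )
    free_bounds = {"C": (0, 40), "H": (0, 60), "N": (0, 8), "O": (0, 8)}
    for hit in hits:
        # the free-base ion cannot contain the metal
        hit.formula_candidates = formula_search(
            hit.free_peak.mz, config.tol_ppm, free_bounds
        )
        hemin_cands = [
            h for h in formula_search(hit.hemin_peak.mz, config.tol_ppm) if h.formula["Fe"]
        ]
        if hemin_cands:
            cluster = extract_cluster(peaks, hit.hemin_peak.mz)
            hit.fe_isotope_score = fe_isotope_score(cluster, hemin_cands[0].formula)
    if acid_treated is not None:
        hits = acid_differential(
            list(peaks), list(acid_treated), hits, config.fold_drop, config.tol_ppm
        )

    entries = []
    for hit in hits:
        if (
            hit.fe_isotope_score is not None
            and hit.fe_isotope_score < config.fe_score_threshold
        ):
            continue
        entry = hit.to_dict()
        entry["isomers"] = []
        free_formulas = [
            h.formula for h in hit.formula_candidates if not h.formula["Fe"]
        ]
        obs = noe_tables.get(f"{hit.free_peak.mz:.4f}") or noe_tables.get("all")
        for cation in free_formulas:
            neutral = cation.add_delta({"H": -1})  # strip the proton
            for multiset in substituent_multisets(neutral):
                per_type = {
                    t: sorted(
                        format_pattern(p) for p in enumerate_isomers(t, multiset)
                    )
                    for t in UroType.ALL
                }
                iso_entry = {
                    "neutral_formula": format_formula(neutral),
                    "multiset": {k: v for k, v in sorted(multiset.items())},
                    "isomers_per_type": {t: len(v) for t, v in per_type.items()},
                    "patterns_per_type": per_type,
                }
                if obs is not None and multiset.get("M", 0) == 4 and obs.n_methyls == 4:
                    result = classify(obs)
                    candidates = {
                        p
                        for t in ("I", "III")
                        for p in enumerate_isomers(t, multiset)
                    }
                    surviving = consistent_isomers(obs, candidates)
                    iso_entry["noe_verdict"] = result.verdict
                    iso_entry["noe_consistent_isomers"] = sorted(
                        format_pattern(p) for p in surviving
                    )
                entry["isomers"].append(iso_entry)
        entries.append(entry)

    return {
        "provenance": {
            "tool": "porphyrintools",
            "version": __version__,
            "config": dataclasses.asdict(config),
        },
        "n_input_peaks": len(peaks),
        "pairs": entries,
    }


def write_report_json(report: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=False)
        fh.write("\n")


def write_report_tsv(report: Mapping, path) -> None:
    """Tabular pair summary mirroring a porphyrin–hemin correlation table."""
    rows = []
    for pair in report["pairs"]:
        best_free = pair["formula_candidates"][0]["formula"] if pair["formula_candidates"] else ""
        verdicts = {
            iso.get("noe_verdict")
            for iso in pair["isomers"]
            if iso.get("noe_verdict")
        }
        rows.append(
            {
                "free_mz": f"{pair['free_mz']:.4f}",
                "hemin_mz": f"{pair['hemin_mz']:.4f}",
                "acn_mz": f"{pair['acn_mz']:.4f}" if pair["acn_mz"] else "",
                "cation_formula": best_free,
                "pair_ppm_err": f"{pair['ppm_err_pair']:.2f}",
                "fe_isotope_score": (
                    f"{pair['fe_isotope_score']:.3f}"
                    if pair["fe_isotope_score"] is not None
                    else ""
                ),
                "confirmed_by_acid": (
                    "" if pair["confirmed_by_acid"] is None else str(pair["confirmed_by_acid"])
                ),
                "noe_verdict": verdicts.pop() if len(verdicts) == 1 else "",
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "free_mz",
            "hemin_mz",
            "acn_mz",
            "cation_formula",
            "pair_ppm_err",
            "fe_isotope_score",
            "confirmed_by_acid",
            "noe_verdict",
        ],
    ).to_csv(path, sep="\t", index=False)
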