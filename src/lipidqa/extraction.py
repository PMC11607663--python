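"""Database-driven targeted feature extraction from MS1 runs.

Given a curated database row (name, formula, monoisotopic mass, RT, adduct
selection) and a centroided MS1 feature table, the extractor locates the
expected adduct ions within a ppm tolerance and an RT window, scores the
observed isotopologue pattern against the formula's prediction, integrates
areas, and rolls per-sample results into an abundance matrix that is then
blank-subtracted and normalized to the total useful signal (TUS).

File dialects are plain CSV: the database schema is
``name,subclass,formula,mass,rt,adducts`` (``adducts`` a ``;``-joined list
of registry labels), and feature tables are ``mz,rt,area``.  Profile-mode
mzML runs can be loaded through :func:`load_mzml` (pyteomics) and centroided
scan-by-scan into the same feature-table form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .adducts import DEFAULT_REGISTRY, AdductDef, ConsensusSquantForm, adduct_mz
from .chem import ElementalFormula, monoisotopic_mass

__all__ = [
    "DatabaseEntry",
    "MS1Run",
    "load_database",
    "write_database",
    "load_feature_table",
    "load_mzml",
    "isotope_pattern",
    "AdductMatch",
    "ExtractionRow",
    "find_by_formula",
    "extract_batch",
    "blank_subtract",
    "tus_normalize",
    "coverage_report",
]

#: tolerance for the database formula/mass cross-check (Da)
MASS_XCHECK_TOL = 1e-4

#: neutron-count mass step used to locate isotopologue peaks (13C − 12C)
ISOTOPE_SPACING = 1.0033548


@dataclass(frozen=True)
class DatabaseEntry:
    """One targeted-extraction template row."""

    name: str
    subclass: str
    formula: ElementalFormula
    mass: float
    rt: float
    adducts: Tuple[str, ...]

    def mass_consistent(self, tol: float = MASS_XCHECK_TOL) -> bool:
        """Whether the stated mass agrees with the formula within ``tol`` Da."""
        return abs(monoisotopic_mass(self.formula) - self.mass) <= tol


@dataclass
class MS1Run:
    """A centroided MS1 run as a feature table (mz, rt, area)."""

    sample_id: str
    polarity: str  # "+" | "-"
    features: pd.DataFrame
    run_type: str = "sample"  # "sample" | "blank"

    def __post_init__(self):
        required = {"mz", "rt", "area"}
        if not required.issubset(self.features.columns):
            raise ValueError(f"feature table needs columns {sorted(required)}")
        if (self.features["area"] < 0).any():
            raise ValueError("feature areas must be >= 0")


# --------------------------------------------------------------------------
# IO
# --------------------------------------------------------------------------

_DB_COLUMNS = ["name", "subclass", "formula", "mass", "rt", "adducts"]


def load_database(path, registry: Sequence[AdductDef] = DEFAULT_REGISTRY) -> List[DatabaseEntry]:
    """Read and schema-validate a database CSV.

    The monoisotopic mass is recomputed from the formula and cross-checked
    against the stated value; a mismatch names the offending row.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"database {path} is empty")
    missing = set(_DB_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"database {path} missing columns {sorted(missing)}")
    known = {a.label for a in registry}
    entries = []
    for _, row in df.iterrows():
        adducts = tuple(str(row["adducts"]).split(";")) if row["adducts"] else ()
        unknown = set(adducts) - known
        if unknown:
            raise ValueError(f"entry {row['name']!r}: unknown adduct labels {sorted(unknown)}")
        entry = DatabaseEntry(
            name=row["name"],
            subclass=row["subclass"],
            formula=ElementalFormula.parse(row["formula"]),
            mass=float(row["mass"]),
            rt=float(row["rt"]),
            adducts=adducts,
        )
        if not entry.mass_consistent():
            raise ValueError(
                f"entry {entry.name!r}: stated mass {entry.mass:.5f} differs from "
                f"formula mass {monoisotopic_mass(entry.formula):.5f} "
                f"by more than {MASS_XCHECK_TOL} Da"
            )
        entries.append(entry)
    return entries


def write_database(entries: Sequence[DatabaseEntry], path) -> None:
    pd.DataFrame(
        {
            "name": [e.name for e in entries],
            "subclass": [e.subclass for e in entries],
            "formula": [e.formula.hill() for e in entries],
            "mass": [round(e.mass, 5) for e in entries],
            "rt": [round(e.rt, 4) for e in entries],
            "adducts": [";".join(e.adducts) for e in entries],
        }
    ).to_csv(path, index=False)


def load_feature_table(path, sample_id: str, polarity: str, run_type: str = "sample") -> MS1Run:
    return MS1Run(sample_id, polarity, pd.read_csv(path), run_type)


def load_mzml(path, sample_id: str, polarity: str, run_type: str = "sample") -> MS1Run:
    """Read an mzML peak map and flatten it into a feature table.

    Each centroid becomes one feature row with its scan time as RT; the
    extractor's RT-window logic then integrates the extracted-ion trace by
    summing matched centroids across scans.
    """
    from pyteomics import mzml as _mzml

    rows = []
    with _mzml.read(str(path)) as reader:
        for spec in reader:
            if spec.get("ms level") != 1:
                continue
            rt = spec["scanList"]["scan"][0]["scan start time"]
            for mz, inten in zip(spec["m/z array"], spec["intensity array"]):
                rows.append((float(mz), float(rt), float(inten)))
    return MS1Run(sample_id, polarity, pd.DataFrame(rows, columns=["mz", "rt", "area"]), run_type)


# --------------------------------------------------------------------------
# Isotope pattern prediction
# --------------------------------------------------------------------------

#: per-element isotopologue abundance ladders at nominal-mass spacing,
#: normalized so index 0 is the monoisotopic species
_ISOTOPE_LADDERS: Mapping[str, Tuple[float, ...]] = {
    "H": (0.999885, 0.000115),
    "C": (0.9893, 0.0107),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "Na": (1.0,),
    "P": (1.0,),
    "S": (0.9499, 0.0075, 0.0425),
    "K": (0.932581, 0.000117, 0.067302),
}


def isotope_pattern(formula: ElementalFormula, k: int = 2) -> np.ndarray:
    """Aggregated nominal-mass isotopologue abundances M..M+k, M = 1.

    The per-element single-atom ladders are convolved ``count`` times and
    across elements, truncating beyond M+k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    dist = np.zeros(k + 1)
    dist[0] = 1.0
    for el, count in formula.counts.items():
        if el not in _ISOTOPE_LADDERS:
            raise ValueError(f"no isotope data for element {el!r}")
        ladder = np.array(_ISOTOPE_LADDERS[el])
        for _ in range(count):
            dist = np.convolve(dist, ladder)[: k + 1]
    if len(dist) < k + 1:
        dist = np.pad(dist, (0, k + 1 - len(dist)))
    return dist / dist[0]


# --------------------------------------------------------------------------
# Find-by-formula
# --------------------------------------------------------------------------


@dataclass
class AdductMatch:
    label: str
    theoretical_mz: float
    observed_mz: float
    rt: float
    area: float
    ppm: float
    isotope_score: Optional[float]  # None when no isotopologue peaks to judge


@dataclass
class ExtractionRow:
    entry: DatabaseEntry
    sample_id: str
    matches: List[AdductMatch]
    detected: bool
    quantifier_area: float
    quantifier_label: Optional[str]


def _isotope_score(
    features: pd.DataFrame,
    mono: AdductMatch,
    predicted: np.ndarray,
    z: int,
    ppm_tol: float,
    rt_tol: float,
) -> Optional[float]:
    """Agreement between observed and predicted isotopologue ratios.

    Score = 1 − max over M+1..M+k of the relative deviation of the observed
    ratio from the predicted one (an absolute floor of 0.05 keeps tiny
    predicted ratios from dominating).  Returns None when no isotopologue
    peak is found at all — absent isotope information is not treated as
    evidence against the match.
    """
    obs = [1.0]
    found_any = False
    for i in range(1, len(predicted)):
        target = mono.observed_mz + i * ISOTOPE_SPACING / abs(z)
        win = features[
            (np.abs(features["mz"] - target) / target * 1e6 <= ppm_tol)
            & (np.abs(features["rt"] - mono.rt) <= rt_tol)
        ]
        if win.empty:
            obs.append(0.0)
        else:
            found_any = True
            obs.append(float(win["area"].max()) / mono.area)
    if not found_any:
        return None
    devs = [
        abs(obs[i] - predicted[i]) / max(predicted[i], 0.05)
        for i in range(1, len(predicted))
    ]
    return max(0.0, 1.0 - max(devs))


def find_by_formula(
    run: MS1Run,
    entry: DatabaseEntry,
    ppm_tol: float = 10.0,
    rt_window: float = 0.2,
    registry: Sequence[AdductDef] = DEFAULT_REGISTRY,
    isotope_k: int = 2,
    isotope_threshold: float = 0.9,
    squant: Optional[ConsensusSquantForm] = None,
) -> ExtractionRow:
    """Locate one database entry's adduct ions in a run.

    For each selected adduct of the run's polarity the most intense feature
    within ``ppm_tol`` of the theoretical m/z and ``rt_window`` of the
    database RT is matched, then screened by isotopologue-pattern agreement.
    The quantifier is the tier-1 adduct of the subclass hierarchy when
    supplied (and matched), otherwise the most intense surviving match.
    """
    by_label = {a.label: a for a in registry}
    selected = [
        by_label[lab]
        for lab in entry.adducts
        if lab in by_label and by_label[lab].polarity == run.polarity
    ]
    feats = run.features
    predicted = isotope_pattern(entry.formula, isotope_k)
    matches: List[AdductMatch] = []
    for add in selected:
        theo = adduct_mz(entry.mass, add)
        win = feats[
            (np.abs(feats["mz"] - theo) / theo * 1e6 <= ppm_tol)
            & (np.abs(feats["rt"] - entry.rt) <= rt_window)
        ]
        if win.empty:
            continue
        best = win.loc[win["area"].idxmax()]
        m = AdductMatch(
            label=add.label,
            theoretical_mz=theo,
            observed_mz=float(best["mz"]),
            rt=float(best["rt"]),
            area=float(best["area"]),
            ppm=(float(best["mz"]) - theo) / theo * 1e6,
            isotope_score=None,
        )
        m.isotope_score = _isotope_score(
            feats, m, predicted, add.z, ppm_tol, rt_window
        )
        if m.isotope_score is None or m.isotope_score >= isotope_threshold:
            matches.append(m)

    detected = bool(matches)
    quant_label, quant_area = None, 0.0
    if matches:
        tier1 = None
        if squant is not None and squant.tiers:
            for m in matches:
                if m.label in squant.tiers[0]:
                    tier1 = m
                    break
        chosen = tier1 or max(matches, key=lambda m: m.area)
        quant_label, quant_area = chosen.label, chosen.area
    return ExtractionRow(entry, run.sample_id, matches, detected, quant_area, quant_label)


def extract_batch(
    runs: Sequence[MS1Run],
    db: Sequence[DatabaseEntry],
    squants: Optional[Mapping[Tuple[str, str], ConsensusSquantForm]] = None,
    **kwargs,
) -> Tuple[pd.DataFrame, List[ExtractionRow]]:
    """Run find-by-formula for every (entry, sample) pair.

    Runs of both polarities belonging to one ``sample_id`` are merged: an
    entry is quantified from whichever polarity matched, preferring the
    larger quantifier area.  Returns the entries × samples area matrix and
    the per-row extraction log.
    """
    if not runs:
        raise ValueError("no runs supplied")
    sample_ids = sorted({r.sample_id for r in runs if r.run_type == "sample"})
    matrix = pd.DataFrame(0.0, index=[e.name for e in db], columns=sample_ids)
    log: List[ExtractionRow] = []
    for run in runs:
        if run.run_type != "sample":
            continue
        for entry in db:
            squant = None
            if squants is not None:
                squant = squants.get((entry.subclass, run.polarity))
            row = find_by_formula(run, entry, squant=squant, **kwargs)
            log.append(row)
            if row.detected and row.quantifier_area > matrix.at[entry.name, run.sample_id]:
                matrix.at[entry.name, run.sample_id] = row.quantifier_area
    return matrix, log


# --------------------------------------------------------------------------
# Post-processing
# --------------------------------------------------------------------------


def blank_subtract(
    matrix: pd.DataFrame,
    blank_matrix: pd.DataFrame,
    ratio_threshold: float = 3.0,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Subtract the entry-wise mean blank area, flooring at zero.

    Entries whose sample-mean to blank-mean ratio falls below
    ``ratio_threshold`` are flagged as background.  Returns
    ``(subtracted_matrix, background_flags)``.
    """
    if blank_matrix.shape[1] < 1:
        raise ValueError("need at least one blank run")
    blank_mean = blank_matrix.reindex(matrix.index).fillna(0.0).mean(axis=1)
    out = matrix.sub(blank_mean, axis=0).clip(lower=0.0)
    sample_mean = matrix.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = sample_mean / blank_mean
    background = (blank_mean > 0) & (ratio < ratio_threshold)
    return out, background


def tus_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Normalize each sample column to its total useful signal (sum = 1)."""
    sums = matrix.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample columns: {list(zero.index)}")
    return matrix.div(sums, axis=1)


def coverage_report(matrix: pd.DataFrame, db: Sequence[DatabaseEntry]) -> Dict[str, float]:
    """Count database entries detected (area > 0) in at least one sample."""
    if matrix.empty or matrix.shape[1] == 0:
        return {"detected": 0, "total": len(db), "percent": 0.0}
    detected = int((matrix.reindex([e.name for e in db]).fillna(0.0) > 0).any(axis=1).sum())
    total = len(db)
    return {
        "detected": detected,
        "total": total,
        "percent": 100.0 * detected / total if total else 0.0,
    }
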