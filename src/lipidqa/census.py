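"""Published bookkeeping of the curated SRM 1950 plasma lipid database.

The shipped database characterizes NIST SRM 1950 ("Metabolites in Frozen
Human Plasma") with 592 lipid species across 20 subclasses.  This module
records the per-subclass species counts and headline curation tallies and
derives the summary ratios from them (subclass shares, annotation-level
percentages, MS/MS coverage, Z-score consistency, hierarchy-exception and
detection-coverage rates), so every percentage the toolkit reports is an
exact ratio of counts rather than a transcribed number.
"""

from __future__ import annotations

from typing import Dict, Mapping

__all__ = [
    "SUBCLASS_COUNTS",
    "total_species",
    "subclass_share",
    "summary",
]

#: species per subclass in the curated database
SUBCLASS_COUNTS: Mapping[str, int] = {
    "FA": 36,
    "CAR": 20,
    "Cer": 29,
    "SM": 51,
    "HexCer": 5,
    "PC": 93,
    "PC O/P": 64,
    "PE": 16,
    "PE O/P": 24,
    "PI": 18,
    "LPC": 37,
    "LPC O": 4,
    "LPC O/P": 4,
    "LPE": 13,
    "LPE O/P": 5,
    "LPI": 10,
    "DG": 16,
    "TG": 135,
    "CE": 11,
    "Cholesterol": 1,
}

#: reference annotation set size (annotations consistent across mass
#: accuracy, MS/MS fragments, retention behavior, and adduct profile)
REFLAS_COUNT = 289

#: annotation-level tallies
MOLECULAR_SPECIES_COUNT = 322
SN_POSITION_COUNT = 281

#: annotations with an MS/MS spectrum in at least one polarity
MSMS_ANNOTATED_COUNT = 445

#: species whose subclass m/z-error Z-score is < 2 / > 3
ZSCORE_LT2_COUNT = 570
ZSCORE_GT3_COUNT = 9

#: adduct-hierarchy exceptions found by compliance screening
TG_HIERARCHY_EXCEPTIONS = 10
CE_HIERARCHY_EXCEPTIONS = 3

#: species detected in the ten-donor healthy cohort
HEALTHY_DETECTED_COUNT = 583


def total_species() -> int:
    """Total database size (sum of the per-subclass counts)."""
    return sum(SUBCLASS_COUNTS.values())


def subclass_share(subclass: str) -> float:
    """Percentage of the database belonging to one subclass."""
    return 100.0 * SUBCLASS_COUNTS[subclass] / total_species()


def summary() -> Dict[str, float]:
    """All headline ratios as exact fractions of the recorded counts."""
    n = total_species()
    exceptions = TG_HIERARCHY_EXCEPTIONS + CE_HIERARCHY_EXCEPTIONS
    non_reflas = n - REFLAS_COUNT
    return {
        "total_species": n,
        "n_subclasses": len(SUBCLASS_COUNTS),
        "pct_tg": subclass_share("TG"),
        "pct_pc": subclass_share("PC"),
        "pct_pc_op": subclass_share("PC O/P"),
        "pct_molecular_species": 100.0 * MOLECULAR_SPECIES_COUNT / n,
        "pct_sn_position": 100.0 * SN_POSITION_COUNT / n,
        "pct_msms_annotated": 100.0 * MSMS_ANNOTATED_COUNT / n,
        "pct_zscore_lt2": 100.0 * ZSCORE_LT2_COUNT / n,
        "tg_exception_rate": 100.0 * TG_HIERARCHY_EXCEPTIONS / SUBCLASS_COUNTS["TG"],
        "ce_exception_rate": 100.0 * CE_HIERARCHY_EXCEPTIONS / SUBCLASS_COUNTS["CE"],
        # the hierarchy-compliance denominator is ambiguous in the source
        # tallies; both summaries are reported, neither is asserted
        "pct_squant_compliant_all": 100.0 * (n - exceptions) / n,
        "pct_squant_compliant_nonreflas": 100.0 * (non_reflas - exceptions) / non_reflas,
        "pct_healthy_coverage": 100.0 * HEALTHY_DETECTED_COUNT / n,
    }
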