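"""Mass-accuracy QC: ppm errors and within-subclass Z-score screening.

MS1 mass accuracy of lipid adduct ions is considered reliable within ±10
ppm, but the informative signal is the *consistency* of the error within a
lipid subclass: each subclass carries its own small bias, and annotations
whose error sits far from the subclass mean are suspect.  Errors are
therefore standardized per subclass (Z-scores) and summarized by the
|Z| < 2 / 2–3 / > 3 bands.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["PPM_RELIABLE", "ppm_error", "subclass_zscores"]

#: reliability bound on MS1 mass error (ppm)
PPM_RELIABLE = 10.0


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive: {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


def subclass_zscores(records: pd.DataFrame) -> tuple[pd.DataFrame, Dict[str, object]]:
    """Standardize m/z errors within each lipid subclass.

    ``records`` needs columns ``species``, ``subclass`` and either
    ``error_ppm`` or both ``observed_mz`` and ``theoretical_mz``.  Returns a
    copy with ``error_ppm``, ``zscore`` and ``reliable`` (|ppm| ≤ 10)
    columns, plus a summary dict with counts and percentages of |Z| < 2,
    2 ≤ |Z| ≤ 3 and |Z| > 3 (boundary values count in the middle band).

    The sample (n−1) standard deviation is used; subclasses with zero SD
    assign Z = 0 to all members; singleton subclasses are skipped with a
    warning (Z = NaN).
    """
    df = records.copy()
    if "error_ppm" not in df.columns:
        df["error_ppm"] = [
            ppm_error(o, t) for o, t in zip(df["observed_mz"], df["theoretical_mz"])
        ]
    df["reliable"] = df["error_ppm"].abs() <= PPM_RELIABLE

    z = np.full(len(df), np.nan)
    for subclass, idx in df.groupby("subclass").groups.items():
        errs = df.loc[idx, "error_ppm"].to_numpy(dtype=float)
        if len(errs) < 2:
            warnings.warn(f"subclass {subclass!r} has a single record; Z-score skipped")
            continue
        sd = errs.std(ddof=1)
        mean = errs.mean()
        z[df.index.get_indexer(idx)] = 0.0 if sd == 0 else (errs - mean) / sd
    df["zscore"] = z

    scored = df["zscore"].dropna().abs()
    n = len(scored)
    lt2 = int((scored < 2).sum())
    gt3 = int((scored > 3).sum())
    mid = n - lt2 - gt3
    summary = {
        "n_scored": n,
        "n_total": len(df),
        "z_lt_2": lt2,
        "z_2_to_3": mid,
        "z_gt_3": gt3,
        "pct_z_lt_2": 100.0 * lt2 / n if n else float("nan"),
        "pct_reliable": 100.0 * df["reliable"].mean() if len(df) else float("nan"),
        "note": "|Z| exactly 2 counts in the 2-3 band (the < 2 band is strict)",
    }
    return df, summary
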