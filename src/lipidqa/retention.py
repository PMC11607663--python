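"""Retention-behavior consistency checks for reversed-phase lipid LC.

The 19-minute gradient is segmented into alternating isocratic and gradient
regions (I1, G1, I2, G2, I3, G3).  Within a lipid subclass the reversed-phase
elution order obeys two empirical rules: at fixed unsaturation, more carbons
→ later elution; at fixed carbon number, more double bonds → earlier
elution.  Chain isomers with the same sum composition separate by a further
set of rules (opposite for glycerophospholipids and sphingolipids), and
triacylglycerols co-elute in equivalent-carbon-number (ECN) series.  This
module encodes those rules as checkable predicates over retention series,
plus replicate-RT confidence intervals and an interpolation-based expected-RT
screen for new annotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .chem import AnnotationLevel, LipidSpecies, Linkage, ecn

__all__ = [
    "GradientSegment",
    "GradientProgram",
    "DEFAULT_GRADIENT",
    "assign_segment",
    "RTSeries",
    "RTViolation",
    "check_carbon_monotonic",
    "check_unsaturation_monotonic",
    "isomer_elution_order",
    "ecn_series_cluster",
    "rt_ci95",
    "validate_annotation_rt",
    "RTValidation",
]

#: instrument-level RT resolution: differences below this are ties
RT_EQUALITY_TOL = 0.01


@dataclass(frozen=True)
class GradientSegment:
    label: str
    start: float
    end: float
    kind: str  # "isocratic" | "gradient"


@dataclass(frozen=True)
class GradientProgram:
    """Contiguous half-open chromatographic segments covering the run."""

    segments: Tuple[GradientSegment, ...]

    def __post_init__(self):
        segs = self.segments
        if not segs:
            raise ValueError("empty gradient program")
        for a, b in zip(segs, segs[1:]):
            if not math.isclose(a.end, b.start):
                raise ValueError(f"segments {a.label}/{b.label} not contiguous")
        for s in segs:
            if s.end <= s.start:
                raise ValueError(f"segment {s.label} has non-positive length")

    @property
    def start(self) -> float:
        return self.segments[0].start

    @property
    def end(self) -> float:
        return self.segments[-1].end


#: the method's program: three isocratic and three gradient segments
DEFAULT_GRADIENT = GradientProgram(
    (
        GradientSegment("I1", 0.0, 1.0, "isocratic"),
        GradientSegment("G1", 1.0, 3.5, "gradient"),
        GradientSegment("I2", 3.5, 10.0, "isocratic"),
        GradientSegment("G2", 10.0, 11.0, "gradient"),
        GradientSegment("I3", 11.0, 17.10, "isocratic"),
        GradientSegment("G3", 17.10, 19.0, "gradient"),
    )
)


def assign_segment(rt: float, program: GradientProgram = DEFAULT_GRADIENT) -> str:
    """Label of the half-open segment containing ``rt``.

    The final end point maps to the last segment, so the mapping is total on
    [start, end].
    """
    if rt < program.start or rt > program.end:
        raise ValueError(f"RT {rt} outside gradient program [{program.start}, {program.end}]")
    for seg in program.segments:
        if seg.start <= rt < seg.end:
            return seg.label
    return program.segments[-1].label


# --------------------------------------------------------------------------
# Monotonicity checks over retention series
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RTSeries:
    """Within-subclass retention series.

    ``kind = "carbon"`` varies NC at fixed DB; ``kind = "unsaturation"``
    varies DB at fixed NC.  Points are (varying index, RT min), strictly
    increasing in the index.
    """

    subclass: str
    kind: str  # "carbon" | "unsaturation"
    points: Tuple[Tuple[int, float], ...]
    fixed: Optional[int] = None  # the held-constant DB (carbon) or NC (unsat)

    def __post_init__(self):
        if self.kind not in ("carbon", "unsaturation"):
            raise ValueError(f"unknown series kind {self.kind!r}")
        if len(self.points) < 2:
            raise ValueError("retention series needs >= 2 points")
        idx = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("series index must be strictly increasing")


@dataclass(frozen=True)
class RTViolation:
    subclass: str
    rule: str
    index_a: int
    index_b: int
    rt_a: float
    rt_b: float


def check_carbon_monotonic(series: RTSeries) -> List[RTViolation]:
    """RT must strictly increase with carbon number at fixed unsaturation.

    Adjacent pairs whose RT decreases by more than the instrument tie
    tolerance are reported.
    """
    if series.kind != "carbon":
        raise ValueError("expected a carbon series")
    out = []
    for (ia, ra), (ib, rb) in zip(series.points, series.points[1:]):
        if rb - ra < -RT_EQUALITY_TOL:
            out.append(RTViolation(series.subclass, "carbon_increasing", ia, ib, ra, rb))
    return out


def check_unsaturation_monotonic(series: RTSeries, category: str = "GP-like") -> List[RTViolation]:
    """RT must strictly decrease with double-bond count at fixed carbons.

    The sum-composition rule is shared by glycerophospholipid-like and
    sphingolipid subclasses; ``category`` is kept for symmetry with the
    chain-isomer rules (the SP reversal concerns isomers, not series).
    """
    if series.kind != "unsaturation":
        raise ValueError("expected an unsaturation series")
    out = []
    for (ia, ra), (ib, rb) in zip(series.points, series.points[1:]):
        if rb - ra > RT_EQUALITY_TOL:
            out.append(
                RTViolation(series.subclass, "unsaturation_decreasing", ia, ib, ra, rb)
            )
    return out


# --------------------------------------------------------------------------
# Chain-isomer elution order
# --------------------------------------------------------------------------

_SP_SUBCLASSES = {"Cer", "SM", "HexCer"}


def isomer_elution_order(a: LipidSpecies, b: LipidSpecies, category: Optional[str] = None) -> str:
    """Predicted elution order of two chain isomers of one sum composition.

    Returns ``"a_later"``, ``"b_later"`` or ``"indeterminate"``.

    Glycerophospholipid (GP) rules, two chains: (1) the isomer with the
    larger unsaturation spread |DB₁ − DB₂| elutes later; (2) at equal
    spread, the isomer with more carbons on its least-unsaturated chain
    elutes later.  Sphingolipid (SP) rule: the isomer with the higher
    double-bond count on the sphingoid backbone elutes later (the backbone
    trans double bond retains, opposite to the cis chains of GP).
    """
    if a.subclass != b.subclass or a.nc != b.nc or a.db != b.db:
        raise ValueError("isomer comparison requires identical subclass and sum composition")
    if a.annotation_level is AnnotationLevel.SPECIES or b.annotation_level is AnnotationLevel.SPECIES:
        raise ValueError("isomer comparison requires resolved chains")
    if category is None:
        category = "SP" if a.subclass in _SP_SUBCLASSES else "GP"

    if sorted((c.carbons, c.double_bonds) for c in a.chains) == sorted(
        (c.carbons, c.double_bonds) for c in b.chains
    ):
        return "indeterminate"

    if category == "SP":
        dba = a.chains[0].double_bonds
        dbb = b.chains[0].double_bonds
        if dba > dbb:
            return "a_later"
        if dbb > dba:
            return "b_later"
        return "indeterminate"

    # GP-like, two chains
    def spread(s: LipidSpecies) -> int:
        dbs = [c.double_bonds for c in s.chains]
        return max(dbs) - min(dbs)

    sa, sb = spread(a), spread(b)
    if sa != sb:
        return "a_later" if sa > sb else "b_later"

    def carbons_on_least_unsat(s: LipidSpecies) -> int:
        min_db = min(c.double_bonds for c in s.chains)
        return max(c.carbons for c in s.chains if c.double_bonds == min_db)

    ca, cb = carbons_on_least_unsat(a), carbons_on_least_unsat(b)
    if ca != cb:
        return "a_later" if ca > cb else "b_later"
    return "indeterminate"


# --------------------------------------------------------------------------
# TG ECN co-elution series
# --------------------------------------------------------------------------


@dataclass
class ECNClusterReport:
    groups: Dict[int, List[Tuple[str, float]]]  # ECN -> [(name, rt)]
    spread_flags: List[int]          # ECN groups with RT spread > 2*rt_tol
    order_flags: List[Tuple[int, int]]   # consecutive ECN pairs with non-increasing medians
    gap_flags: List[Tuple[int, int, int]]  # ECN triples where the RT gap narrows

    @property
    def ok(self) -> bool:
        return not (self.spread_flags or self.order_flags or self.gap_flags)


def ecn_series_cluster(
    entries: Sequence[Tuple[LipidSpecies, float]],
    rt_tol: float = 0.2,
) -> ECNClusterReport:
    """Group TG by ECN and diagnose the co-elution series structure.

    TG sharing an ECN must co-elute within ± ``rt_tol`` min; group median
    RTs must increase with ECN; and the RT gap between consecutive series
    must widen as ECN increases.
    """
    if not entries:
        raise ValueError("empty TG entry list")
    groups: Dict[int, List[Tuple[str, float]]] = {}
    for sp, rt in entries:
        if sp.subclass != "TG":
            raise ValueError(f"{sp.name} is not a TG")
        groups.setdefault(ecn(sp), []).append((sp.name, rt))
    for g in groups.values():
        g.sort()

    spread_flags = [
        e for e, g in groups.items()
        if max(rt for _, rt in g) - min(rt for _, rt in g) > 2 * rt_tol
    ]
    ecns = sorted(groups)
    medians = {e: float(np.median([rt for _, rt in groups[e]])) for e in ecns}
    order_flags = [
        (e1, e2)
        for e1, e2 in zip(ecns, ecns[1:])
        if medians[e2] - medians[e1] < RT_EQUALITY_TOL
    ]
    gap_flags = []
    for e1, e2, e3 in zip(ecns, ecns[1:], ecns[2:]):
        # normalize gaps per ECN unit so uneven series spacing compares fairly
        g12 = (medians[e2] - medians[e1]) / (e2 - e1)
        g23 = (medians[e3] - medians[e2]) / (e3 - e2)
        if g23 - g12 < -RT_EQUALITY_TOL:
            gap_flags.append((e1, e2, e3))
    return ECNClusterReport(groups, spread_flags, order_flags, gap_flags)


# --------------------------------------------------------------------------
# Replicate RT confidence interval
# --------------------------------------------------------------------------


def rt_ci95(replicate_rts: Sequence[float], flag_width: float = 0.2) -> Tuple[float, bool]:
    """95% CI width (upper − lower) of the replicate mean RT, t-distribution.

    Returns ``(width, flagged)``; flagged when the width exceeds
    ``flag_width`` minutes (the method's RT robustness ceiling).
    """
    n = len(replicate_rts)
    if n < 2:
        raise ValueError("need >= 2 replicates for a confidence interval")
    arr = np.asarray(replicate_rts, dtype=float)
    sd = arr.std(ddof=1)
    half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    width = 2.0 * half
    return width, width > flag_width


# --------------------------------------------------------------------------
# Expected-RT validation of candidate annotations
# --------------------------------------------------------------------------


@dataclass
class RTValidation:
    species: str
    observed_rt: float
    expected_rt: Optional[float]
    residual: Optional[float]
    status: str  # "accept" | "flag" | "soft_flag"


def _interp_extrap(x: float, xs: np.ndarray, ys: np.ndarray) -> float:
    # piecewise linear inside the series, linear extrapolation at the ends
    if x <= xs[0]:
        slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
        return float(ys[0] + slope * (x - xs[0]))
    if x >= xs[-1]:
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        return float(ys[-1] + slope * (x - xs[-1]))
    return float(np.interp(x, xs, ys))


def validate_annotation_rt(
    candidate: Tuple[LipidSpecies, float],
    refmap: Mapping[str, Sequence[RTSeries]],
    tol: float = 0.2,
) -> RTValidation:
    """Screen a candidate (species, RT) against reference retention series.

    The expected RT is interpolated on the subclass series matching the
    candidate (a carbon series at its DB, or an unsaturation series at its
    NC), linearly extrapolated at the ends.  Residuals beyond ``tol`` are
    hard flags; candidates outside the gross subclass RT range but with no
    matching series are soft flags only — out-of-range species are not
    automatically false positives.
    """
    species, rt = candidate
    series_list = refmap.get(species.subclass)
    if not series_list:
        raise ValueError(f"no reference series for subclass {species.subclass}")

    matching = [
        s for s in series_list
        if (s.kind == "carbon" and (s.fixed is None or s.fixed == species.db))
        or (s.kind == "unsaturation" and (s.fixed is None or s.fixed == species.nc))
    ]
    all_rts = [rt_ for s in series_list for _, rt_ in s.points]
    gross_lo, gross_hi = min(all_rts) - tol, max(all_rts) + tol

    best: Optional[Tuple[float, float]] = None  # (|residual|, expected)
    for s in matching:
        xs = np.array([p[0] for p in s.points], dtype=float)
        ys = np.array([p[1] for p in s.points], dtype=float)
        x = float(species.nc if s.kind == "carbon" else species.db)
        exp_rt = _interp_extrap(x, xs, ys)
        if best is None or abs(rt - exp_rt) < best[0]:
            best = (abs(rt - exp_rt), exp_rt)

    if best is None:
        status = "soft_flag" if not (gross_lo <= rt <= gross_hi) else "accept"
        return RTValidation(species.name, rt, None, None, status)

    residual = rt - best[1]
    if abs(residual) <= tol:
        status = "accept"
    elif not (gross_lo <= rt <= gross_hi):
        status = "soft_flag"
    else:
        status = "flag"
    return RTValidation(species.name, rt, best[1], residual, status)
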