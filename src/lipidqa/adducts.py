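"""ESI adduct/cluster/in-source-fragment chemistry and hierarchy consensus.

In electrospray, each lipid species produces a subclass-characteristic set of
singly charged adducts ([M+H]+, [M+Na]+, [M+NH4]+, [M+CH3COO]−, ...),
background clusters (sodium-acetate ladders in negative mode) and in-source
fragments (ISF).  This module:

* registers adduct chemistry (:class:`AdductDef`, :data:`DEFAULT_REGISTRY`)
  and computes adduct m/z from the neutral monoisotopic mass;
* groups co-eluting MS1 features into per-species adduct profiles by
  requiring two or more adduct hypotheses to agree on one neutral mass;
* builds per-subclass consensus forms from a reference annotation set:
  the qualitative adduct set (cQualForm) and the reproducible intensity-rank
  hierarchy (cSquantForm, ordered tiers);
* scores observed profiles against the consensus: the adduct hierarchy
  richness level (AHRL) and a compliance report used for false-positive
  screening;
* implements the triacylglycerol neutral-loss bookkeeping that flags
  chimeric MS/MS fragments shared between co-eluting [M+NH4]+ precursors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .chem import (
    ELECTRON_MASS,
    ElementalFormula,
    LipidSpecies,
    compose_formula,
    monoisotopic_mass,
    parse_lipid_name,
)

__all__ = [
    "AdductDef",
    "DEFAULT_REGISTRY",
    "SODIUM_ACETATE",
    "adduct_mz",
    "neutral_mass_from_mz",
    "SpeciesAdductProfile",
    "group_coeluting_features",
    "ConsensusQualForm",
    "ConsensusSquantForm",
    "build_cqualform",
    "build_csquantform",
    "ahrl",
    "ComplianceReport",
    "check_compliance",
    "expected_isf",
    "tg_neutral_loss_assign",
]

EMPTY = ElementalFormula({})
SODIUM_ACETATE = ElementalFormula.parse("NaC2H3O2")  # +82.0031 Da repeat unit


@dataclass(frozen=True)
class AdductDef:
    """One ESI ion form: label, polarity, charge, atoms added/removed."""

    label: str
    polarity: str  # "+" or "-"
    z: int  # signed charge
    added: ElementalFormula = EMPTY
    removed: ElementalFormula = EMPTY
    n: int = 1  # multimer count
    is_isf: bool = False
    cluster_repeat: Optional[Tuple[ElementalFormula, int]] = None

    def __post_init__(self):
        if self.z == 0:
            raise ValueError("adduct charge must be non-zero")
        if self.polarity not in ("+", "-"):
            raise ValueError(f"polarity must be '+' or '-': {self.polarity!r}")


def adduct_mz(neutral_mass: float, adduct: AdductDef) -> float:
    """m/z of an adduct: (n·M + m(added) − m(removed) − z·mₑ) / |z|."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive: {neutral_mass}")
    m = (
        adduct.n * neutral_mass
        + monoisotopic_mass(adduct.added)
        - monoisotopic_mass(adduct.removed)
        - adduct.z * ELECTRON_MASS
    )
    return m / abs(adduct.z)


def neutral_mass_from_mz(mz: float, adduct: AdductDef) -> float:
    """Invert :func:`adduct_mz` for n = 1 ions."""
    m = mz * abs(adduct.z)
    return (
        m
        - monoisotopic_mass(adduct.added)
        + monoisotopic_mass(adduct.removed)
        + adduct.z * ELECTRON_MASS
    ) / adduct.n


def _sodium_acetate_clusters(max_n: int = 6) -> List[AdductDef]:
    out = []
    for k in range(1, max_n + 1):
        out.append(
            AdductDef(
                label=f"[M+CH3COO+{k}NaC2H3O2]-",
                polarity="-",
                z=-1,
                added=ElementalFormula.parse("C2H3O2") + k * SODIUM_ACETATE,
                cluster_repeat=(SODIUM_ACETATE, 6),
            )
        )
    return out


#: Default singly charged registry for this LC-MS method.  ESI(+):
#: protonated, sodiated, potassiated, ammoniated, the ammonium–acetonitrile
#: cluster [M+C2H7N2]+, and the water-loss ISF.  ESI(−): deprotonated,
#: acetate, the choline methyl-loss ISF, and sodium-acetate cluster ladders.
DEFAULT_REGISTRY: Tuple[AdductDef, ...] = tuple(
    [
        AdductDef("[M+H]+", "+", 1, added=ElementalFormula.parse("H")),
        AdductDef("[M+Na]+", "+", 1, added=ElementalFormula.parse("Na")),
        AdductDef("[M+K]+", "+", 1, added=ElementalFormula.parse("K")),
        AdductDef("[M+NH4]+", "+", 1, added=ElementalFormula.parse("NH4")),
        AdductDef("[M+C2H7N2]+", "+", 1, added=ElementalFormula.parse("C2H7N2")),
        AdductDef(
            "[M+H-H2O]+", "+", 1,
            added=ElementalFormula.parse("H"),
            removed=ElementalFormula.parse("H2O"),
            is_isf=True,
        ),
        AdductDef("[M-H]-", "-", -1, removed=ElementalFormula.parse("H")),
        AdductDef("[M+CH3COO]-", "-", -1, added=ElementalFormula.parse("C2H3O2")),
        AdductDef(
            "[M-CH3]-", "-", -1,
            removed=ElementalFormula.parse("CH3"),
            is_isf=True,
        ),
    ]
    + _sodium_acetate_clusters()
)

_REGISTRY_ORDER = {a.label: i for i, a in enumerate(DEFAULT_REGISTRY)}


def registry_order(label: str) -> int:
    """Position of an adduct label in the default registry (tie-breaking)."""
    return _REGISTRY_ORDER.get(label, len(_REGISTRY_ORDER))


# --------------------------------------------------------------------------
# Co-eluting feature grouping
# --------------------------------------------------------------------------


@dataclass
class SpeciesAdductProfile:
    """Observed adduct ions of one (putative) species at one retention time."""

    species_id: str
    polarity: str
    observations: List[Tuple[str, float, float, float]]  # (label, mz, rt, intensity)
    neutral_mass_estimate: float
    subclass: Optional[str] = None

    @property
    def labels(self) -> List[str]:
        return [o[0] for o in self.observations]

    def intensity(self, label: str) -> Optional[float]:
        for lab, _, _, inten in self.observations:
            if lab == label:
                return inten
        return None

    @property
    def rt(self) -> float:
        return sum(o[2] for o in self.observations) / len(self.observations)


def group_coeluting_features(
    features: Sequence[Tuple[float, float, float]],
    registry: Sequence[AdductDef] = DEFAULT_REGISTRY,
    rt_tol: float = 0.2,
    ppm_tol: float = 10.0,
) -> Tuple[List[SpeciesAdductProfile], List[Tuple[float, float, float]]]:
    """Group centroided features into species adduct profiles.

    A profile is accepted when ≥ 2 features, mutually within ``rt_tol`` min,
    are explained by one neutral mass (within ``ppm_tol``) under distinct
    registry adducts — the molecular mass is then unambiguously determined by
    adduct co-presence.  Conflicts are resolved greedily by descending summed
    intensity of the candidate group, so the output is deterministic under
    permutation of the input.

    Returns ``(profiles, ungrouped_features)``.
    """
    if not registry:
        raise ValueError("adduct registry is empty")
    feats = sorted(features, key=lambda f: (f[0], f[1], f[2]))
    # All (feature, adduct) neutral-mass hypotheses.
    hyps = []  # (neutral_mass, feat_index, adduct)
    for i, (mz, rt, inten) in enumerate(feats):
        for add in registry:
            m = neutral_mass_from_mz(mz, add)
            if m > 0:
                hyps.append((m, i, add))

    # Candidate groups: anchor each hypothesis, collect agreeing hypotheses.
    candidates = []  # (summed_intensity, key, member dict feat_idx -> label, mass)
    for m0, i0, a0 in hyps:
        members: Dict[int, Tuple[str, float]] = {}
        for m, i, a in hyps:
            if a.polarity != a0.polarity:
                continue
            if abs(m - m0) / m0 * 1e6 > ppm_tol:
                continue
            if abs(feats[i][1] - feats[i0][1]) > rt_tol:
                continue
            # keep one hypothesis per feature: closest mass to anchor
            prev = members.get(i)
            if prev is None or abs(m - m0) < abs(prev[1] - m0):
                members[i] = (a.label, m)
        if len(members) < 2:
            continue
        if len({lab for lab, _ in members.values()}) < 2:
            continue
        total = sum(feats[i][2] for i in members)
        key = tuple(sorted((i, lab) for i, (lab, _) in members.items()))
        candidates.append((total, key, members, m0))

    # Greedy assignment by descending summed intensity (key breaks ties).
    candidates.sort(key=lambda c: (-c[0], c[1]))
    used: Set[int] = set()
    profiles: List[SpeciesAdductProfile] = []
    for total, key, members, m0 in candidates:
        free = {i: v for i, v in members.items() if i not in used}
        if len(free) < 2 or len({lab for lab, _ in free.values()}) < 2:
            continue
        used.update(free)
        obs = [
            (lab, feats[i][0], feats[i][1], feats[i][2])
            for i, (lab, m) in sorted(free.items())
        ]
        mass = sum(m for _, m in free.values()) / len(free)
        by_label = {a.label: a.polarity for a in registry}
        pol = by_label[obs[0][0]]
        profiles.append(
            SpeciesAdductProfile(
                species_id=f"M{mass:.4f}@{feats[min(free)][1]:.2f}",
                polarity=pol,
                observations=obs,
                neutral_mass_estimate=mass,
            )
        )
    ungrouped = [f for i, f in enumerate(feats) if i not in used]
    return profiles, ungrouped


# --------------------------------------------------------------------------
# Consensus forms
# --------------------------------------------------------------------------


@dataclass
class ConsensusQualForm:
    """Qualitative adduct set expected for a subclass in one polarity."""

    subclass: str
    polarity: str
    required: Set[str]
    optional: Set[str]

    @property
    def allowed(self) -> Set[str]:
        return self.required | self.optional


@dataclass
class ConsensusSquantForm:
    """Reproducible intensity-rank hierarchy: ordered tiers of adduct labels."""

    subclass: str
    polarity: str
    tiers: List[Set[str]]  # tier 0 = most intense
    support: List[float]   # fraction of profiles reproducing each tier's rank

    def tier_of(self, label: str) -> Optional[int]:
        for i, tier in enumerate(self.tiers):
            if label in tier:
                return i
        return None


def _admit(profiles: Iterable[SpeciesAdductProfile]) -> List[SpeciesAdductProfile]:
    # Reference-set admission rule: the molecular mass must be determined by
    # the co-presence of two or more adducts.
    return [p for p in profiles if len(set(p.labels)) >= 2]


def build_cqualform(
    profiles: Sequence[SpeciesAdductProfile],
    min_presence: float = 0.9,
) -> Dict[Tuple[str, str], ConsensusQualForm]:
    """Build per-(subclass, polarity) qualitative consensus adduct sets.

    An adduct is *required* when present in ≥ ``min_presence`` of the
    admitted reference profiles of the subclass, *optional* when observed at
    all.  Profiles with fewer than two adducts are rejected at admission.
    """
    admitted = _admit(profiles)
    by_group: Dict[Tuple[str, str], List[SpeciesAdductProfile]] = {}
    for p in admitted:
        if p.subclass is None:
            raise ValueError(f"profile {p.species_id} has no subclass label")
        by_group.setdefault((p.subclass, p.polarity), []).append(p)
    if not by_group:
        raise ValueError("no admissible reference profiles (need >= 2 adducts each)")
    out = {}
    for (subclass, pol), group in by_group.items():
        counts: Dict[str, int] = {}
        for p in group:
            for lab in set(p.labels):
                counts[lab] = counts.get(lab, 0) + 1
        required = {lab for lab, c in counts.items() if c / len(group) >= min_presence}
        optional = set(counts) - required
        out[(subclass, pol)] = ConsensusQualForm(subclass, pol, required, optional)
    return out


def build_csquantform(
    profiles: Sequence[SpeciesAdductProfile],
    support_threshold: float = 0.8,
) -> Dict[Tuple[str, str], ConsensusSquantForm]:
    """Build per-(subclass, polarity) semi-quantitative adduct hierarchies.

    Adducts are ordered by mean within-profile intensity rank; consecutive
    adducts are merged into one tier when the pairwise order is reproduced in
    fewer than ``support_threshold`` of the profiles observing both.
    """
    admitted = _admit(profiles)
    by_group: Dict[Tuple[str, str], List[SpeciesAdductProfile]] = {}
    for p in admitted:
        if p.subclass is None:
            raise ValueError(f"profile {p.species_id} has no subclass label")
        by_group.setdefault((p.subclass, p.polarity), []).append(p)
    if not by_group:
        raise ValueError("no admissible reference profiles (need >= 2 adducts each)")

    out = {}
    for (subclass, pol), group in by_group.items():
        labels = sorted(
            {lab for p in group for lab in p.labels}, key=registry_order
        )
        # Mean normalized rank (0 = most intense within its profile).
        rank_sum = {lab: 0.0 for lab in labels}
        rank_n = {lab: 0 for lab in labels}
        for p in group:
            order = sorted(
                set(p.labels),
                key=lambda lab: (-p.intensity(lab), registry_order(lab)),
            )
            denom = max(len(order) - 1, 1)
            for r, lab in enumerate(order):
                rank_sum[lab] += r / denom
                rank_n[lab] += 1
        consensus_order = sorted(
            labels, key=lambda lab: (rank_sum[lab] / rank_n[lab], registry_order(lab))
        )

        # Pairwise order support between consecutive adducts.
        tiers: List[Set[str]] = [{consensus_order[0]}]
        support: List[float] = [1.0]
        for prev, cur in zip(consensus_order, consensus_order[1:]):
            both = [
                p for p in group
                if p.intensity(prev) is not None and p.intensity(cur) is not None
            ]
            if both:
                frac = sum(
                    1 for p in both if p.intensity(prev) > p.intensity(cur)
                ) / len(both)
            else:
                frac = 0.0
            if frac >= support_threshold:
                tiers.append({cur})
                support.append(frac)
            else:
                tiers[-1].add(cur)
                support[-1] = min(support[-1], frac) if len(both) else support[-1]
        out[(subclass, pol)] = ConsensusSquantForm(subclass, pol, tiers, support)
    return out


def ahrl(profile: SpeciesAdductProfile, form: ConsensusSquantForm) -> int:
    """Adduct hierarchy richness level.

    The largest k such that tiers 1..k of the subclass hierarchy each have at
    least one observed adduct; 0 when the top tier is unobserved.
    """
    if profile.polarity != form.polarity:
        raise ValueError("profile polarity does not match consensus form")
    observed = set(profile.labels)
    level = 0
    for tier in form.tiers:
        if tier & observed:
            level += 1
        else:
            break
    return level


@dataclass
class ComplianceReport:
    """Result of screening one profile against its subclass consensus."""

    species_id: str
    qual_pass: bool
    hierarchy_pass: bool
    foreign_adducts: List[str]
    hierarchy_violations: List[Tuple[str, str]]  # (lower-tier label outranking, higher-tier label)

    @property
    def ok(self) -> bool:
        return self.qual_pass and self.hierarchy_pass


def check_compliance(
    profile: SpeciesAdductProfile,
    qual: ConsensusQualForm,
    squant: ConsensusSquantForm,
) -> ComplianceReport:
    """Screen a profile for foreign adducts and hierarchy inversions.

    ``qual_pass`` fails when any observed adduct is outside the consensus
    qualitative set (false-positive indicator).  ``hierarchy_pass`` fails
    when an adduct from a lower tier shows intensity ≥ an observed adduct of
    a higher tier (e.g. [M+K]+ ≥ [M+Na]+ in TG).
    """
    observed = set(profile.labels)
    foreign = sorted(observed - qual.allowed, key=registry_order)
    violations: List[Tuple[str, str]] = []
    ranked = [
        (lab, squant.tier_of(lab))
        for lab in sorted(observed, key=registry_order)
        if squant.tier_of(lab) is not None
    ]
    for (la, ta), (lb, tb) in itertools.combinations(ranked, 2):
        if ta == tb:
            continue
        hi, lo = (la, lb) if ta < tb else (lb, la)
        if profile.intensity(lo) >= profile.intensity(hi):
            violations.append((lo, hi))
    return ComplianceReport(
        species_id=profile.species_id,
        qual_pass=not foreign,
        hierarchy_pass=not violations,
        foreign_adducts=foreign,
        hierarchy_violations=violations,
    )


# --------------------------------------------------------------------------
# In-source fragmentation expectations
# --------------------------------------------------------------------------

_ISF_WATER_LOSS = {"LPC", "Cer", "HexCer", "DG", "Cholesterol"}
_ISF_METHYL_LOSS = {"SM", "PC", "PC O/P", "LPC"}

_KNOWN_SUBCLASSES = {
    "FA", "CAR", "Cer", "SM", "HexCer", "PC", "PC O/P", "PE", "PE O/P", "PI",
    "LPC", "LPC O", "LPC O/P", "LPE", "LPE O/P", "LPI", "DG", "TG", "CE",
    "Cholesterol",
}


def expected_isf(subclass: str) -> Set[AdductDef]:
    """In-source fragments expected for a subclass under this method.

    Hydroxyl-bearing subclasses lose water from the protonated ion
    ([M+H−H2O]+); choline-head subclasses lose a methyl from the acetate
    adduct ([M−CH3]−).
    """
    if subclass not in _KNOWN_SUBCLASSES:
        raise ValueError(f"unknown subclass {subclass!r}")
    out: Set[AdductDef] = set()
    by_label = {a.label: a for a in DEFAULT_REGISTRY}
    if subclass in _ISF_WATER_LOSS:
        out.add(by_label["[M+H-H2O]+"])
    if subclass in _ISF_METHYL_LOSS:
        out.add(by_label["[M-CH3]-"])
    return out


# --------------------------------------------------------------------------
# TG neutral-loss assignment and chimeric-spectrum flagging
# --------------------------------------------------------------------------

NH3 = ElementalFormula.parse("NH3")


@dataclass
class NeutralLossAssignment:
    precursor: str
    precursor_mz: float
    fragment_mz: float
    fa: Optional[str]  # "FA(c:d)" or None when unassigned
    ppm: Optional[float]
    chimeric: bool = False


def _fa_nl_masses(
    c_range: Tuple[int, int] = (2, 30), d_range: Tuple[int, int] = (0, 8)
) -> List[Tuple[str, float]]:
    out = []
    for c in range(c_range[0], c_range[1] + 1):
        for d in range(d_range[0], min(d_range[1], c // 2) + 1):
            fa = parse_lipid_name(f"FA({c}:{d})")
            out.append((fa.name, monoisotopic_mass(compose_formula(fa)) +
                        monoisotopic_mass(NH3)))
    return out


def tg_neutral_loss_assign(
    precursors: Sequence[Tuple[str, float]],
    fragments: Sequence[float],
    ppm_tol: float = 10.0,
) -> Tuple[List[NeutralLossAssignment], bool]:
    """Assign MS/MS fragments of co-eluting TG [M+NH4]+ precursors.

    For each (precursor, fragment) pair the neutral loss is matched against
    FA(c:d) + NH3 within ``ppm_tol``.  A fragment assignable under two or
    more precursors is *chimeric*; a spectrum containing any chimeric
    fragment is flagged convoluted.

    Returns ``(assignments, convoluted_flag)``.
    """
    if not precursors:
        raise ValueError("empty precursor list")
    nl_table = _fa_nl_masses()
    assignments: List[NeutralLossAssignment] = []
    frag_hits: Dict[float, int] = {f: 0 for f in fragments}
    for name, pmz in precursors:
        for fmz in fragments:
            nl = pmz - fmz
            if nl <= 0:
                continue
            best = None
            for fa_name, nl_theory in nl_table:
                ppm = (nl - nl_theory) / nl_theory * 1e6
                if abs(ppm) <= ppm_tol and (best is None or abs(ppm) < abs(best[1])):
                    best = (fa_name, ppm)
            if best is not None:
                frag_hits[fmz] += 1
                assignments.append(
                    NeutralLossAssignment(name, pmz, fmz, best[0], best[1])
                )
            else:
                assignments.append(
                    NeutralLossAssignment(name, pmz, fmz, None, None)
                )
    chimeric_frags = {f for f, n in frag_hits.items() if n >= 2}
    for a in assignments:
        if a.fragment_mz in chimeric_frags and a.fa is not None:
            a.chimeric = True
    return assignments, bool(chimeric_frags)
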