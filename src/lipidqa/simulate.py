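"""Synthetic plasma-like lipid databases and MS1 runs with ground truth.

The generator emulates the statistical structure the QA and extraction
modules assume of a real plasma run on this LC-MS method:

* per-subclass species pools over realistic (NC, DB) grids, sized like the
  curated database (592 species over 20 subclasses);
* an additive retention model per subclass — positive carbon slope,
  negative double-bond slope — which guarantees the reversed-phase elution
  rules by construction; TG use a convex function of ECN so ECN series
  co-elute exactly and inter-series gaps widen with ECN;
* subclass-specific adduct hierarchies emitted with reproducible tiered
  intensity ratios plus rank-preserving log-normal noise;
* ppm-scale m/z error with a per-subclass bias, RT jitter, isotopologue
  peaks M..M+2, and optional per-adduct dropout;
* blank runs containing only random background and, in negative mode, the
  sodium-acetate cluster ladder.

Everything is driven by a single integer seed, so each draw is reproducible
and the generating parameters double as ground truth for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .adducts import DEFAULT_REGISTRY, adduct_mz
from .chem import LipidSpecies, compose_formula, monoisotopic_mass, parse_lipid_name
from .extraction import DatabaseEntry, MS1Run, isotope_pattern

__all__ = [
    "SubclassSim",
    "SimulationConfig",
    "DEFAULT_SUBCLASS_SIMS",
    "simulate_database",
    "simulate_run",
    "simulate_runs",
]


@dataclass(frozen=True)
class SubclassSim:
    """Generative parameters for one lipid subclass."""

    count: int
    nc_range: Tuple[int, int]
    db_range: Tuple[int, int]
    rt_intercept: float
    rt_carbon_slope: float      # min per carbon, > 0
    rt_db_slope: float          # min per double bond, applied negatively, > 0
    pos_tiers: Tuple[Tuple[str, ...], ...] = ()
    neg_tiers: Tuple[Tuple[str, ...], ...] = ()
    ecn_range: Optional[Tuple[int, int]] = None   # extra constraint (TG)
    ecn_model: Optional[Tuple[float, float, float]] = None  # rt = a + b*ECN + c*ECN^2

    def rt_of(self, nc: int, db: int) -> float:
        if self.ecn_model is not None:
            a, b, c = self.ecn_model
            e = nc - 2 * db
            return a + b * e + c * e * e
        return self.rt_intercept + self.rt_carbon_slope * nc - self.rt_db_slope * db


def _t(*tiers: Sequence[str]) -> Tuple[Tuple[str, ...], ...]:
    return tuple(tuple(t) for t in tiers)


# Counts mirror the curated database census; RT coefficients are calibrated
# so each subclass elutes inside its observed window of the 19-min program.
DEFAULT_SUBCLASS_SIMS: Mapping[str, SubclassSim] = {
    "FA": SubclassSim(36, (10, 26), (0, 6), 1.2, 0.22, 0.35,
                      neg_tiers=_t(["[M-H]-"])),
    "CAR": SubclassSim(20, (2, 18), (0, 2), 0.55, 0.11, 0.20,
                       pos_tiers=_t(["[M+H]+"], ["[M+Na]+"])),
    "Cer": SubclassSim(29, (32, 46), (1, 3), -2.5, 0.33, 0.50,
                       pos_tiers=_t(["[M+H]+"], ["[M+H-H2O]+"], ["[M+Na]+"]),
                       neg_tiers=_t(["[M+CH3COO]-"], ["[M-H]-"])),
    "SM": SubclassSim(51, (30, 44), (1, 4), -3.0, 0.33, 0.50,
                      pos_tiers=_t(["[M+H]+"], ["[M+Na]+"], ["[M+K]+"]),
                      neg_tiers=_t(["[M+CH3COO]-"], ["[M-CH3]-"])),
    "HexCer": SubclassSim(5, (34, 42), (1, 2), -3.6, 0.33, 0.50,
                          pos_tiers=_t(["[M+H]+"], ["[M+H-H2O]+"], ["[M+Na]+"]),
                          neg_tiers=_t(["[M+CH3COO]-"], ["[M-H]-"])),
    "PC": SubclassSim(93, (28, 42), (1, 7), -1.5, 0.33, 0.50,
                      pos_tiers=_t(["[M+H]+"], ["[M+Na]+"], ["[M+C2H7N2]+"], ["[M+K]+"]),
                      neg_tiers=_t(["[M+CH3COO]-"], ["[M-CH3]-"])),
    "PC O/P": SubclassSim(64, (28, 40), (1, 6), -0.8, 0.33, 0.50,
                          pos_tiers=_t(["[M+H]+"], ["[M+Na]+"], ["[M+C2H7N2]+"], ["[M+K]+"]),
                          neg_tiers=_t(["[M+CH3COO]-"], ["[M-CH3]-"])),
    "PE": SubclassSim(16, (32, 40), (1, 6), -2.2, 0.33, 0.50,
                      pos_tiers=_t(["[M+H]+"], ["[M+Na]+"]),
                      neg_tiers=_t(["[M-H]-"])),
    "PE O/P": SubclassSim(24, (32, 40), (1, 6), -1.6, 0.33, 0.50,
                          pos_tiers=_t(["[M+H]+"], ["[M+Na]+"]),
                          neg_tiers=_t(["[M-H]-"])),
    "PI": SubclassSim(18, (30, 38), (1, 5), -1.0, 0.27, 0.45,
                      neg_tiers=_t(["[M-H]-"])),
    "LPC": SubclassSim(37, (14, 24), (0, 4), -0.5, 0.25, 0.40,
                       pos_tiers=_t(["[M+H]+"], ["[M+Na]+"], ["[M+H-H2O]+"]),
                       neg_tiers=_t(["[M+CH3COO]-"], ["[M-CH3]-"])),
    "LPC O": SubclassSim(4, (16, 18), (0, 1), -0.6, 0.22, 0.30,
                         pos_tiers=_t(["[M+H]+"], ["[M+Na]+"]),
                         neg_tiers=_t(["[M+CH3COO]-"])),
    "LPC O/P": SubclassSim(4, (16, 18), (0, 1), -0.4, 0.22, 0.30,
                           pos_tiers=_t(["[M+H]+"], ["[M+Na]+"]),
                           neg_tiers=_t(["[M+CH3COO]-"])),
    "LPE": SubclassSim(13, (16, 22), (0, 4), -1.2, 0.20, 0.25,
                       pos_tiers=_t(["[M+H]+"]),
                       neg_tiers=_t(["[M-H]-"])),
    "LPE O/P": SubclassSim(5, (16, 18), (0, 2), -0.3, 0.22, 0.30,
                           pos_tiers=_t(["[M+H]+"]),
                           neg_tiers=_t(["[M-H]-"])),
    "LPI": SubclassSim(10, (16, 20), (0, 2), -1.5, 0.22, 0.30,
                       neg_tiers=_t(["[M-H]-"])),
    "DG": SubclassSim(16, (30, 38), (0, 4), -0.3, 0.33, 0.45,
                      pos_tiers=_t(["[M+NH4]+"], ["[M+Na]+"], ["[M+H-H2O]+"])),
    "TG": SubclassSim(135, (38, 60), (0, 8), 0.0, 0.0, 0.0,
                      pos_tiers=_t(["[M+NH4]+"], ["[M+Na]+"], ["[M+K]+"], ["[M+C2H7N2]+"]),
                      ecn_range=(34, 56),
                      ecn_model=(6.5, 0.08, 0.002)),
    "CE": SubclassSim(11, (14, 22), (0, 6), 11.0, 0.22, 0.35,
                      pos_tiers=_t(["[M+NH4]+"], ["[M+Na]+"], ["[M+K]+"], ["[M+C2H7N2]+"])),
    "Cholesterol": SubclassSim(1, (0, 0), (0, 0), 7.4, 0.0, 0.0,
                               pos_tiers=_t(["[M+H-H2O]+"], ["[M+Na]+"])),
}

#: default per-subclass m/z bias (ppm), cycled deterministically
_BIAS_CYCLE = (-3.0, -1.5, 0.0, 1.5, 3.0)


def _default_biases() -> Dict[str, float]:
    return {
        sc: _BIAS_CYCLE[i % len(_BIAS_CYCLE)]
        for i, sc in enumerate(sorted(DEFAULT_SUBCLASS_SIMS))
    }


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic lipidome."""

    seed: int = 0
    subclasses: Mapping[str, SubclassSim] = field(
        default_factory=lambda: dict(DEFAULT_SUBCLASS_SIMS)
    )
    tier_ratios: Tuple[float, ...] = (1.0, 0.30, 0.10, 0.03)
    adduct_ratio_sigma: float = 0.2   # log-scale, rank-preserving
    area_log_sigma: float = 0.8       # species base-area log-normal spread
    base_area: float = 1.0e6
    ppm_bias: Mapping[str, float] = field(default_factory=_default_biases)
    ppm_sigma: float = 1.0
    rt_jitter_sigma: float = 0.02     # min
    dropout_rate: float = 0.015       # per species-adduct, per run
    n_background: int = 150           # blank background features per run
    background_area: float = 1.0e4

    def __post_init__(self):
        for name, val in (
            ("adduct_ratio_sigma", self.adduct_ratio_sigma),
            ("area_log_sigma", self.area_log_sigma),
            ("ppm_sigma", self.ppm_sigma),
            ("rt_jitter_sigma", self.rt_jitter_sigma),
        ):
            if val < 0:
                raise ValueError(f"{name} must be >= 0, got {val}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


def _species_name(subclass: str, nc: int, db: int) -> str:
    head = subclass.split(" ")[0]
    if subclass in ("Cer", "SM", "HexCer"):
        return f"{head}(d{nc}:{db})"
    if subclass == "LPC O/P":
        return f"{head}(P-{nc}:{db})"
    if subclass.endswith("O/P") or subclass.endswith(" O"):
        return f"{head}(O-{nc}:{db})"
    if subclass == "Cholesterol":
        return "Cholesterol"
    return f"{head}({nc}:{db})"


def _chain_pool(sim: SubclassSim) -> List[Tuple[int, int]]:
    lo_c, hi_c = sim.nc_range
    lo_d, hi_d = sim.db_range
    pool = []
    for nc in range(lo_c, hi_c + 1):
        for db in range(lo_d, min(hi_d, nc // 2) + 1):
            if sim.ecn_range is not None:
                e = nc - 2 * db
                if not (sim.ecn_range[0] <= e <= sim.ecn_range[1]):
                    continue
            pool.append((nc, db))
    return pool


def simulate_database(
    config: SimulationConfig,
) -> Tuple[List[DatabaseEntry], pd.DataFrame]:
    """Draw a species pool per subclass and assign formulas and RTs.

    Returns the database entries and a ground-truth table with the
    generative (NC, DB, ECN, RT, polarity hierarchy) of every species.
    Raises when a subclass pool cannot supply the requested species count.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD5]))
    entries: List[DatabaseEntry] = []
    truth_rows = []
    for subclass in sorted(config.subclasses):
        sim = config.subclasses[subclass]
        if subclass == "Cholesterol":
            combos = [(0, 0)] * sim.count
        else:
            pool = _chain_pool(sim)
            if len(pool) < sim.count:
                raise ValueError(
                    f"infeasible chain pool for {subclass}: "
                    f"{len(pool)} combos < {sim.count} species"
                )
            idx = rng.choice(len(pool), size=sim.count, replace=False)
            combos = sorted(pool[i] for i in idx)
        for nc, db in combos:
            name = _species_name(subclass, nc, db)
            species = parse_lipid_name(name)
            formula = compose_formula(species)
            mass = monoisotopic_mass(formula)
            rt = sim.rt_of(nc, db)
            adducts = tuple(
                lab for tier in (sim.pos_tiers + sim.neg_tiers) for lab in tier
            )
            entries.append(
                DatabaseEntry(name, subclass, formula, mass, rt, adducts)
            )
            truth_rows.append(
                {
                    "name": name,
                    "subclass": subclass,
                    "nc": species.nc,
                    "db": species.db,
                    "ecn": species.nc - 2 * species.db,
                    "rt": rt,
                    "mass": mass,
                    "has_pos": bool(sim.pos_tiers),
                    "has_neg": bool(sim.neg_tiers),
                }
            )
    return entries, pd.DataFrame(truth_rows)


_BY_LABEL = {a.label: a for a in DEFAULT_REGISTRY}


def simulate_run(
    db: Sequence[DatabaseEntry],
    config: SimulationConfig,
    sample_id: str,
    polarity: str = "+",
    run_type: str = "sample",
    run_seed: Optional[int] = None,
) -> Tuple[MS1Run, pd.DataFrame]:
    """Emit one centroided MS1 run for a database, with ground truth.

    Sample runs contain the tiered adduct ions of every species whose
    subclass ionizes in ``polarity``, each with isotopologues M..M+2; blank
    runs contain only random background plus, in negative mode, the
    sodium-acetate cluster ladder.  Returns ``(run, truth)`` where truth has
    one row per emitted monoisotopic adduct ion.
    """
    if run_seed is None:
        run_seed = config.seed
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, run_seed, 1 if polarity == "+" else 2,
                                0 if run_type == "sample" else 1])
    )
    rows: List[Tuple[float, float, float]] = []
    truth_rows = []

    if run_type == "sample":
        for entry in db:
            sim = config.subclasses[entry.subclass]
            tiers = sim.pos_tiers if polarity == "+" else sim.neg_tiers
            if not tiers:
                continue
            base = config.base_area * math.exp(
                rng.normal(0.0, config.area_log_sigma)
            )
            rt_obs = entry.rt + rng.normal(0.0, config.rt_jitter_sigma)
            bias = config.ppm_bias.get(entry.subclass, 0.0)
            pattern = isotope_pattern(entry.formula, 2)
            for t_idx, tier in enumerate(tiers):
                ratio = config.tier_ratios[min(t_idx, len(config.tier_ratios) - 1)]
                for lab in tier:
                    if config.dropout_rate and rng.random() < config.dropout_rate:
                        continue
                    add = _BY_LABEL[lab]
                    inten = base * ratio * math.exp(
                        rng.normal(0.0, config.adduct_ratio_sigma)
                    )
                    theo = adduct_mz(entry.mass, add)
                    ppm = bias + rng.normal(0.0, config.ppm_sigma)
                    mz_obs = theo * (1.0 + ppm / 1e6)
                    for i, rel in enumerate(pattern):
                        rows.append(
                            (mz_obs + i * 1.0033548 / abs(add.z), rt_obs, inten * rel)
                        )
                    truth_rows.append(
                        {
                            "name": entry.name,
                            "subclass": entry.subclass,
                            "adduct": lab,
                            "tier": t_idx,
                            "theoretical_mz": theo,
                            "observed_mz": mz_obs,
                            "ppm": ppm,
                            "rt": rt_obs,
                            "area": inten,
                        }
                    )

    # background in every run; it is all a blank contains
    n_bg = config.n_background if run_type == "blank" else config.n_background // 3
    for _ in range(n_bg):
        rows.append(
            (
                float(rng.uniform(150.0, 1100.0)),
                float(rng.uniform(0.0, 19.0)),
                config.background_area * math.exp(rng.normal(0.0, 1.0)),
            )
        )
    if polarity == "-":
        # sodium-acetate cluster ladder anchored on the acetate anion
        acetate = 59.013304 + 0.000549  # CH3COO- with its extra electron
        for n in range(1, 7):
            for rt_anchor in np.arange(0.5, 19.0, 2.0):
                rows.append(
                    (
                        acetate + n * 82.003074,
                        float(rt_anchor),
                        config.background_area * 5.0 / n,
                    )
                )

    features = pd.DataFrame(rows, columns=["mz", "rt", "area"])
    run = MS1Run(sample_id, polarity, features, run_type)
    return run, pd.DataFrame(truth_rows)


def simulate_runs(
    db: Sequence[DatabaseEntry],
    config: SimulationConfig,
    n_samples: int = 3,
    n_blanks: int = 1,
    polarities: Sequence[str] = ("+", "-"),
) -> Tuple[List[MS1Run], pd.DataFrame]:
    """Simulate a batch: sample and blank runs in each polarity."""
    runs: List[MS1Run] = []
    truths = []
    for i in range(n_samples):
        for pol in polarities:
            run, truth = simulate_run(
                db, config, f"S{i + 1}", polarity=pol, run_seed=100 + i
            )
            truth["sample_id"] = run.sample_id
            runs.append(run)
            truths.append(truth)
    for i in range(n_blanks):
        for pol in polarities:
            run, _ = simulate_run(
                db, config, f"B{i + 1}", polarity=pol, run_type="blank",
                run_seed=900 + i,
            )
            runs.append(run)
    truth = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame()
    return runs, truth
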