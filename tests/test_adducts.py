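"""Adduct chemistry, co-elution grouping, consensus hierarchy, compliance."""

import itertools

import pytest

from lipidqa.adducts import (
    DEFAULT_REGISTRY,
    SODIUM_ACETATE,
    AdductDef,
    ConsensusSquantForm,
    SpeciesAdductProfile,
    adduct_mz,
    ahrl,
    build_cqualform,
    build_csquantform,
    check_compliance,
    expected_isf,
    group_coeluting_features,
    neutral_mass_from_mz,
    tg_neutral_loss_assign,
)
from lipidqa.chem import PROTON_MASS, compose_formula, monoisotopic_mass, parse_lipid_name

BY_LABEL = {a.label: a for a in DEFAULT_REGISTRY}


# ---------------------------------------------------------------- adduct m/z


def test_deprotonated_fa():
    m = monoisotopic_mass(compose_formula(parse_lipid_name("FA(20:4)")))
    assert m == pytest.approx(304.2402, abs=5e-4)
    assert adduct_mz(m, BY_LABEL["[M-H]-"]) == pytest.approx(303.2330, abs=5e-4)


def test_sodium_vs_proton_shift():
    for m in (300.0, 700.0, 900.0):
        delta = adduct_mz(m, BY_LABEL["[M+Na]+"]) - adduct_mz(m, BY_LABEL["[M+H]+"])
        assert delta == pytest.approx(21.9819, abs=5e-4)


def test_tg_ammonium_matches_printed_mz():
    m = monoisotopic_mass(compose_formula(parse_lipid_name("TG(52:2)")))
    mz = adduct_mz(m, BY_LABEL["[M+NH4]+"])
    assert abs(mz - 876.8028) / 876.8028 * 1e6 < 10  # within the 10 ppm bound


def test_proton_gap_between_polarities():
    for m in (200.0, 500.0, 1000.0):
        gap = adduct_mz(m, BY_LABEL["[M+H]+"]) - adduct_mz(m, BY_LABEL["[M-H]-"])
        assert gap == pytest.approx(2 * PROTON_MASS, abs=1e-6)


def test_sodium_acetate_ladder_spacing():
    assert round(monoisotopic_mass(SODIUM_ACETATE), 4) == 82.0031
    mzs = [
        adduct_mz(700.0, BY_LABEL[f"[M+CH3COO+{k}NaC2H3O2]-"]) for k in range(1, 7)
    ]
    for a, b in zip(mzs, mzs[1:]):
        assert round(b - a, 4) == 82.0031


def test_adduct_mz_input_guards():
    with pytest.raises(ValueError):
        adduct_mz(-1.0, BY_LABEL["[M+H]+"])
    with pytest.raises(ValueError):
        AdductDef("[M]+", "+", 0)


# ---------------------------------------------------------------- grouping


def _mz(m, label):
    return adduct_mz(m, BY_LABEL[label])


def test_grouping_pairs_h_and_na():
    m = 760.0
    feats = [(_mz(m, "[M+H]+"), 5.00, 100.0), (_mz(m, "[M+Na]+"), 5.02, 40.0)]
    profiles, ungrouped = group_coeluting_features(feats)
    assert len(profiles) == 1 and not ungrouped
    assert sorted(profiles[0].labels) == ["[M+H]+", "[M+Na]+"]
    assert profiles[0].neutral_mass_estimate == pytest.approx(m, abs=1e-3)


def test_grouping_respects_rt_tolerance():
    m = 760.0
    feats = [(_mz(m, "[M+H]+"), 5.00, 100.0), (_mz(m, "[M+Na]+"), 6.00, 40.0)]
    profiles, ungrouped = group_coeluting_features(feats, rt_tol=0.2)
    assert not profiles and len(ungrouped) == 2


def test_grouping_four_adducts_and_permutation_invariance():
    m = 858.76
    labels = ["[M+H]+", "[M+Na]+", "[M+K]+", "[M+NH4]+"]
    feats = [(_mz(m, lab), 14.50, inten) for lab, inten in zip(labels, (90, 50, 20, 100))]
    ref, _ = group_coeluting_features(feats)
    assert len(ref) == 1 and len(ref[0].observations) == 4
    for perm in itertools.permutations(feats):
        got, _ = group_coeluting_features(list(perm))
        assert [p.observations for p in got] == [p.observations for p in ref]


def test_grouping_requires_registry():
    with pytest.raises(ValueError):
        group_coeluting_features([(500.0, 1.0, 1.0)], registry=[])


# ---------------------------------------------------------------- consensus


def _profile(name, subclass, intensities, pol="+", rt=10.0):
    obs = [(lab, 500.0 + i, rt, inten) for i, (lab, inten) in enumerate(intensities.items())]
    return SpeciesAdductProfile(name, pol, obs, 500.0, subclass=subclass)


def test_cqualform_required_vs_optional():
    profiles = [
        _profile(f"PC{i}", "PC", {"[M+H]+": 100, "[M+Na]+": 30}) for i in range(8)
    ] + [
        _profile(f"PC{8 + i}", "PC", {"[M+H]+": 100, "[M+K]+": 5}) for i in range(2)
    ]
    forms = build_cqualform(profiles, min_presence=0.9)
    form = forms[("PC", "+")]
    assert "[M+H]+" in form.required
    assert "[M+Na]+" in form.optional and "[M+K]+" in form.optional


def test_single_adduct_profiles_rejected_at_admission():
    profiles = [_profile(f"X{i}", "PC", {"[M+H]+": 100}) for i in range(5)]
    with pytest.raises(ValueError):
        build_cqualform(profiles)


def test_csquantform_recovers_strict_order():
    profiles = [
        _profile(f"PC{i}", "PC", {"[M+H]+": 100 + i, "[M+Na]+": 30, "[M+K]+": 8})
        for i in range(10)
    ]
    form = build_csquantform(profiles)[("PC", "+")]
    assert form.tiers == [{"[M+H]+"}, {"[M+Na]+"}, {"[M+K]+"}]


def test_csquantform_merges_irreproducible_ranks():
    profiles = []
    for i in range(10):
        hi, lo = (60, 40) if i % 2 else (40, 60)  # Na/K swap half the time
        profiles.append(
            _profile(f"PC{i}", "PC", {"[M+H]+": 100, "[M+Na]+": hi, "[M+K]+": lo})
        )
    form = build_csquantform(profiles, support_threshold=0.8)
    tiers = form[("PC", "+")].tiers
    assert tiers[0] == {"[M+H]+"}
    assert tiers[1] == {"[M+Na]+", "[M+K]+"}


def test_ahrl_counts_consecutive_tiers():
    form = ConsensusSquantForm("PC", "+", [{"[M+H]+"}, {"[M+Na]+"}, {"[M+K]+"}], [1, 1, 1])
    full = _profile("a", "PC", {"[M+H]+": 9, "[M+Na]+": 5, "[M+K]+": 2})
    assert ahrl(full, form) == 3
    top_only = _profile("b", "PC", {"[M+H]+": 9})
    assert ahrl(top_only, form) == 1
    skip = _profile("c", "PC", {"[M+H]+": 9, "[M+K]+": 2})
    assert ahrl(skip, form) == 1
    tier2_only = _profile("d", "PC", {"[M+Na]+": 5})
    assert ahrl(tier2_only, form) == 0


def test_compliance_flags_potassium_over_sodium():
    """A lower-tier adduct outranking a higher-tier one is a violation."""
    clean = [
        _profile(f"TG{i}", "TG", {"[M+NH4]+": 100, "[M+Na]+": 30, "[M+K]+": 10})
        for i in range(10)
    ]
    qual = build_cqualform(clean)[("TG", "+")]
    squant = build_csquantform(clean)[("TG", "+")]
    bad = _profile("TGx", "TG", {"[M+NH4]+": 100, "[M+Na]+": 10, "[M+K]+": 10})
    rep = check_compliance(bad, qual, squant)
    assert not rep.hierarchy_pass
    assert ("[M+K]+", "[M+Na]+") in rep.hierarchy_violations
    ok = check_compliance(clean[0], qual, squant)
    assert ok.ok and not ok.hierarchy_violations


def test_compliance_flags_foreign_adduct():
    clean = [
        _profile(f"SM{i}", "SM", {"[M+H]+": 100, "[M+Na]+": 30}) for i in range(10)
    ]
    qual = build_cqualform(clean)[("SM", "+")]
    squant = build_csquantform(clean)[("SM", "+")]
    # SM-like candidate dominated by the ammonium-acetonitrile cluster
    suspect = _profile("SMx", "SM", {"[M+C2H7N2]+": 200, "[M+H]+": 100})
    rep = check_compliance(suspect, qual, squant)
    assert not rep.qual_pass
    assert rep.foreign_adducts == ["[M+C2H7N2]+"]


# ---------------------------------------------------------------- ISF


def test_expected_isf_rules():
    water = "[M+H-H2O]+"
    methyl = "[M-CH3]-"
    for subclass in ("LPC", "Cer", "HexCer", "DG", "Cholesterol"):
        assert water in {a.label for a in expected_isf(subclass)}
    for subclass in ("SM", "PC", "PC O/P", "LPC"):
        assert methyl in {a.label for a in expected_isf(subclass)}
    assert expected_isf("PI") == set()
    with pytest.raises(ValueError):
        expected_isf("NOPE")


# ---------------------------------------------------------------- TG NL


def test_tg_neutral_loss_worked_example():
    """One fragment explained by two co-eluting precursors is chimeric."""
    assignments, convoluted = tg_neutral_loss_assign(
        [("TG(52:2)", 876.8028), ("TG(50:1)", 850.7864)], [577.5196]
    )
    by_prec = {a.precursor: a for a in assignments}
    assert by_prec["TG(52:2)"].fa == "FA(18:1)"
    assert by_prec["TG(50:1)"].fa == "FA(16:0)"
    assert all(abs(a.ppm) <= 10 for a in assignments)
    assert all(a.chimeric for a in assignments)
    assert convoluted


def test_tg_neutral_loss_clean_spectrum():
    tg = parse_lipid_name("TG(48:0)")
    m = monoisotopic_mass(compose_formula(tg))
    prec = adduct_mz(m, BY_LABEL["[M+NH4]+"])
    fa16 = monoisotopic_mass(compose_formula(parse_lipid_name("FA(16:0)")))
    nh3 = 17.02655
    frag = prec - (fa16 + nh3)
    assignments, convoluted = tg_neutral_loss_assign([("TG(48:0)", prec)], [frag])
    assert assignments[0].fa == "FA(16:0)"
    assert not convoluted and not assignments[0].chimeric


def test_tg_neutral_loss_unassigned_and_empty():
    assignments, convoluted = tg_neutral_loss_assign([("TG(48:0)", 824.7702)], [300.0])
    assert assignments[0].fa is None and not convoluted
    with pytest.raises(ValueError):
        tg_neutral_loss_assign([], [500.0])
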