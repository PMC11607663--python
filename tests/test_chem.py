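"""Shorthand parsing, composition templates, masses, ECN and Kendrick."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pt_mass

from lipidqa.chem import (
    CH2,
    H2,
    AnnotationLevel,
    ElementalFormula,
    FormulaError,
    Linkage,
    LipidNameError,
    compose_formula,
    ecn,
    format_lipid_name,
    kendrick_quantities,
    monoisotopic_mass,
    parse_lipid_name,
)

# ---------------------------------------------------------------- formulas


def test_formula_parse_and_hill_roundtrip():
    f = ElementalFormula.parse("C42H82NO8P")
    assert f.counts == {"C": 42, "H": 82, "N": 1, "O": 8, "P": 1}
    assert f.hill() == "C42H82NO8P"


def test_formula_arithmetic_and_negative_guard():
    a = ElementalFormula.parse("C2H4O")
    b = ElementalFormula.parse("H2O")
    assert (a + b).hill() == "C2H6O2"
    assert (a - ElementalFormula.parse("CH2")).hill() == "CH2O"
    with pytest.raises(FormulaError):
        a - ElementalFormula.parse("N")


def test_mass_additivity_and_known_values():
    naac = ElementalFormula.parse("NaC2H3O2")
    assert round(monoisotopic_mass(naac), 4) == 82.0031
    assert round(monoisotopic_mass(ElementalFormula.parse("H2O")), 4) == 18.0106
    assert monoisotopic_mass(ElementalFormula({})) == 0.0
    a, b = ElementalFormula.parse("C5H5N5"), ElementalFormula.parse("NaK")
    assert monoisotopic_mass(a + b) == pytest.approx(
        monoisotopic_mass(a) + monoisotopic_mass(b), abs=1e-12
    )


@pytest.mark.parametrize(
    "formula",
    ["C42H82NO8P", "C55H102O6", "C20H32O2", "C27H46O", "NaC2H3O2", "C39H79N2O6P"],
)
def test_masses_agree_with_pyteomics(formula):
    """Vendored mass table cross-checked against an independent oracle."""
    ours = monoisotopic_mass(ElementalFormula.parse(formula))
    theirs = pt_mass.calculate_mass(formula=formula)
    assert ours == pytest.approx(theirs, abs=5e-4)


# ---------------------------------------------------------------- parsing


@pytest.mark.parametrize(
    "name,subclass,level,nc,db",
    [
        ("TG(48:0)", "TG", AnnotationLevel.SPECIES, 48, 0),
        ("TG(8:0_8:0_10:0)", "TG", AnnotationLevel.MOLECULAR_SPECIES, 26, 0),
        ("SM(d18:1/12:0)", "SM", AnnotationLevel.SN_POSITION, 30, 1),
        ("Cer(d42:2)", "Cer", AnnotationLevel.SPECIES, 42, 2),
        ("LPC(18:0/0:0)", "LPC", AnnotationLevel.SN_POSITION, 18, 0),
        ("PC(16:0/18:1)", "PC", AnnotationLevel.SN_POSITION, 34, 1),
        ("PC(O-34:1)", "PC O/P", AnnotationLevel.SPECIES, 34, 1),
        ("LPC(O-16:0)", "LPC O", AnnotationLevel.SPECIES, 16, 0),
        ("LPC(P-18:0)", "LPC O/P", AnnotationLevel.SPECIES, 18, 0),
        ("Cholesterol", "Cholesterol", AnnotationLevel.SPECIES, 0, 0),
    ],
)
def test_parse_examples(name, subclass, level, nc, db):
    sp = parse_lipid_name(name)
    assert sp.subclass == subclass
    assert sp.annotation_level is level
    assert sp.nc == nc and sp.db == db


def test_sm_sn_position_chains():
    sp = parse_lipid_name("SM(d18:1/12:0)")
    assert [(c.carbons, c.double_bonds) for c in sp.chains] == [(18, 1), (12, 0)]
    assert sp.chains[0].linkage is Linkage.SPHINGOID


@pytest.mark.parametrize(
    "bad",
    [
        "PC(0:0/0:0)",       # all-zero chains on a diacyl subclass
        "XX(16:0)",          # unknown subclass token
        "PC(16:0/18:x)",     # malformed C:D token
        "PC(d18:1/16:0)",    # sphingoid prefix on a glycerophospholipid
        "TG(16:0/18:1)",     # wrong chain count
        "PC(16:0/18:1_18:0)",  # mixed separators
        "SM(34:1)",          # sphingolipid without the d prefix
        "FA(2:4)",           # more double bonds than carbons
    ],
)
def test_parse_rejects_malformed(bad):
    with pytest.raises(LipidNameError):
        parse_lipid_name(bad)


_SPECIES_NAMES = st.sampled_from(
    ["FA", "CAR", "PC", "PE", "PI", "LPC", "LPE", "LPI", "DG", "TG", "CE"]
).flatmap(
    lambda head: st.tuples(
        st.integers(10, 60), st.integers(0, 5)
    ).map(lambda cd: f"{head}({cd[0]}:{cd[1]})")
)


@settings(max_examples=200, derandomize=True)
@given(_SPECIES_NAMES)
def test_format_parse_roundtrip(name):
    assert format_lipid_name(parse_lipid_name(name)) == name


def test_roundtrip_all_subclass_styles():
    for name in [
        "FA(18:2)", "CAR(12:0)", "Cer(d42:2)", "SM(d34:1)", "HexCer(d40:1)",
        "PC(34:2)", "PC(O-34:2)", "PE(36:4)", "PE(O-36:4)", "PI(38:4)",
        "LPC(18:0)", "LPC(O-16:0)", "LPC(P-18:0)", "LPE(18:1)", "LPE(O-18:1)",
        "LPI(18:0)", "DG(36:2)", "TG(52:2)", "CE(18:1)", "Cholesterol",
        "PC(16:0/18:1)", "PC(16:0_18:1)", "Cer(d18:1/24:0)",
    ]:
        assert format_lipid_name(parse_lipid_name(name)) == name


# ---------------------------------------------------------------- templates


@pytest.mark.parametrize(
    "name,expected",
    [
        ("PC(16:0/18:1)", "C42H82NO8P"),  # glycerophosphocholine + 2 acyl - 2 H2O
        ("TG(52:2)", "C55H102O6"),        # glycerol + 3 acyl - 3 H2O
        ("FA(20:4)", "C20H32O2"),
        ("SM(d18:1/16:0)", "C39H79N2O6P"),
        ("Cer(d18:1/16:0)", "C34H67NO3"),
        ("HexCer(d18:1/16:0)", "C40H77NO8"),
        ("LPC(16:0)", "C24H50NO7P"),
        ("LPE(18:1)", "C23H46NO7P"),
        ("PE(16:0/18:1)", "C39H76NO8P"),
        ("PI(16:0/18:1)", "C43H81O13P"),
        ("LPI(18:1)", "C27H51O12P"),
        ("DG(16:0/18:1)", "C37H70O5"),
        ("CE(18:1)", "C45H78O2"),
        ("CAR(16:0)", "C23H45NO4"),
        ("Cholesterol", "C27H46O"),
        ("PC(O-34:1)", "C42H84NO7P"),     # ether: -O +2H vs the diacyl form
        ("PC(P-34:1)", "C42H82NO7P"),     # plasmenyl: ether with one extra DBE
    ],
)
def test_composition_templates(name, expected):
    assert compose_formula(parse_lipid_name(name)).hill() == expected


@pytest.mark.parametrize("head", ["PC", "PE", "PI", "DG", "TG", "SM"])
def test_template_degree_consistency(head):
    """+1 carbon adds exactly CH2; +1 double bond removes exactly H2."""
    base = parse_lipid_name(f"{head}(d36:2)" if head == "SM" else f"{head}(36:2)")
    up_c = parse_lipid_name(f"{head}(d37:2)" if head == "SM" else f"{head}(37:2)")
    up_d = parse_lipid_name(f"{head}(d36:3)" if head == "SM" else f"{head}(36:3)")
    assert (compose_formula(up_c) - compose_formula(base)) == CH2
    assert (compose_formula(base) - compose_formula(up_d)) == H2


def test_cholesterol_rejects_chains():
    from lipidqa.chem import ChainSpec, LipidSpecies

    sp = LipidSpecies("Cholesterol", (ChainSpec(16, 0),), AnnotationLevel.SPECIES)
    with pytest.raises(FormulaError):
        compose_formula(sp)


# ---------------------------------------------------------------- ECN / KMD


@pytest.mark.parametrize(
    "name,expected",
    [("TG(48:0)", 48), ("TG(50:1)", 48), ("TG(52:2)", 48), ("TG(54:3)", 48),
     ("TG(58:5)", 48), ("PC(34:2)", 30), ("FA(20:4)", 12)],
)
def test_ecn(name, expected):
    assert ecn(parse_lipid_name(name)) == expected


def test_ecn_invariant_under_chain_redistribution():
    a = parse_lipid_name("PC(18:2_16:0)")
    b = parse_lipid_name("PC(18:1_16:1)")
    assert ecn(a) == ecn(b)


def test_kendrick_normalization_point_and_series():
    km, kmd = kendrick_quantities(monoisotopic_mass(CH2))
    assert km == pytest.approx(14.0, abs=1e-9)
    assert kmd == pytest.approx(0.0, abs=1e-9)
    # one CH2 apart -> identical KMD
    mz = 760.5851
    _, k1 = kendrick_quantities(mz)
    _, k2 = kendrick_quantities(mz + monoisotopic_mass(CH2))
    assert abs(k1 - k2) < 1e-9
    with pytest.raises(ValueError):
        kendrick_quantities(0.0)
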