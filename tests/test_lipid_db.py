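"""Database layer: naming grammar, formula assembly, exact masses, isotopes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import colipid as cl
from colipid.lipid_db import (
    CH2_MASS,
    ClassRange,
    DatabaseConfig,
    H2_MASS,
    LIPID_CLASSES,
    PROTON_MASS,
)

# independent monoisotopic mass table (CODATA/AME values, not the pyteomics path)
ATOM = {"C": 12.0, "H": 1.00782503207, "N": 14.0030740048, "O": 15.9949146196, "P": 30.97376163}


def oracle_mz(formula: cl.ElementalFormula) -> float:
    m = sum(ATOM[el] * getattr(formula, el) for el in ATOM)
    return m - PROTON_MASS


def oracle_isotope_ratio(n_carbons: int, k: int, p: float = 0.011) -> float:
    """Brute-force polynomial expansion of the n-carbon isotope distribution."""
    poly = np.array([1.0])
    for _ in range(n_carbons):
        poly = np.convolve(poly, [1.0 - p, p])
    return poly[k] / poly[0]


# ---------------------------------------------------------------------------
# naming

@pytest.mark.parametrize(
    "cls,c,db,cyc,expected",
    [
        ("PE", 33, 0, 1, "PE 33:0c1"),
        ("PE", 34, 1, 0, "PE 34:1"),
        ("aPG", 50, 2, 0, "aPG 50:2"),
        ("PBut", 33, 0, 1, "PBut 33:0c1"),
    ],
)
def test_build_species_name(cls, c, db, cyc, expected):
    assert cl.build_species_name(cls, cl.AcylComposition(c, db, cyc)) == expected


@pytest.mark.parametrize(
    "name,expected",
    [
        ("PG 35:0c1", ("PG", 35, 0, 1)),
        ("PE 32:1", ("PE", 32, 1, 0)),
        ("CDP-DAG 32:1", ("CDP-DAG", 32, 1, 0)),
    ],
)
def test_parse_species_name(name, expected):
    cls, comp = cl.parse_species_name(name)
    assert (cls, comp.total_carbons, comp.double_bonds, comp.cyclopropane_rings) == expected


@pytest.mark.parametrize("bad", ["XX 10:0", "PE 34", "PE34:1", "PE 34:1c", ""])
def test_parse_rejects_malformed_names(bad):
    with pytest.raises(ValueError):
        cl.parse_species_name(bad)


@settings(max_examples=200, derandomize=True)
@given(
    cls=st.sampled_from(sorted(LIPID_CLASSES)),
    c=st.integers(8, 80),
    db=st.integers(0, 2),
    cyc=st.integers(0, 2),
)
def test_name_round_trip(cls, c, db, cyc):
    comp = cl.AcylComposition(c, db, cyc)
    assert cl.parse_species_name(cl.build_species_name(cls, comp)) == (cls, comp)


# ---------------------------------------------------------------------------
# formulas and masses

def test_pe_34_1_formula_against_structural_oracle():
    # glycerophosphoethanolamine core C5H14NO6P + C34H66O4 acyls - 2 H2O
    f = cl.molecular_formula(LIPID_CLASSES["PE"], cl.AcylComposition(34, 1))
    assert f == cl.ElementalFormula.from_string("C39H76NO8P")


def test_cyclopropane_isobaric_with_double_bond():
    ring = cl.molecular_formula(LIPID_CLASSES["PE"], cl.AcylComposition(33, 0, 1))
    unsat = cl.molecular_formula(LIPID_CLASSES["PE"], cl.AcylComposition(33, 1, 0))
    assert ring == unsat
    assert cl.monoisotopic_mz(ring) == cl.monoisotopic_mz(unsat)


def test_pbut_is_butyl_ester_of_pa():
    pbut = cl.molecular_formula(LIPID_CLASSES["PBut"], cl.AcylComposition(32, 0))
    pa = cl.molecular_formula(LIPID_CLASSES["PA"], cl.AcylComposition(32, 0))
    assert pbut - pa == cl.ElementalFormula.from_string("C4H8")


@pytest.mark.parametrize(
    "cls,comp,formula",
    [
        # two structure-derived spot checks per diacyl class family
        ("PA", (32, 0, 0), "C35H69O8P"),
        ("PA", (34, 1, 0), "C37H71O8P"),
        ("PE", (32, 1, 0), "C37H72NO8P"),
        ("PG", (34, 1, 0), "C40H77O10P"),
        ("PS", (34, 1, 0), "C40H76NO10P"),
        ("PGP", (34, 1, 0), "C40H78O13P2"),
        ("CDP-DAG", (34, 1, 0), "C46H83N3O15P2"),
        ("CL", (72, 8, 0), "C81H142O17P2"),
        ("DLCL", (34, 1, 0), "C43H84O15P2"),
        ("aPE", (51, 1, 0), "C56H108NO9P"),
        ("aPG", (50, 2, 0), "C56H105O11P"),
        ("PBut", (33, 0, 1), "C40H77O8P"),
    ],
)
def test_backbone_spot_checks(cls, comp, formula):
    got = cl.molecular_formula(LIPID_CLASSES[cls], cl.AcylComposition(*comp))
    assert got == cl.ElementalFormula.from_string(formula)


def test_monoisotopic_mz_against_independent_oracle():
    f = cl.ElementalFormula.from_string("C39H76NO8P")
    mz = cl.monoisotopic_mz(f)
    assert abs(mz - 716.5236) < 1e-3
    assert abs(mz - oracle_mz(f)) < 1e-4


def test_mz_increments_exact_across_database(species):
    for (_, dbe), sub in species.groupby(["class", "dbe"]):
        sub = sub.sort_values("total_carbons")
        diffs = np.diff(sub["mz"].to_numpy())
        assert np.allclose(diffs, CH2_MASS, atol=1e-6)
    for (_, c), sub in species.groupby(["class", "total_carbons"]):
        sub = sub.sort_values("dbe")
        diffs = -np.diff(sub["mz"].to_numpy())
        assert np.allclose(diffs, H2_MASS, atol=1e-6)


def test_deprotonation_requires_hydrogen():
    with pytest.raises(ValueError):
        cl.monoisotopic_mz(cl.ElementalFormula(C=2, O=2))


# ---------------------------------------------------------------------------
# isotope model

def test_isotope_ratio_matches_brute_force(species):
    for f in species["formula"].unique():
        n = cl.ElementalFormula.from_string(f).C
        for k in (0, 1, 2):
            got = cl.isotope_ratio(cl.ElementalFormula(C=n, H=1), k)
            assert abs(got - oracle_isotope_ratio(n, k)) < 1e-6


def test_isotope_ratio_closed_forms():
    f = cl.ElementalFormula(C=39, H=76)
    assert cl.isotope_ratio(f, 0) == 1.0
    assert math.isclose(cl.isotope_ratio(f, 1), 39 * 0.011 / 0.989)
    assert math.isclose(cl.isotope_ratio(f, 2), math.comb(39, 2) * (0.011 / 0.989) ** 2)
    with pytest.raises(ValueError):
        cl.isotope_ratio(cl.ElementalFormula(C=1, H=4), 2)


# ---------------------------------------------------------------------------
# database generation

def test_pe_window_enumeration_count():
    cfg = DatabaseConfig(classes={"PE": ClassRange((30, 36))})
    db = cl.generate_database(cfg)
    # 7 carbons x 5 (db, ring) combos with db + ring <= 2
    assert len(db) == 35


def test_default_database_census(species):
    assert len(species) == 231
    assert species["class"].nunique() == 11
    assert species["mz"].between(350, 1750).all()
    for name in cl.REFERENCE_MARKER_PANEL.index:
        assert name in species.index


def test_database_deterministic(database):
    again = cl.generate_database()
    assert [s.name for s in database] == [s.name for s in again]
    assert [s.mz for s in database] == [s.mz for s in again]


def test_empty_config_warns():
    with pytest.warns(UserWarning):
        assert cl.generate_database(DatabaseConfig(classes={})) == []


def test_canonical_name_convention():
    assert cl.canonical_name("PE", 33, 1) == "PE 33:0c1"
    assert cl.canonical_name("PE", 34, 1) == "PE 34:1"
    assert cl.canonical_name("PE", 33, 0) == "PE 33:0"


def test_database_export_import_round_trip(tmp_path, database):
    for ext in ("csv", "json"):
        path = tmp_path / f"db.{ext}"
        cl.lipid_db.write_database(database, str(path))
        back = cl.lipid_db.read_database(str(path))
        assert [s.name for s in back] == [s.name for s in database]
        assert np.allclose([s.mz for s in back], [s.mz for s in database])
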