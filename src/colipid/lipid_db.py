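"""In-silico glycerophospholipid database for negative-mode HILIC lipidomics of E. coli.

Species are enumerated per lipid class as (total acyl carbons, double bonds,
cyclopropane rings) combinations on a fixed zero-acyl backbone, with exact
deprotonated monoisotopic masses and a carbon-only isotope model.

Cyclopropane rings are isobaric with double bonds, so a measured peak cannot
distinguish e.g. PE 33:1 from PE 33:0c1.  E. coli makes cyclopropane rings by
Cfa methylenation of a double bond in an even-carbon chain, producing an
odd-total-carbon species; the canonical naming convention here therefore
assigns the ``cN`` annotation to odd-carbon species and the plain double-bond
name to even-carbon species.
"""

from __future__ import annotations

import itertools
import json
import math
import re
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd
from pyteomics import mass as _ptmass

# ---------------------------------------------------------------------------
# constants

#: charge carrier removed on deprotonation ([M-H]-), u
PROTON_MASS = 1.00727646688

#: 13C - 12C mass difference, u
C13_DELTA = 1.0033548378

#: natural abundance of 13C used for de-isotoping
DEFAULT_C13_ABUNDANCE = 0.011

#: CH2 homolog spacing, u
CH2_MASS = 14.0156500642
#: H2 (one double-bond equivalent) spacing, u
H2_MASS = 2.0156500642

#: full-scan acquisition window of the ion trap, Th
DEFAULT_MASS_RANGE = (350.0, 1750.0)

_ELEMENTS = ("C", "H", "N", "O", "P")


# ---------------------------------------------------------------------------
# elemental formulas

@dataclass(frozen=True)
class ElementalFormula:
    """Elemental composition over C/H/N/O/P with simple arithmetic."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    P: int = 0

    def __post_init__(self):
        for el in _ELEMENTS:
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el} count in formula {self}")

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(**{el: getattr(self, el) + getattr(other, el) for el in _ELEMENTS})

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(**{el: getattr(self, el) - getattr(other, el) for el in _ELEMENTS})

    def __mul__(self, k: int) -> "ElementalFormula":
        return ElementalFormula(**{el: getattr(self, el) * k for el in _ELEMENTS})

    def hill(self) -> str:
        """Formula string in Hill order (C, H, then alphabetical)."""
        parts = []
        for el in ("C", "H", "N", "O", "P"):
            n = getattr(self, el)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)

    @classmethod
    def from_string(cls, s: str) -> "ElementalFormula":
        counts = dict.fromkeys(_ELEMENTS, 0)
        for el, num in re.findall(r"([A-Z][a-z]?)(\d*)", s):
            if not el:
                continue
            if el not in counts:
                raise ValueError(f"unsupported element {el!r} in formula {s!r}")
            counts[el] += int(num) if num else 1
        return cls(**counts)

    def mass(self) -> float:
        """Neutral monoisotopic mass, u."""
        return _ptmass.calculate_mass(formula=self.hill())


WATER = ElementalFormula(H=2, O=1)


# ---------------------------------------------------------------------------
# lipid classes

@dataclass(frozen=True)
class LipidClassDef:
    """A phospholipid class: zero-acyl backbone plus a number of acyl positions.

    ``backbone`` is the fully hydroxylated/aminated core (all acyl positions
    free); each acylation condenses a free fatty acid with loss of one water.
    ``rt_window`` is the class elution window on the HILIC gradient, minutes.
    """

    name: str
    n_chains: int
    backbone: ElementalFormula
    rt_window: tuple[float, float]
    charge: int = 1  # deprotonation charge state

    def __post_init__(self):
        lo, hi = self.rt_window
        if not (0 <= lo < hi):
            raise ValueError(f"invalid rt window for {self.name}: {self.rt_window}")

    @property
    def rt_center(self) -> float:
        return 0.5 * (self.rt_window[0] + self.rt_window[1])


def _f(s: str) -> ElementalFormula:
    return ElementalFormula.from_string(s)


# Backbones are the zero-acyl cores: e.g. PE -> glycerophosphoethanolamine
# C5H14NO6P, PG -> glycerophosphoglycerol C6H15O8P, CL/DLCL -> the
# bis(glycerophospho)glycerol core C9H22O13P2, CDP-DAG -> CDP-glycerol,
# PBut -> glycerophosphate butyl ester (PA backbone + C4H8).
# RT windows are artifact conventions for the ~5-min HILIC gradient; the class
# separation (headgroup chromatography) is what matters, not absolute values.
LIPID_CLASSES: dict[str, LipidClassDef] = {
    c.name: c
    for c in [
        LipidClassDef("PBut", 2, _f("C7H17O6P"), (0.30, 0.70)),
        LipidClassDef("PA", 2, _f("C3H9O6P"), (0.65, 1.05)),
        LipidClassDef("PG", 2, _f("C6H15O8P"), (1.00, 1.40)),
        LipidClassDef("aPG", 3, _f("C6H15O8P"), (1.35, 1.75)),
        LipidClassDef("CL", 4, _f("C9H22O13P2"), (1.70, 2.10)),
        LipidClassDef("DLCL", 2, _f("C9H22O13P2"), (2.05, 2.45)),
        LipidClassDef("PGP", 2, _f("C6H16O11P2"), (2.40, 2.80)),
        LipidClassDef("CDP-DAG", 2, _f("C12H21N3O13P2"), (2.75, 3.15)),
        LipidClassDef("PE", 2, _f("C5H14NO6P"), (3.10, 3.50)),
        LipidClassDef("aPE", 3, _f("C5H14NO6P"), (3.45, 3.85)),
        LipidClassDef("PS", 2, _f("C6H14NO8P"), (3.80, 4.20)),
    ]
}


def default_rt_windows() -> dict[str, tuple[float, float]]:
    """Per-class retention-time windows (minutes) used by annotator and simulator."""
    return {name: c.rt_window for name, c in LIPID_CLASSES.items()}


# ---------------------------------------------------------------------------
# acyl compositions and species

@dataclass(frozen=True)
class AcylComposition:
    """Summed acyl-chain descriptor: total carbons, double bonds, cyclopropane rings."""

    total_carbons: int
    double_bonds: int
    cyclopropane_rings: int = 0

    def __post_init__(self):
        if self.total_carbons < 2:
            raise ValueError("total_carbons must be >= 2")
        if self.double_bonds < 0:
            raise ValueError("double_bonds must be >= 0")
        if self.cyclopropane_rings not in (0, 1, 2):
            raise ValueError("cyclopropane_rings must be 0, 1 or 2")

    @property
    def dbe(self) -> int:
        """Degrees of flexibility lost to rings+double bonds (each costs 2 H)."""
        return self.double_bonds + self.cyclopropane_rings


@dataclass(frozen=True)
class LipidSpecies:
    class_def: LipidClassDef
    comp: AcylComposition
    name: str
    formula: ElementalFormula
    mz: float

    @property
    def class_name(self) -> str:
        return self.class_def.name


def build_species_name(class_name: str, comp: AcylComposition) -> str:
    """Canonical species-level name, e.g. ``PE 34:1`` or ``PE 33:0c1``."""
    if class_name not in LIPID_CLASSES:
        raise ValueError(f"unknown lipid class {class_name!r}")
    name = f"{class_name} {comp.total_carbons}:{comp.double_bonds}"
    if comp.cyclopropane_rings >= 1:
        name += f"c{comp.cyclopropane_rings}"
    return name


_NAME_RE = re.compile(r"^([A-Za-z][A-Za-z-]*) (\d+):(\d+)(?:c(\d+))?$")


def parse_species_name(name: str) -> tuple[str, AcylComposition]:
    """Inverse of :func:`build_species_name`."""
    m = _NAME_RE.match(name.strip())
    if not m:
        raise ValueError(f"malformed species name {name!r}")
    cls, c, db, cyc = m.groups()
    if cls not in LIPID_CLASSES:
        raise ValueError(f"unknown lipid class {cls!r} in {name!r}")
    return cls, AcylComposition(int(c), int(db), int(cyc) if cyc else 0)


def molecular_formula(class_def: LipidClassDef, comp: AcylComposition) -> ElementalFormula:
    """Neutral elemental formula of a species.

    Backbone + combined free fatty acids (C_C H_{2C-2(DB+c)} O_{2n}) minus one
    water per ester/amide linkage.  A cyclopropane ring costs two hydrogens,
    exactly like a double bond.
    """
    n = class_def.n_chains
    if comp.total_carbons < 2 * n:
        raise ValueError(
            f"{class_def.name} needs >= {2 * n} acyl carbons, got {comp.total_carbons}"
        )
    h = 2 * comp.total_carbons - 2 * comp.dbe
    if h <= 0:
        raise ValueError(f"too many double-bond equivalents for C{comp.total_carbons}")
    acyls = ElementalFormula(C=comp.total_carbons, H=h, O=2 * n)
    return class_def.backbone + acyls - WATER * n


def monoisotopic_mz(formula: ElementalFormula) -> float:
    """m/z of the deprotonated molecule [M-H]-, Th."""
    if formula.H < 1:
        raise ValueError("cannot deprotonate a formula without hydrogen")
    return formula.mass() - PROTON_MASS


def isotope_ratio(formula: ElementalFormula, k: int, p: float = DEFAULT_C13_ABUNDANCE) -> float:
    """Intensity of the A+k isotope peak relative to the monoisotopic peak.

    Carbon-only binomial model: ratio = C(n,k) (p/(1-p))^k with n carbons.
    Minor isotopes of H/N/O/P contribute <0.1% at A+2 for these formulas and
    are neglected.
    """
    if k < 0 or k > 2:
        raise ValueError("k must be 0, 1 or 2")
    n = formula.C
    if k > n:
        raise ValueError(f"A+{k} requires at least {k} carbons, formula has {n}")
    return math.comb(n, k) * (p / (1.0 - p)) ** k


# ---------------------------------------------------------------------------
# database generation

@dataclass(frozen=True)
class ClassRange:
    """Enumeration range for one class: carbons, double bonds, cyclopropane."""

    carbons: tuple[int, int]
    double_bonds: tuple[int, int] = (0, 2)
    cyclopropane: tuple[int, ...] = (0, 1)
    dbe_cap: int = 2  # max double_bonds + rings


@dataclass(frozen=True)
class DatabaseConfig:
    classes: dict[str, ClassRange] = field(default_factory=dict)
    mass_range: tuple[float, float] = DEFAULT_MASS_RANGE
    c13_abundance: float = DEFAULT_C13_ABUNDANCE


def default_database_config() -> DatabaseConfig:
    """Carbon ranges spanning the species observed in E. coli HILIC lipidomes.

    With the odd/even naming convention each class contributes
    3 x (number of carbon values) named species; the defaults give 231 names
    over the 11 classes.
    """
    return DatabaseConfig(
        classes={
            "PE": ClassRange((28, 40)),
            "PG": ClassRange((28, 40)),
            "PA": ClassRange((30, 34)),
            "PS": ClassRange((30, 34)),
            "PGP": ClassRange((30, 34)),
            "CDP-DAG": ClassRange((30, 34)),
            "CL": ClassRange((62, 70)),
            "DLCL": ClassRange((30, 33)),
            "aPE": ClassRange((46, 52)),
            "aPG": ClassRange((46, 52)),
            "PBut": ClassRange((31, 34)),
        }
    )


def generate_database(config: DatabaseConfig | None = None) -> list[LipidSpecies]:
    """Enumerate all species combinations, filter to the scan range, sort.

    Isobaric (C, d+1, c) / (C, d, c+1) pairs are kept as distinct entries
    sharing one formula and m/z; annotation collapses them by the odd/even
    carbon convention (see :func:`canonical_name`).
    """
    if config is None:
        config = default_database_config()
    if not config.classes:
        warnings.warn("empty database config: returning empty database")
        return []
    out: dict[tuple[str, AcylComposition], LipidSpecies] = {}
    lo_mz, hi_mz = config.mass_range
    for cls_name in sorted(config.classes):
        rng = config.classes[cls_name]
        class_def = LIPID_CLASSES[cls_name]
        c_lo, c_hi = rng.carbons
        d_lo, d_hi = rng.double_bonds
        for c, d, r in itertools.product(
            range(c_lo, c_hi + 1), range(d_lo, d_hi + 1), rng.cyclopropane
        ):
            if d + r > rng.dbe_cap:
                continue
            comp = AcylComposition(c, d, r)
            key = (cls_name, comp)
            if key in out:
                continue
            formula = molecular_formula(class_def, comp)
            mz = monoisotopic_mz(formula)
            if not (lo_mz <= mz <= hi_mz):
                continue
            out[key] = LipidSpecies(
                class_def, comp, build_species_name(cls_name, comp), formula, mz
            )
    return sorted(out.values(), key=lambda s: (s.class_name, s.mz, s.comp.cyclopropane_rings))


def canonical_name(class_name: str, total_carbons: int, dbe: int) -> str:
    """Collapse isobaric ring/double-bond annotations into one reported name.

    Odd-total-carbon species (Cfa products) are annotated with one
    cyclopropane ring; even-carbon species carry plain double bonds.
    """
    if total_carbons % 2 == 1 and dbe >= 1:
        return build_species_name(class_name, AcylComposition(total_carbons, dbe - 1, 1))
    return build_species_name(class_name, AcylComposition(total_carbons, dbe, 0))


def named_species_table(database: list[LipidSpecies]) -> pd.DataFrame:
    """Unique reported species (isobars collapsed) with formula and m/z.

    Index: canonical name.  Columns: class, total_carbons, double_bonds,
    cyclopropane, dbe, n_chains, formula, mz, rt_lo, rt_hi, rt_center.
    """
    rows = {}
    for sp in database:
        name = canonical_name(sp.class_name, sp.comp.total_carbons, sp.comp.dbe)
        if name in rows:
            continue
        cls, comp = parse_species_name(name)
        cd = sp.class_def
        rows[name] = {
            "class": cls,
            "total_carbons": comp.total_carbons,
            "double_bonds": comp.double_bonds,
            "cyclopropane": comp.cyclopropane_rings,
            "dbe": comp.dbe,
            "n_chains": cd.n_chains,
            "formula": sp.formula.hill(),
            "mz": sp.mz,
            "rt_lo": cd.rt_window[0],
            "rt_hi": cd.rt_window[1],
            "rt_center": cd.rt_center,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "name"
    return df.sort_values(["class", "mz"])


# ---------------------------------------------------------------------------
# export / import

def database_to_frame(database: list[LipidSpecies]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "class": [s.class_name for s in database],
            "name": [s.name for s in database],
            "total_carbons": [s.comp.total_carbons for s in database],
            "double_bonds": [s.comp.double_bonds for s in database],
            "cyclopropane": [s.comp.cyclopropane_rings for s in database],
            "formula": [s.formula.hill() for s in database],
            "mz": [s.mz for s in database],
        }
    )


def write_database(database: list[LipidSpecies], path: str) -> None:
    df = database_to_frame(database)
    if str(path).endswith(".json"):
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1)
    else:
        df.to_csv(path, index=False)


def read_database(path: str) -> list[LipidSpecies]:
    if str(path).endswith(".json"):
        with open(path) as fh:
            df = pd.DataFrame(json.load(fh))
    else:
        df = pd.read_csv(path)
    out = []
    for rec in df.itertuples(index=False):
        cls, comp = parse_species_name(rec.name)
        out.append(
            LipidSpecies(
                LIPID_CLASSES[cls], comp, rec.name,
                ElementalFormula.from_string(rec.formula), float(rec.mz),
            )
        )
    return out
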