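"""Synthetic study generator: ground-truth lipidomes, LC-MS feature tables and
OD600 growth curves with the statistical structure the analysis assumes.

The generator emulates a screen of the E. coli lipid-gene complement: 68
lipid-related genes, each overexpressed (OV) and, for the 48 non-essential
ones, knocked out (KO), grown in triplicate with and without 0.5% n-butanol,
with wild-type (WT) and empty-vector (EV) controls on every 96-well plate
(116 constructs, ~730 cultures).

Generative model (all parameters in :class:`StudyConfig`):

* one study-level baseline composition over the ~230 database species, drawn
  from a Dirichlet prior whose mean follows class weights x a per-class
  carbon-number profile, spread over ~4 orders of magnitude of abundance;
* construct effects as multiplicative log-normal factors on gene-specific
  target species; ten designated "hub" marker species are targeted by many
  genes and carry most of the between-construct variance;
* mechanistic effects for selected genes (cfa ring synthesis, fabH chain
  initiation, clsA/clsB cardiolipin metabolism, aas/pldA headgroup acylation);
* butanol effects: growth-rate halving, partial cyclopropane-to-double-bond
  shift, and phosphatidylbutanol (PBut) formation, strongly amplified in the
  ClsB overexpressor;
* measurement layer: per-species log-normal intensity noise, m/z and rt
  jitter, 13C isotope peaks (A+1, A+2), decoy noise features, and a detection
  limit below which feature cells are censored;
* logistic growth curves on a 5-min grid with multiplicative reading noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lipid_db import (
    canonical_name,
    default_database_config,
    ElementalFormula,
    generate_database,
    isotope_ratio,
    named_species_table,
)

# 20 genes essential in the deletion collection (overexpression only) and 48
# non-essential ones (overexpression and knock-out): 116 constructs.
ESSENTIAL_GENES = [
    "accA", "accB", "accC", "accD", "fabA", "fabB", "fabD", "fabG", "fabI",
    "fabZ", "plsB", "plsC", "plsX", "plsY", "pssA", "psd", "pgsA", "cdsA",
    "gpsA", "lgt",
]
NONESSENTIAL_GENES = [
    "cfa", "clsA", "clsB", "clsC", "pldA", "pldB", "pldC", "aas", "aes",
    "tesA", "tesB", "ybgC", "fadA", "fadB", "fadD", "fadE", "fadI", "fadJ",
    "fadL", "fadM", "fadR", "fabF", "fabH", "fabR", "pgpA", "pgpB", "pgpC",
    "dgkA", "dgkB", "glpA", "glpB", "glpC", "glpD", "glpE", "glpF", "glpG",
    "glpK", "glpQ", "glpR", "glpT", "glpX", "ugpQ", "cdh", "eptA", "eptB",
    "pagP", "lpxT", "mdoB",
]

#: species carrying the planted between-construct signal (marker ground truth)
DEFAULT_MARKER_SPECIES = [
    "PE 32:1", "PE 33:0c1", "PE 36:2", "PG 35:0c1", "PG 31:0c1",
    "aPG 50:2", "aPE 49:0c1", "aPG 49:1c1", "CL 66:2", "PBut 33:0c1",
]

_CLASS_WEIGHTS = {
    "PE": 40.0, "PG": 25.0, "CL": 8.0, "PA": 3.0, "aPE": 1.5, "aPG": 1.5,
    "PS": 0.8, "CDP-DAG": 0.8, "PGP": 0.5, "DLCL": 0.3, "PBut": 0.0,
}
_CLASS_C_MODE = {
    "PE": 33, "PG": 33, "PA": 32, "PS": 32, "PGP": 32, "CDP-DAG": 32,
    "CL": 66, "DLCL": 31, "aPE": 49, "aPG": 49, "PBut": 33,
}
_DBE_WEIGHTS = (0.35, 0.40, 0.25)


@dataclass(frozen=True)
class StudyConfig:
    """Study design and generative parameters; the defaults are the emulated
    study conditions."""

    seed: int
    replicates: int = 3
    butanol_arm: bool = True
    controls_per_plate: int = 2          # WT wells and EV wells per plate
    plate_capacity: int = 96

    # baseline composition
    baseline_concentration: float = 5000.0  # Dirichlet precision
    baseline_spread_sd: float = 1.0         # log-normal spread of the prior mean

    # construct effect model
    marker_species: tuple = tuple(DEFAULT_MARKER_SPECIES)
    hub_targets_per_gene: int = 2
    other_targets_per_gene: int = 4
    hub_effect_sd: float = 0.8           # log-scale
    other_effect_sd: float = 0.4
    replicate_sd: float = 0.05           # biological replicate log-noise
    mechanistic_effects: bool = True     # cfa/fabH/clsA/clsB/aas/pldA overlays

    # butanol composition effects
    cyclopropane_retention: float = 0.6  # fraction of ring species kept under butanol
    pbut_fraction_clsb_ov: float = 3.0   # percent of signal, ClsB OV + butanol
    pbut_background: float = 0.05        # percent, any strain + butanol

    # mechanistic gene effects
    cfa_ko_retention: float = 0.05       # ring species kept in the cfa knock-out
    cfa_ov_conversion: float = 0.8       # precursor fraction converted on overexpression
    fabh_chain_shift: float = 0.7        # log-multiplier per carbon-per-chain deviation
    fabh_unsat_shift: float = 0.9        # log-multiplier per double-bond-per-chain deviation

    # measurement layer
    total_signal: float = 1e6
    total_signal_cv: float = 0.1
    intensity_cv: float = 0.05
    mz_jitter_sd: float = 0.01           # Th
    rt_jitter_sd: float = 0.03           # min
    decoy_rate: float = 0.1              # decoys per species feature row
    decoy_median: float = 20.0
    detection_limit: float = 50.0

    # growth layer
    mu_base: float = 1.0                 # h^-1, control condition
    mu_construct_sd: float = 0.03
    butanol_mu_factor: float = 0.5       # 50% growth inhibition at 0.5% butanol
    k_base: float = 1.0                  # carrying capacity, OD600
    k_construct_sd: float = 0.08
    butanol_k_factor: float = 0.85
    od0: float = 0.02                    # 1:100 dilution of a stationary culture
    od_noise: float = 0.01
    duration_h: float = 16.0
    interval_min: float = 5.0
    replicate_mu_sd: float = 0.02
    replicate_k_sd: float = 0.02
    growth_failure_rate: float = 0.0
    n_growth_effect_constructs: int = 42
    growth_effect_min: float = 0.15
    growth_effect_max: float = 0.5

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class SyntheticStudy:
    """Generated study: observed tables plus the ground-truth ledger."""

    config: StudyConfig
    species: pd.DataFrame                # named-species database table
    metadata: pd.DataFrame               # sample_id -> gene, construct_type, butanol, plate, replicate
    truth_compositions: pd.DataFrame     # species x samples, percent (pre-measurement)
    features: pd.DataFrame               # censored feature table (mz, rt, samples)
    features_raw: pd.DataFrame           # uncensored re-integration table
    od: pd.DataFrame                     # time_min + one column per sample
    truth: dict                          # baseline, markers, effects, mu/K, failures


# ---------------------------------------------------------------------------
# composition model

def _baseline_composition(species: pd.DataFrame, config: StudyConfig, rng) -> pd.Series:
    """One study-level baseline percent composition (PBut absent)."""
    cls = species["class"]
    w = (
        cls.map(_CLASS_WEIGHTS).to_numpy()
        * np.exp(-0.5 * ((species["total_carbons"] - cls.map(_CLASS_C_MODE)) / 1.8) ** 2).to_numpy()
        * np.array([_DBE_WEIGHTS[min(d, 2)] for d in species["dbe"]])
    )
    w = w * rng.lognormal(0.0, config.baseline_spread_sd, size=len(w))
    live = w > 0
    alpha = config.baseline_concentration * w[live] / w[live].sum()
    comp = np.zeros(len(w))
    comp[live] = rng.dirichlet(np.clip(alpha, 1e-3, None))
    return pd.Series(100.0 * comp, index=species.index)


def _ring_maps(species: pd.DataFrame):
    """Canonical-name maps for the Cfa reaction: precursor <-> ring product."""
    names = set(species.index)
    prec_of, prod_of = {}, {}
    for name, row in species.iterrows():
        if row["cyclopropane"] >= 1:
            p = canonical_name(row["class"], row["total_carbons"] - 1, row["dbe"])
            if p in names:
                prec_of[name] = p
        elif row["double_bonds"] >= 1:
            q = canonical_name(row["class"], row["total_carbons"] + 1, row["dbe"])
            if q in names:
                prod_of[name] = q
    return prec_of, prod_of


def _shift_mass(comp: pd.Series, mapping: dict, fraction: float) -> pd.Series:
    """Move ``fraction`` of each source species' abundance to its mapped target."""
    out = comp.copy()
    for src, dst in mapping.items():
        moved = comp[src] * fraction
        out[src] -= moved
        out[dst] += moved
    return out


class _EffectModel:
    """Study-level state: baseline, per-construct multipliers, growth truth."""

    def __init__(self, species: pd.DataFrame, config: StudyConfig, rng):
        self.species = species
        self.config = config
        self.baseline = _baseline_composition(species, config, rng)
        self.prec_of, self.prod_of = _ring_maps(species)
        self.pbut_weights = self._pbut_profile()
        hubs = [m for m in config.marker_species if species.loc[m, "class"] != "PBut"]
        non_hubs = [s for s in species.index
                    if s not in config.marker_species and species.loc[s, "class"] != "PBut"]
        self.gene_targets: dict[str, list] = {}
        self.construct_lfc: dict[tuple[str, str], pd.Series] = {}
        genes = ESSENTIAL_GENES + NONESSENTIAL_GENES
        for gene in genes:
            t_hub = list(rng.choice(hubs, size=config.hub_targets_per_gene, replace=False))
            t_other = list(rng.choice(non_hubs, size=config.other_targets_per_gene, replace=False))
            self.gene_targets[gene] = t_hub + t_other
            lfc = pd.Series(0.0, index=species.index)
            lfc[t_hub] = rng.normal(0.0, config.hub_effect_sd, size=len(t_hub))
            lfc[t_other] = rng.normal(0.0, config.other_effect_sd, size=len(t_other))
            self.construct_lfc[(gene, "OV")] = lfc
            if gene in NONESSENTIAL_GENES:
                self.construct_lfc[(gene, "KO")] = -lfc
        if config.mechanistic_effects:
            self._add_mechanistic(rng)
        self._growth_truth(rng)

    def _pbut_profile(self) -> pd.Series:
        sub = self.species[self.species["class"] == "PBut"]
        w = np.exp(-0.5 * ((sub["total_carbons"] - 33) / 1.0) ** 2) * [
            _DBE_WEIGHTS[min(d, 2)] for d in sub["dbe"]
        ]
        return pd.Series(w / w.sum(), index=sub.index)

    def _add_mechanistic(self, rng):
        sp = self.species
        cl = sp.index[sp["class"] == "CL"]
        acy = sp.index[sp["class"].isin(["aPE", "aPG"])]
        apg = sp.index[sp["class"] == "aPG"]
        for gene, targets, lfc_ov in [
            ("clsA", cl, np.log(2.5)),
            ("aas", acy, np.log(3.0)),
            ("pldA", apg, np.log(2.0)),
            ("clsB", cl, np.log(1.3)),
        ]:
            self.construct_lfc[(gene, "OV")][targets] += lfc_ov
            if gene in NONESSENTIAL_GENES and (gene, "KO") in self.construct_lfc:
                self.construct_lfc[(gene, "KO")][targets] -= lfc_ov
        # fabH: expression level shifts chain length and unsaturation
        chains = sp["n_chains"].to_numpy(float)
        c_per = sp["total_carbons"].to_numpy(float) / chains
        d_per = sp["double_bonds"].to_numpy(float) / chains
        dev = (c_per - np.average(c_per, weights=self.baseline)) * self.config.fabh_chain_shift
        dev += (d_per - np.average(d_per, weights=self.baseline)) * self.config.fabh_unsat_shift
        fabh = pd.Series(dev, index=sp.index)
        self.construct_lfc[("fabH", "OV")] -= fabh
        self.construct_lfc[("fabH", "KO")] += fabh
        # glycerol-metabolism genes act on growth, not on the lipidome
        for gene in ("glpD", "glpK", "glpR"):
            for ct in ("OV", "KO"):
                if (gene, ct) in self.construct_lfc:
                    self.construct_lfc[(gene, ct)][:] = 0.0

    def _growth_truth(self, rng):
        cfg = self.config
        constructs = list(self.construct_lfc.keys()) + [("WT", "WT"), ("EV", "EV")]
        self.mu_mult = {c: float(rng.lognormal(0.0, cfg.mu_construct_sd)) for c in constructs}
        self.k_mult = {c: float(rng.lognormal(0.0, cfg.k_construct_sd)) for c in constructs}
        self.mu_mult[("WT", "WT")] = self.mu_mult[("EV", "EV")] = 1.0
        self.k_mult[("WT", "WT")] = self.k_mult[("EV", "EV")] = 1.0
        curated = {
            ("glpK", "OV"): 1.5, ("glpR", "KO"): 1.3,
            ("glpD", "KO"): 0.6, ("glpD", "OV"): 0.65,
        }
        pool = [c for c in self.construct_lfc if c not in curated]
        extra = cfg.n_growth_effect_constructs - len(curated)
        idx = rng.choice(len(pool), size=max(extra, 0), replace=False)
        effects = dict(curated)
        for i in idx:
            size = rng.uniform(cfg.growth_effect_min, cfg.growth_effect_max)
            effects[pool[i]] = float(1.0 + np.sign(rng.normal()) * size)
        for c, f in effects.items():
            self.mu_mult[c] *= f
            self.k_mult[c] *= min(max(f, 0.7), 1.3)
        self.growth_effect_constructs = effects

    # ---- per-sample draws ---------------------------------------------

    def composition(self, gene: str, ctype: str, butanol: bool, rng) -> pd.Series:
        cfg = self.config
        comp = self.baseline.copy()
        if ctype in ("KO", "OV"):
            comp = comp * np.exp(self.construct_lfc[(gene, ctype)])
            if gene == "cfa" and cfg.mechanistic_effects:
                if ctype == "KO":
                    # no ring synthesis: ring species collapse onto precursors
                    comp = _shift_mass(comp, self.prec_of, 1.0 - cfg.cfa_ko_retention)
                else:
                    comp = _shift_mass(comp, self.prod_of, cfg.cfa_ov_conversion)
        if butanol:
            comp = _shift_mass(comp, self.prec_of, 1.0 - cfg.cyclopropane_retention)
        comp = comp * rng.lognormal(0.0, cfg.replicate_sd, size=len(comp))
        comp = 100.0 * comp / comp.sum()
        if butanol:
            pbut = cfg.pbut_background
            if gene == "clsB" and ctype == "OV":
                pbut += cfg.pbut_fraction_clsb_ov
            pbut *= float(rng.lognormal(0.0, cfg.replicate_sd))
            comp *= (100.0 - pbut) / 100.0
            comp += self.pbut_weights.reindex(comp.index, fill_value=0.0) * pbut
        return comp


def simulate_lipidome(effects: _EffectModel, gene: str, ctype: str, butanol: bool, rng) -> pd.Series:
    """True percent composition of one culture (sums to 100)."""
    return effects.composition(gene, ctype, butanol, rng)


# ---------------------------------------------------------------------------
# measurement layer

def simulate_feature_table(
    compositions: pd.DataFrame,
    species: pd.DataFrame,
    config: StudyConfig,
    rng,
    isotopes: bool = True,
    noise: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit (censored, raw) mz/rt feature tables for true compositions.

    Each species produces a monoisotopic feature row plus A+1 and A+2 isotope
    rows scaled by the carbon binomial model; decoy noise features are
    appended; cells below the detection limit are censored to NaN in the
    first table and kept in the second.
    """
    samples = list(compositions.columns)
    n_s = len(samples)
    sp = species.loc[compositions.index]
    totals = config.total_signal * (
        rng.lognormal(0.0, config.total_signal_cv, size=n_s) if noise else np.ones(n_s)
    )
    base = compositions.to_numpy(float) / 100.0 * totals[None, :]
    if noise:
        base = base * rng.lognormal(0.0, config.intensity_cv, size=base.shape)
    rows, data = [], []
    r1 = np.array([isotope_ratio(ElementalFormula.from_string(f), 1) for f in sp["formula"]])
    r2 = np.array([isotope_ratio(ElementalFormula.from_string(f), 2) for f in sp["formula"]])
    jitter = (lambda sd, size: rng.normal(0.0, sd, size=size)) if noise else (
        lambda sd, size: np.zeros(size)
    )
    mz = sp["mz"].to_numpy()
    rt = sp["rt_center"].to_numpy()
    peaks = [(0.0, np.ones(len(sp)))]
    if isotopes:
        peaks += [(1.0033548378, r1), (2.0067096756, r2)]
    for delta, ratio in peaks:
        rows.append(
            pd.DataFrame(
                {
                    "mz": mz + delta + jitter(config.mz_jitter_sd, len(sp)),
                    "rt": rt + jitter(config.rt_jitter_sd, len(sp)),
                }
            )
        )
        data.append(base * ratio[:, None])
    n_decoy = int(rng.poisson(config.decoy_rate * len(sp) * len(peaks))) if noise else 0
    if n_decoy:
        rows.append(
            pd.DataFrame(
                {
                    "mz": rng.uniform(350.0, 1750.0, size=n_decoy),
                    "rt": rng.uniform(0.0, 4.5, size=n_decoy),
                }
            )
        )
        data.append(rng.lognormal(np.log(config.decoy_median), 1.0, size=(n_decoy, n_s)))
    table = pd.concat(rows, ignore_index=True)
    values = np.vstack(data)
    raw = pd.concat([table, pd.DataFrame(values, columns=samples)], axis=1)
    censored = raw.copy()
    if noise:  # detection censoring is part of the measurement model
        cens_vals = censored[samples].to_numpy()
        cens_vals[cens_vals < config.detection_limit] = np.nan
        censored[samples] = cens_vals
    return censored, raw


# ---------------------------------------------------------------------------
# growth layer

def logistic_od(t_h: np.ndarray, mu: float, K: float, od0: float) -> np.ndarray:
    e = np.exp(mu * t_h)
    return K * od0 * e / (K + od0 * (e - 1.0))


def simulate_growth_curve(
    mu: float,
    K: float,
    od0: float,
    butanol: bool,
    config: StudyConfig,
    rng,
    noise: bool | None = None,
) -> pd.DataFrame:
    """One logistic OD600 curve on the configured grid (butanol halves mu)."""
    if not (mu > 0 and K > od0 > 0):
        raise ValueError("need mu > 0 and K > od0 > 0")
    if butanol:
        mu = mu * config.butanol_mu_factor
    t_min = np.arange(0.0, config.duration_h * 60.0 + config.interval_min, config.interval_min)
    od = logistic_od(t_min / 60.0, mu, K, od0)
    if noise is None:
        noise = config.od_noise > 0
    if noise:
        od = od * rng.lognormal(0.0, config.od_noise, size=od.shape)
    return pd.DataFrame({"time_min": t_min, "od": od})


# ---------------------------------------------------------------------------
# full study

def _design(config: StudyConfig) -> pd.DataFrame:
    """Sample sheet: constructs in triplicate plus plate-level controls."""
    constructs = [(g, "OV") for g in ESSENTIAL_GENES + NONESSENTIAL_GENES]
    constructs += [(g, "KO") for g in NONESSENTIAL_GENES]
    conditions = [0, 1] if config.butanol_arm else [0]
    rows = []
    for butanol in conditions:
        wells = [(g, t, r) for g, t in constructs for r in range(config.replicates)]
        per_plate = config.plate_capacity - 2 * config.controls_per_plate
        n_plates = int(np.ceil(len(wells) / per_plate))
        for p in range(n_plates):
            chunk = wells[p * per_plate : (p + 1) * per_plate]
            plate = f"P{butanol}{p + 1}"
            for g, t, r in chunk:
                rows.append((g, t, butanol, plate, r))
            for r in range(config.controls_per_plate):
                rows.append(("WT", "WT", butanol, plate, r))
                rows.append(("EV", "EV", butanol, plate, r))
    meta = pd.DataFrame(rows, columns=["gene", "construct_type", "butanol", "plate", "replicate"])
    meta.index = pd.Index([f"S{i + 1:04d}" for i in range(len(meta))], name="sample_id")
    return meta


def simulate_study(config: StudyConfig) -> SyntheticStudy:
    """Assemble metadata, true compositions, feature tables, OD curves and the
    ground-truth ledger; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    species = named_species_table(generate_database(default_database_config()))
    effects = _EffectModel(species, config, rng)
    meta = _design(config)

    comps = {}
    mu_true, k_true, failed = {}, {}, []
    curves = {}
    t_min = None
    cfg = config
    for sid, row in meta.iterrows():
        comps[sid] = effects.composition(
            row["gene"], row["construct_type"], bool(row["butanol"]), rng
        )
        key = (row["gene"], row["construct_type"])
        mu = cfg.mu_base * effects.mu_mult[key] * float(rng.lognormal(0.0, cfg.replicate_mu_sd))
        K = cfg.k_base * effects.k_mult[key] * float(rng.lognormal(0.0, cfg.replicate_k_sd))
        if row["butanol"]:
            mu *= cfg.butanol_mu_factor
            K *= cfg.butanol_k_factor
        if cfg.growth_failure_rate > 0 and rng.uniform() < cfg.growth_failure_rate:
            K = float(rng.uniform(0.05, 0.15))
            failed.append(sid)
        mu_true[sid], k_true[sid] = mu, K
        t_min = np.arange(0.0, cfg.duration_h * 60.0 + cfg.interval_min, cfg.interval_min)
        od_curve = logistic_od(t_min / 60.0, mu, K, cfg.od0)
        if cfg.od_noise > 0:
            od_curve = od_curve * rng.lognormal(0.0, cfg.od_noise, size=od_curve.shape)
        curves[sid] = od_curve

    truth_comp = pd.DataFrame(comps)
    features, features_raw = simulate_feature_table(truth_comp, species, cfg, rng)
    od = pd.DataFrame({"time_min": t_min} | {sid: curves[sid] for sid in meta.index})
    truth = {
        "baseline": effects.baseline,
        "marker_species": list(cfg.marker_species),
        "gene_targets": effects.gene_targets,
        "mu": pd.Series(mu_true, name="mu_true"),
        "K": pd.Series(k_true, name="K_true"),
        "growth_effect_constructs": effects.growth_effect_constructs,
        "growth_failures": failed,
        "construct_lfc": effects.construct_lfc,
    }
    return SyntheticStudy(cfg, species, meta, truth_comp, features, features_raw, od, truth)
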