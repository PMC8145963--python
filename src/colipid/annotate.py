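"""Feature annotation: m/z-rt matching, de-isotoping, filtering, normalization.

Turns an upstream mz/rt feature table (one intensity column per sample) into a
species-level lipidome matrix expressed as percent of total lipid signal per
sample.  Matching uses the in-silico database of :mod:`colipid.lipid_db`:
retention time identifies the lipid class (HILIC headgroup separation) and the
deprotonated exact mass identifies the species within the class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lipid_db import (
    C13_DELTA,
    DEFAULT_C13_ABUNDANCE,
    ElementalFormula,
    LipidSpecies,
    isotope_ratio,
    named_species_table,
)

DEFAULT_MZ_TOLERANCE = 0.3  # Th; unit-resolution ion trap


@dataclass
class AnnotatedLipidome:
    """Species x samples lipidome with provenance and processing log.

    ``abundance`` holds raw summed intensities until :func:`normalize` is
    applied, then percent-of-total values.  ``provenance`` flags each cell as
    ``detected`` or ``force_integrated``.
    """

    abundance: pd.DataFrame                  # species x samples
    species: pd.DataFrame                    # named-species info (lipid_db schema)
    provenance: pd.DataFrame                 # species x samples, str
    unmatched: pd.DataFrame                  # leftover feature rows
    metadata: pd.DataFrame | None = None     # per-sample (gene, construct_type, butanol, plate)
    normalized: bool = False
    dropped_samples: list = field(default_factory=list)
    log: list = field(default_factory=list)

    @property
    def sample_ids(self) -> list:
        return list(self.abundance.columns)

    def copy(self) -> "AnnotatedLipidome":
        return AnnotatedLipidome(
            self.abundance.copy(), self.species, self.provenance.copy(),
            self.unmatched, self.metadata, self.normalized,
            list(self.dropped_samples), list(self.log),
        )


def _feature_columns(table: pd.DataFrame) -> list:
    missing = {"mz", "rt"} - set(table.columns)
    if missing:
        raise ValueError(f"feature table lacks required columns: {sorted(missing)}")
    return [c for c in table.columns if c not in ("mz", "rt")]


def _assign_classes(rt: np.ndarray, species: pd.DataFrame, log: list) -> np.ndarray:
    """Class label per feature from rt windows; overlaps resolved by nearest center."""
    classes = species[["class", "rt_lo", "rt_hi", "rt_center"]].drop_duplicates("class")
    out = np.full(rt.shape, None, dtype=object)
    best = np.full(rt.shape, np.inf)
    hits = np.zeros(rt.shape, dtype=int)
    for _, row in classes.iterrows():
        inside = (rt >= row["rt_lo"]) & (rt <= row["rt_hi"])
        hits += inside
        dist = np.abs(rt - row["rt_center"])
        take = inside & (dist < best)
        out[take] = row["class"]
        best[take] = dist[take]
    n_ambig = int((hits > 1).sum())
    if n_ambig:
        log.append(f"{n_ambig} features fell in overlapping rt windows; nearest window center used")
    return out


def match_features(
    table: pd.DataFrame,
    database: list[LipidSpecies] | pd.DataFrame,
    mz_tolerance: float = DEFAULT_MZ_TOLERANCE,
    metadata: pd.DataFrame | None = None,
) -> AnnotatedLipidome:
    """Assign mz/rt features to database species; sum multiply-matched features.

    A feature is assigned to the species of its rt-determined class whose m/z
    is nearest, provided |delta mz| <= tolerance.  Isobaric ring/double-bond
    entries are collapsed to the canonical (odd/even carbon) name beforehand,
    so a feature never matches two species of one class.  Matching is
    independent of feature-table row order.
    """
    if mz_tolerance <= 0:
        raise ValueError("mz_tolerance must be positive")
    species = database if isinstance(database, pd.DataFrame) else named_species_table(database)
    log: list = []
    samples = _feature_columns(table)
    mz = table["mz"].to_numpy(float)
    rt = table["rt"].to_numpy(float)
    feat_class = _assign_classes(rt, species, log)

    assigned = np.full(mz.shape, None, dtype=object)
    for cls, sub in species.groupby("class", sort=True):
        sub = sub.sort_values("mz")
        smz = sub["mz"].to_numpy()
        mask = feat_class == cls
        if not mask.any():
            continue
        idx = np.searchsorted(smz, mz[mask])
        idx_lo = np.clip(idx - 1, 0, len(smz) - 1)
        idx_hi = np.clip(idx, 0, len(smz) - 1)
        d_lo = np.abs(mz[mask] - smz[idx_lo])
        d_hi = np.abs(mz[mask] - smz[idx_hi])
        nearest = np.where(d_lo <= d_hi, idx_lo, idx_hi)
        dist = np.minimum(d_lo, d_hi)
        names = sub.index.to_numpy()[nearest]
        names = np.where(dist <= mz_tolerance, names, None)
        assigned[mask] = names

    matched = assigned != None  # noqa: E711
    intens = table[samples].to_numpy(float)
    values = np.nan_to_num(intens, nan=0.0)
    detected = ~np.isnan(intens)

    abundance = pd.DataFrame(0.0, index=species.index, columns=samples)
    seen = pd.DataFrame(False, index=species.index, columns=samples)
    if matched.any():
        agg = pd.DataFrame(values[matched], columns=samples)
        agg["__sp"] = assigned[matched]
        sums = agg.groupby("__sp").sum()
        abundance.loc[sums.index, :] += sums
        det = pd.DataFrame(detected[matched], columns=samples)
        det["__sp"] = assigned[matched]
        seen.loc[det.groupby("__sp").any().index, :] |= det.groupby("__sp").any()
    provenance = pd.DataFrame(
        np.where(seen.to_numpy(), "detected", "absent"), index=species.index, columns=samples
    )
    unmatched = table.loc[~matched].reset_index(drop=True)
    # tag unmatched features sitting one 13C spacing above a database species
    # (A+1 peaks are real signal, not noise; the floor estimate skips them)
    iso = np.zeros(len(unmatched), dtype=bool)
    if len(unmatched):
        umz = unmatched["mz"].to_numpy(float)
        ucls = _assign_classes(unmatched["rt"].to_numpy(float), species, [])
        for cls, sub in species.groupby("class", sort=True):
            mask = ucls == cls
            if not mask.any():
                continue
            base = sub["mz"].to_numpy()
            smz = np.sort(np.concatenate([base + C13_DELTA, base + 2 * C13_DELTA]))
            idx = np.clip(np.searchsorted(smz, umz[mask]), 1, len(smz) - 1)
            d = np.minimum(np.abs(umz[mask] - smz[idx - 1]), np.abs(umz[mask] - smz[idx]))
            iso[mask] = d <= mz_tolerance
    unmatched = unmatched.assign(isotope_a1=iso)
    log.append(f"matched {int(matched.sum())}/{len(table)} features to {int((abundance.sum(axis=1) > 0).sum())} species")
    return AnnotatedLipidome(abundance, species, provenance, unmatched, metadata, log=log)


def deisotope(
    lipidome: AnnotatedLipidome,
    c13_abundance: float = DEFAULT_C13_ABUNDANCE,
    mz_tolerance: float = DEFAULT_MZ_TOLERANCE,
    cells: pd.DataFrame | None = None,
) -> AnnotatedLipidome:
    """Subtract A+2 13C2 isotope overlap within each lipid class.

    On a unit-resolution trap the A+2 peak of a species (at +2.0067 Th) merges
    with the monoisotopic peak of the species with one double-bond equivalent
    fewer (+2.0156 Th).  Species are processed in ascending m/z within each
    class in a single pass, so cascaded corrections use already-corrected
    upstream intensities.  Intensities are clipped at zero and clips logged.

    ``cells`` optionally restricts the correction to a boolean species x
    samples mask (used to correct freshly gap-filled cells without
    re-correcting cells that were already de-isotoped).
    """
    out = lipidome.copy()
    ab = out.abundance
    sp = out.species
    n_clip = 0
    for _, cls_sp in sp.groupby("class", sort=True):
        cls_sp = cls_sp.sort_values("mz")
        names = cls_sp.index.to_numpy()
        mzs = cls_sp["mz"].to_numpy()
        formulas = [ElementalFormula.from_string(f) for f in cls_sp["formula"]]
        for j in range(len(names)):
            for i in range(j - 1, -1, -1):
                d = mzs[j] - mzs[i]
                if d > 2 * C13_DELTA + mz_tolerance:
                    break
                if abs(d - 2 * C13_DELTA) <= mz_tolerance:
                    ratio = isotope_ratio(formulas[i], 2, c13_abundance)
                    corr = ab.loc[names[j]] - ratio * ab.loc[names[i]]
                    if cells is not None:
                        mask = cells.loc[names[j]].reindex(ab.columns).fillna(False)
                        corr = corr.where(mask, ab.loc[names[j]])
                    n_clip += int((corr < 0).sum())
                    ab.loc[names[j]] = corr.clip(lower=0.0)
    if n_clip:
        out.log.append(f"deisotoping clipped {n_clip} cells at zero")
    return out


def estimate_noise_floor(lipidome: AnnotatedLipidome) -> float:
    """Noise-floor estimate: median positive intensity of unmatched features."""
    un = lipidome.unmatched
    if "isotope_a1" in un.columns:
        un = un[~un["isotope_a1"]]
    if len(un) == 0:
        return 0.0
    samples = [c for c in un.columns if c not in ("mz", "rt", "isotope_a1")]
    vals = un[samples].to_numpy(float)
    vals = vals[np.isfinite(vals) & (vals > 0)]
    return float(np.median(vals)) if vals.size else 0.0


def noise_filter(
    lipidome: AnnotatedLipidome,
    min_intensity: float | None = None,
    min_samples: int = 1,
) -> AnnotatedLipidome:
    """Drop species not exceeding ``min_intensity`` in >= ``min_samples`` samples.

    Default threshold is 3x the estimated noise floor.
    """
    if min_intensity is None:
        min_intensity = 3.0 * estimate_noise_floor(lipidome)
    if min_intensity < 0 or min_samples < 0:
        raise ValueError("thresholds must be >= 0")
    keep = (lipidome.abundance > min_intensity).sum(axis=1) >= min_samples
    removed = sorted(lipidome.abundance.index[~keep])
    out = lipidome.copy()
    out.abundance = out.abundance.loc[keep]
    out.provenance = out.provenance.loc[keep]
    out.species = out.species.loc[keep]
    out.log.append(
        f"noise filter (>{min_intensity:.3g} in >={min_samples} samples) removed "
        f"{len(removed)} species"
    )
    return out


def force_integrate(
    lipidome: AnnotatedLipidome,
    table: pd.DataFrame,
    mz_tolerance: float = DEFAULT_MZ_TOLERANCE,
) -> AnnotatedLipidome:
    """Fill cells where a retained species was not detected in a sample.

    The intensity is re-read from ``table`` (typically the raw, uncensored
    re-integration of the same runs) at the species' expected m/z and class rt
    window; if nothing is found there either, 0 is recorded.  Either way the
    cell is flagged ``force_integrated``, so downstream users can tell gap
    fills from detections.
    """
    out = lipidome.copy()
    samples = _feature_columns(table)
    mz = table["mz"].to_numpy(float)
    rt = table["rt"].to_numpy(float)
    vals = np.nan_to_num(table[samples].to_numpy(float), nan=0.0)
    n_filled = 0
    for name, row in out.species.iterrows():
        missing = out.provenance.loc[name] != "detected"
        if not missing.any():
            continue
        sel = (np.abs(mz - row["mz"]) <= mz_tolerance) & (rt >= row["rt_lo"]) & (rt <= row["rt_hi"])
        cols = [s for s in out.sample_ids if missing.get(s, False)]
        if sel.any():
            reread = pd.Series(vals[sel].sum(axis=0), index=samples)
            out.abundance.loc[name, cols] = reread.reindex(cols).fillna(0.0)
        else:
            out.abundance.loc[name, cols] = 0.0
        out.provenance.loc[name, cols] = "force_integrated"
        n_filled += len(cols)
    out.log.append(f"force-integrated {n_filled} cells")
    return out


def normalize(lipidome: AnnotatedLipidome) -> AnnotatedLipidome:
    """Scale every sample column to sum to 100% of total lipid signal.

    Samples with no lipid signal at all (e.g. cell-free incubations) are
    dropped and reported in ``dropped_samples``.
    """
    out = lipidome.copy()
    totals = out.abundance.sum(axis=0)
    dead = totals[totals <= 0].index.tolist()
    if dead:
        out.dropped_samples.extend(dead)
        out.log.append(f"dropped {len(dead)} all-zero samples: {dead}")
        out.abundance = out.abundance.drop(columns=dead)
        out.provenance = out.provenance.drop(columns=dead)
        totals = totals.drop(dead)
    out.abundance = out.abundance.div(totals, axis=1) * 100.0
    out.normalized = True
    return out


def process_feature_table(
    table: pd.DataFrame,
    database: list[LipidSpecies] | pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    raw_table: pd.DataFrame | None = None,
    mz_tolerance: float = DEFAULT_MZ_TOLERANCE,
    c13_abundance: float = DEFAULT_C13_ABUNDANCE,
    min_intensity: float | None = None,
    min_samples: int = 1,
) -> AnnotatedLipidome:
    """Full annotation pipeline: match, de-isotope, filter, gap-fill, normalize."""
    lip = match_features(table, database, mz_tolerance, metadata)
    lip = deisotope(lip, c13_abundance, mz_tolerance)
    lip = noise_filter(lip, min_intensity, min_samples)
    before = lip.provenance.copy()
    lip = force_integrate(lip, raw_table if raw_table is not None else table, mz_tolerance)
    # freshly gap-filled cells carry uncorrected isotope overlap
    filled = (lip.provenance == "force_integrated") & (before != "force_integrated")
    if filled.to_numpy().any():
        lip = deisotope(lip, c13_abundance, mz_tolerance, cells=filled)
    return normalize(lip)
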