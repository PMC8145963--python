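"""End-to-end orchestration: database -> annotation -> metrics -> markers ->
differential tests -> growth phenotyping, from one config, with a
reproducibility manifest.

All tables go in and out as CSV; the manifest (JSON) records the seed, the
parameter hash and package version so a report bundle can be regenerated
exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import process_feature_table
from .differential import (
    construct_label,
    cybert_anova,
    gene_tag_counts,
    joint_label,
    marker_summary,
    rf_select_markers,
)
from .growth import compare_to_controls, summarize_growth
from .lipid_db import default_database_config, generate_database, named_species_table
from .metrics import acyl_properties_table, butanol_zscore, correlation_structure


class SchemaError(ValueError):
    """Raised when an input table does not match its expected schema."""


DEFAULT_PARAMS = {
    "mz_tolerance": 0.3,
    "c13_abundance": 0.011,
    "min_samples": 1,
    "rf_trees": 500,
    "rf_step": 1,
    "rf_cv_folds": 10,
    "cybert_window": 101,
    "cybert_conf": 5.0,
    "alpha": 0.05,
    "qc_min_od": 0.2,
    "growth_window_points": 13,
    "cluster_k": 8,
    "seed": 0,
}


def _require(df: pd.DataFrame, cols, what: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} lacks required columns {missing}")


def load_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    _require(meta, ["sample_id", "gene", "construct_type", "butanol"], "metadata")
    bad = set(meta["construct_type"]) - {"KO", "OV", "WT", "EV"}
    if bad:
        raise SchemaError(f"metadata construct_type contains unknown values {sorted(bad)}")
    return meta.set_index("sample_id")


def run_pipeline(
    feature_table: pd.DataFrame,
    metadata: pd.DataFrame,
    od_table: pd.DataFrame | None = None,
    raw_feature_table: pd.DataFrame | None = None,
    params: dict | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full analysis; returns (and optionally writes) the report bundle.

    QC-excluded cultures (never reaching the minimum OD) are removed from the
    lipidome before any downstream statistics.
    """
    p = dict(DEFAULT_PARAMS)
    if params:
        p.update(params)
    _require(feature_table, ["mz", "rt"], "feature table")
    report: dict = {}

    database = generate_database(default_database_config())
    species = named_species_table(database)

    excluded: list = []
    if od_table is not None:
        _require(od_table, ["time_min"], "OD table")
        growth = summarize_growth(
            od_table, window_points=p["growth_window_points"], min_od=p["qc_min_od"]
        )
        excluded = growth.index[~growth["qc_pass"]].tolist()
        report["growth_summary"] = growth
        report["growth_classification_mu"] = compare_to_controls(
            growth[growth["qc_pass"]], metadata, alpha=p["alpha"], value="mu_max"
        )
        report["growth_classification_od"] = compare_to_controls(
            growth[growth["qc_pass"]], metadata, alpha=p["alpha"], value="steady_state_od"
        )

    sample_cols = [c for c in feature_table.columns if c not in ("mz", "rt")]
    keep = [c for c in sample_cols if c not in excluded]
    ft = feature_table[["mz", "rt"] + keep]
    raw = raw_feature_table[["mz", "rt"] + keep] if raw_feature_table is not None else None

    lip = process_feature_table(
        ft, species, metadata=metadata, raw_table=raw,
        mz_tolerance=p["mz_tolerance"], c13_abundance=p["c13_abundance"],
        min_samples=p["min_samples"],
    )
    report["lipidome"] = lip.abundance
    report["provenance"] = lip.provenance
    report["unmatched_features"] = lip.unmatched
    report["processing_log"] = lip.log

    meta = metadata.loc[lip.abundance.columns]
    report["acyl_properties"] = acyl_properties_table(lip.abundance)
    if meta["butanol"].astype(int).nunique() > 1:
        report["zscores"] = butanol_zscore(lip.abundance, meta).to_frame()
    struct = correlation_structure(lip.abundance)
    report["correlation_matrix"] = struct.matrix
    report["clusters"] = struct.cluster_labels(p["cluster_k"]).to_frame()
    report["dendrogram_newick"] = struct.to_newick()

    labels = joint_label(meta) if meta["butanol"].astype(int).nunique() > 1 else construct_label(meta)
    panel = rf_select_markers(
        lip.abundance.T, labels, n_trees=p["rf_trees"], step=p["rf_step"],
        cv_folds=p["rf_cv_folds"], seed=p["seed"],
    )
    report["marker_panel"] = marker_summary(panel.species, lip.abundance, meta)
    report["oob_trace"] = panel.oob_trace
    try:
        report["gene_tags"] = gene_tag_counts(panel.species, lip.abundance, meta).to_frame()
    except ValueError:
        pass  # tiny designs without 2k constructs
    test = cybert_anova(
        lip.abundance, construct_label(meta),
        window=p["cybert_window"], conf=p["cybert_conf"], alpha=p["alpha"],
    )
    report["differential"] = test.table

    manifest = {
        "package": "colipid",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": p["seed"],
        "params": {k: v for k, v in p.items()},
        "params_hash": hashlib.sha256(
            json.dumps(p, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_samples": len(lip.abundance.columns),
        "n_species": len(lip.abundance.index),
        "qc_excluded": excluded,
    }
    report["manifest"] = manifest

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, obj in report.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(out / f"{name}.csv")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        (out / "dendrogram.nwk").write_text(report["dendrogram_newick"])
        (out / "processing_log.txt").write_text("\n".join(report["processing_log"]))
    return report
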