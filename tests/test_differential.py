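"""Marker selection by random forest and Bayes-regularized differential tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import colipid as cl
from colipid.differential import (
    REFERENCE_MARKER_PANEL,
    construct_label,
    cybert_anova,
    gene_tag_counts,
    joint_label,
    marker_summary,
    rf_select_markers,
)


def test_reference_panel_average_sums_to_published_total():
    assert round(REFERENCE_MARKER_PANEL["average_pct"].sum(), 1) == 21.2
    # printed averages lie within their printed extremes
    assert (REFERENCE_MARKER_PANEL["average_pct"] <= REFERENCE_MARKER_PANEL["max_pct"]).all()
    assert (REFERENCE_MARKER_PANEL["average_pct"] >= REFERENCE_MARKER_PANEL["min_pct"]).all()


# ---------------------------------------------------------------------------
# random forest marker selection

def _toy_classification(rng, n_classes=6, n_per=12, n_features=40, n_informative=4):
    y = np.repeat([f"g{i}" for i in range(n_classes)], n_per)
    X = rng.normal(0, 1, size=(n_classes * n_per, n_features))
    centers = rng.normal(0, 3, size=(n_classes, n_informative))
    for c in range(n_classes):
        X[y == f"g{c}", :n_informative] += centers[c]
    cols = [f"sp{i:02d}" for i in range(n_features)]
    return (
        pd.DataFrame(X, columns=cols),
        pd.Series(y, index=pd.RangeIndex(len(y))),
        cols[:n_informative],
    )


def test_rf_recovers_informative_features_and_is_deterministic(rng):
    X, y, informative = _toy_classification(rng)
    a = rf_select_markers(X, y, n_trees=80, step=2, seed=5)
    b = rf_select_markers(X, y, n_trees=80, step=2, seed=5)
    assert a.species == b.species
    assert a.oob_trace.equals(b.oob_trace)
    assert set(informative) <= set(a.species)
    assert a.informative
    # the trace covers every elimination step down to one feature
    assert a.oob_trace["n_features"].iloc[0] == X.shape[1]
    assert a.oob_trace["n_features"].iloc[-1] == 1


def test_rf_flags_pure_noise_as_uninformative(rng):
    X = pd.DataFrame(rng.normal(size=(60, 15)), columns=[f"sp{i}" for i in range(15)])
    y = pd.Series(rng.choice(["a", "b", "c"], size=60))
    panel = rf_select_markers(X, y, n_trees=60, step=3, seed=1, cv_folds=5)
    assert not panel.informative


def test_rf_input_validation(rng):
    X = pd.DataFrame(rng.normal(size=(6, 4)))
    with pytest.raises(ValueError):
        rf_select_markers(X, pd.Series(["a"] * 6), n_trees=10)
    with pytest.raises(ValueError):
        rf_select_markers(X, pd.Series(["a", "b"] * 3), n_trees=10, cv_folds=10)


def test_rf_panel_core_stable_across_seeds(rng):
    """The informative core survives selection for every forest seed; panel
    tails (noise features kept by the 1-SE tolerance) may fluctuate."""
    X, y, informative = _toy_classification(rng, n_classes=6, n_per=20)
    panels = [
        set(rf_select_markers(X, y, n_trees=120, step=2, seed=s).species)
        for s in range(3)
    ]
    for p in panels:
        assert set(informative) <= p
        assert len(p) <= X.shape[1] // 2  # selection compresses in every seed


# ---------------------------------------------------------------------------
# marker summaries and tag counts

def _small_lipidome(rng):
    genes = [f"gene{i}" for i in range(12)]
    meta_rows, cols = [], []
    for g in genes:
        for t in ("KO", "OV"):
            for r in range(2):
                cols.append(f"{g}_{t}_{r}")
                meta_rows.append({"gene": g, "construct_type": t, "butanol": 0})
    for r in range(4):
        cols.append(f"WT_{r}")
        meta_rows.append({"gene": "WT", "construct_type": "WT", "butanol": 0})
    meta = pd.DataFrame(meta_rows, index=cols)
    ab = pd.DataFrame(
        rng.lognormal(1, 0.4, size=(6, len(cols))),
        index=["PE 34:1", "PE 32:1", "PG 35:0c1", "CL 66:2", "aPE 50:1", "PBut 33:0c1"],
        columns=cols,
    )
    return ab, meta


def test_marker_summary_extremes_and_ordering(rng):
    ab, meta = _small_lipidome(rng)
    ab.loc["PE 34:1", meta.index[(meta["gene"] == "gene3") & (meta["construct_type"] == "OV")]] = 50.0
    out = marker_summary(["PE 34:1", "PE 32:1"], ab, meta)
    assert out.loc["PE 34:1", "construct_max"] == "gene3 (OV)"
    assert (out["min_pct"] <= out["average_pct"]).all()
    assert (out["average_pct"] <= out["max_pct"]).all()
    assert "panel_total_reference_pct" in out.attrs


def test_marker_summary_degenerate_and_missing(rng):
    ab, meta = _small_lipidome(rng)
    ab.loc["PE 32:1"] = 5.0
    out = marker_summary(["PE 32:1"], ab, meta)
    assert out.loc["PE 32:1", "degenerate"]
    assert out.loc["PE 32:1", "average_pct"] == pytest.approx(5.0)
    with pytest.raises(KeyError):
        marker_summary(["PS 32:0"], ab, meta)


def test_gene_tag_counts_total(rng):
    ab, meta = _small_lipidome(rng)
    tags = gene_tag_counts(list(ab.index), ab, meta, k=5)
    assert tags.sum() == 2 * 5 * len(ab.index)  # 6 markers x 10 tags
    with pytest.raises(ValueError):
        gene_tag_counts(list(ab.index), ab, meta, k=40)


def test_construct_and_joint_labels():
    meta = pd.DataFrame(
        {"gene": ["cfa", "WT"], "construct_type": ["KO", "WT"], "butanol": [1, 0]},
        index=["a", "b"],
    )
    assert list(construct_label(meta)) == ["cfa (KO)", "WT"]
    assert list(joint_label(meta)) == ["cfa (KO)|buoh", "WT|ctl"]


# ---------------------------------------------------------------------------
# Bayes-regularized ANOVA

def _null_data(rng, n_species=200, k=3, n=8, sd=0.3):
    means = rng.normal(2, 1, size=(n_species, 1))
    X = pd.DataFrame(
        rng.lognormal(np.tile(means, (1, k * n)), sd),
        index=[f"sp{i:03d}" for i in range(n_species)],
        columns=[f"s{j}" for j in range(k * n)],
    )
    groups = pd.Series([f"g{j // n}" for j in range(k * n)], index=X.columns)
    return X, groups


def test_cybert_null_p_values_uniform():
    """Identical group means for every species: p-values are U(0,1)."""
    rng = np.random.default_rng(0)
    mu = rng.normal(10, 3, size=(200, 1))
    X = pd.DataFrame(mu + rng.normal(0, 1, size=(200, 24)),
                     index=[f"sp{i:03d}" for i in range(200)])
    groups = pd.Series([f"g{j // 8}" for j in range(24)], index=X.columns)
    res = cybert_anova(X, groups, window=101, conf=5.0)
    ks = stats.kstest(res.table["p"], "uniform")
    assert ks.pvalue > 0.01


def test_cybert_species_order_invariance(rng):
    X, groups = _null_data(rng, n_species=60)
    a = cybert_anova(X, groups, window=21, conf=5.0).table
    b = cybert_anova(X.iloc[::-1], groups, window=21, conf=5.0).table
    pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


def test_cybert_regularization_shrinks_variance_dispersion(rng):
    X, groups = _null_data(rng, n_species=150, k=2, n=4)
    raw_s2, reg_s2 = [], []
    for g in ("g0", "g1"):
        cols = groups[groups == g].index
        s2 = X[cols].var(axis=1, ddof=1)
        from colipid.differential import _background_variance

        bg = _background_variance(X[cols].mean(axis=1), s2, 51)
        n = len(cols)
        reg = (5.0 * bg + (n - 1) * s2) / (5.0 + n - 2)
        raw_s2.append(s2)
        reg_s2.append(reg)
    assert pd.concat(reg_s2).var() < pd.concat(raw_s2).var()


def test_cybert_classical_limit(rng):
    # conf -> 0 coincides with the classical one-way F (any group size)
    n = 500
    X = pd.DataFrame(rng.normal(size=(3, 2 * n)), index=list("abc"))
    groups = pd.Series(["x"] * n + ["y"] * n, index=X.columns)
    res = cybert_anova(X, groups, window=3, conf=0.0)
    classic = np.array(
        [stats.f_oneway(X.iloc[i, :n], X.iloc[i, n:]).statistic for i in range(3)]
    )
    assert np.abs(res.table["F"].to_numpy() / classic - 1).max() < 1e-9


def test_cybert_power_on_planted_two_fold_shift(rng):
    """2-fold shifted species at n=3/group are detected at 10% replicate CV."""
    n_species = 200
    base = rng.normal(2, 1, size=(n_species, 1))
    A = rng.lognormal(np.tile(base, (1, 3)), 0.1)
    B = rng.lognormal(np.tile(base, (1, 3)), 0.1)
    B[:10] *= 2.0
    X = pd.DataFrame(np.hstack([A, B]), index=[f"sp{i:03d}" for i in range(n_species)])
    groups = pd.Series(["a"] * 3 + ["b"] * 3, index=X.columns)
    res = cybert_anova(X, groups, window=101, conf=5.0)
    assert res.table["significant"].iloc[:10].mean() >= 0.8
    assert res.table["significant"].iloc[10:].mean() <= 0.05


def test_cybert_validation_and_window_clipping(rng):
    X, groups = _null_data(rng, n_species=20)
    with pytest.raises(ValueError):
        cybert_anova(X, groups, window=100)  # even window
    with pytest.warns(UserWarning):
        res = cybert_anova(X, groups, window=101)  # larger than species count
    assert res.window <= 20
    t = res.table
    assert t["p"].between(0, 1).all()
    assert (t["p_adj"] >= t["p"] - 1e-12).all()
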