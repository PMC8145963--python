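"""Membrane-level acyl properties, butanol response Z-scores, and the
lipid-lipid correlation / hierarchical-cluster structure of a lipidome.

Acyl properties summarise a percent composition as averages per acyl chain:
mean chain length (carbons), unsaturation index (double bonds per chain) and
cyclopropane fraction (rings per chain).  Averages are chain-weighted by
default: a cardiolipin molecule contributes four chains per mole, a headgroup
acylated lipid three, a diacyl lipid two.  Mole weighting is available for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .lipid_db import LIPID_CLASSES, parse_species_name


@dataclass(frozen=True)
class AcylProperties:
    mean_chain_length: float
    unsaturation_index: float
    cyclopropane_fraction: float


def _species_features(names) -> pd.DataFrame:
    rows = []
    for name in names:
        cls, comp = parse_species_name(name)
        rows.append(
            {
                "class": cls,
                "n_chains": LIPID_CLASSES[cls].n_chains,
                "total_carbons": comp.total_carbons,
                "double_bonds": comp.double_bonds,
                "cyclopropane": comp.cyclopropane_rings,
            }
        )
    return pd.DataFrame(rows, index=pd.Index(names, name="name"))


def acyl_properties(composition: pd.Series, chain_weighted: bool = True) -> AcylProperties:
    """Average acyl properties of one (percent) composition.

    With chain weighting, weights are abundance x n_chains and per-chain values
    are C/n, DB/n, rings/n; mole weighting uses the abundances directly.
    Scale-free: multiplying the composition by a constant changes nothing.
    """
    composition = composition[composition > 0]
    if len(composition) == 0 or composition.sum() <= 0:
        raise ValueError("empty or all-zero composition")
    feats = _species_features(composition.index)
    n = feats["n_chains"].to_numpy(float)
    w = composition.to_numpy(float) * (n if chain_weighted else 1.0)
    per_chain = feats[["total_carbons", "double_bonds", "cyclopropane"]].to_numpy(float) / n[:, None]
    mcl, ui, cf = (w @ per_chain) / w.sum()
    return AcylProperties(float(mcl), float(ui), float(cf))


def acyl_properties_table(abundance: pd.DataFrame, chain_weighted: bool = True) -> pd.DataFrame:
    """Per-sample acyl properties of a species x samples percent matrix."""
    feats = _species_features(abundance.index)
    n = feats["n_chains"].to_numpy(float)
    w = abundance.to_numpy(float) * ((n if chain_weighted else np.ones_like(n))[:, None])
    per_chain = feats[["total_carbons", "double_bonds", "cyclopropane"]].to_numpy(float) / n[:, None]
    tot = w.sum(axis=0)
    vals = (w.T @ per_chain) / tot[:, None]
    return pd.DataFrame(
        vals,
        index=abundance.columns,
        columns=["mean_chain_length", "unsaturation_index", "cyclopropane_fraction"],
    )


def butanol_zscore(abundance: pd.DataFrame, metadata: pd.DataFrame) -> pd.Series:
    """Per-species Z-score of butanol exposure against the control distribution.

    Z = (mean_butanol - mean_control) / sd_control; positive means more
    abundant under n-butanol.  Species with zero control variance get NaN.
    """
    meta = metadata.loc[abundance.columns]
    but = meta["butanol"].astype(int) == 1
    if but.all() or (~but).all():
        raise ValueError("need both butanol and control samples")
    a_but = abundance.loc[:, but.to_numpy()]
    a_ctl = abundance.loc[:, (~but).to_numpy()]
    sd = a_ctl.std(axis=1, ddof=1)
    z = (a_but.mean(axis=1) - a_ctl.mean(axis=1)) / sd
    z[sd == 0] = np.nan
    return z.rename("zscore")


@dataclass
class CorrelationStructure:
    matrix: pd.DataFrame          # species x species correlations
    linkage: np.ndarray           # scipy linkage matrix
    leaf_order: list              # species names in dendrogram leaf order
    excluded: list                # constant species removed before correlation
    method: str
    linkage_rule: str

    def cluster_labels(self, k: int) -> pd.Series:
        labels = fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.matrix.index, name="cluster")

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage, list(self.matrix.index))
        return str(tree)


def correlation_structure(
    abundance: pd.DataFrame,
    method: str = "pearson",
    linkage_rule: str = "average",
    clr: bool = False,
) -> CorrelationStructure:
    """Lipid-lipid correlation matrix with hierarchical clustering.

    Correlations are computed across samples on percent values (optionally on
    centered log-ratios for compositional-bias-aware analysis); agglomeration
    uses distance 1 - r.  Species are sorted by name first, making the result
    independent of input species and sample order.
    """
    if abundance.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    X = abundance.sort_index()
    if clr:
        logged = np.log(X.clip(lower=X[X > 0].min().min() / 2.0))
        X = logged - logged.mean(axis=0)
    sd = X.std(axis=1, ddof=1)
    excluded = sorted(X.index[sd == 0])
    X = X.loc[sd > 0]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 non-constant species")
    corr = X.T.corr(method=method)
    dist = squareform(np.clip(1.0 - corr.to_numpy(), 0.0, 2.0), checks=False)
    Z = linkage(dist, method=linkage_rule)
    order = [corr.index[i] for i in leaves_list(Z)]
    return CorrelationStructure(corr, Z, order, excluded, method, linkage_rule)


def class_annotation_bars(species_list) -> pd.DataFrame:
    """Per-species (class, total double bonds, cyclopropane yes/no) annotation.

    Mirrors the colored category bars drawn above a clustered lipid heatmap.
    """
    feats = _species_features(species_list)
    return pd.DataFrame(
        {
            "class": feats["class"],
            "total_double_bonds": feats["double_bonds"],
            "cyclopropane": np.where(feats["cyclopropane"] > 0, "yes", "no"),
        },
        index=feats.index,
    )
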