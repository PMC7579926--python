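"""Differential expression and clustering-based feature reduction.

DE is the feature-selection engine for the smoking index, the timing
classifier and the benign/malignant models: a per-gene NB GLM (log link) on
raw counts with log size factors as offset, dispersion anchored to the seed
reference trend at the gene's normalized mean, a Wald test on the contrast
coefficient and Benjamini-Hochberg adjustment.  The case group can be
augmented with an auxiliary set of out-of-indication malignant samples to
boost power; auxiliary samples contribute fully to the design.

Feature reduction collapses correlated genes: average-linkage hierarchical
clustering on the 1 - |Pearson r| distance, cut to ceil(proportion * n)
clusters, keeping one representative per cluster (smallest DE p-value,
ties broken by gene-id order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from ._nbglm import DesignError, design_matrix, fit_nb_glm
from .normalize import SeedReference, _size_factor

__all__ = ["DEResult", "FeatureSet", "de_analysis", "reduce_features"]


@dataclass
class DEResult:
    """Per-gene Wald DE table: log2FC, SE, statistic, p and BH-adjusted p."""

    table: pd.DataFrame
    contrast: str
    design_covariates: tuple[str, ...]

    def significant(self, fdr: float = 0.05) -> pd.Index:
        t = self.table
        return t.index[t["padj"] < fdr]


@dataclass
class FeatureSet:
    """A gene feature set with provenance."""

    genes: list[str]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def de_analysis(
    counts: pd.DataFrame,
    clinical: pd.DataFrame,
    contrast: str,
    design_covariates: list[str],
    ref: SeedReference,
    auxiliary: pd.Index | None = None,
) -> DEResult:
    """Negative-binomial Wald differential expression.

    ``contrast`` names a binary clinical column; its second sorted level is
    the tested (case) direction, so log2FC > 0 means higher in that level.
    ``auxiliary`` optionally names extra case samples (columns of
    ``counts``) appended to the analysis, e.g. out-of-indication malignant
    bronchial samples when testing the benign/malignant label.
    """
    samples = list(counts.columns)
    if auxiliary is not None:
        samples = samples + [s for s in auxiliary if s not in counts.columns]
    clin = clinical.loc[counts.columns]
    levels = sorted(clin[contrast].dropna().astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"contrast {contrast!r} must be binary, found levels {levels}")

    X_df = design_matrix(clin, design_covariates + [contrast])
    contrast_col = f"{contrast}[{levels[1]}]"
    if contrast_col not in X_df.columns:
        raise ValueError(f"contrast column {contrast_col!r} not in design")
    X = X_df.to_numpy()
    j = list(X_df.columns).index(contrast_col)

    arr = counts.to_numpy(dtype=float)
    geo = ref.geo_means.reindex(counts.index).to_numpy()
    sfs = np.array([_size_factor(arr[:, k], geo) for k in range(arr.shape[1])])
    offset = np.log(sfs)
    norm_mean = np.maximum((arr / sfs[None, :]).mean(axis=1), 1e-8)
    disp = ref.dispersion(norm_mean)

    beta, se = fit_nb_glm(arr, X, offset, disp)
    b, s = beta[:, j], np.maximum(se[:, j], 1e-12)
    stat = b / s
    pval = 2.0 * norm.sf(np.abs(stat))
    padj = multipletests(pval, method="fdr_bh")[1]
    ln2 = np.log(2.0)
    table = pd.DataFrame(
        {
            "log2fc": b / ln2,
            "se": s / ln2,
            "stat": stat,
            "pvalue": pval,
            "padj": padj,
            "base_mean": norm_mean,
        },
        index=counts.index,
    )
    return DEResult(table=table, contrast=contrast, design_covariates=tuple(design_covariates))


def reduce_features(
    normalized: pd.DataFrame,
    feature_set: FeatureSet | list[str],
    proportion: float,
    de_pvalues: pd.Series | None = None,
    method: str = "hierarchical",
) -> FeatureSet:
    """Trim a gene set to ``ceil(proportion * n)`` cluster representatives.

    Distance is 1 - |Pearson r| across samples, average linkage; the
    representative of each cluster is the member with the smallest DE
    p-value (ties and missing p-values resolved by gene-id order).
    ``proportion == 1`` returns the input unchanged.
    """
    if method != "hierarchical":
        raise ValueError(f"unknown reduction method {method!r}")
    if not 0.0 < proportion <= 1.0:
        raise ValueError(f"proportion {proportion} outside (0, 1]")
    genes = list(feature_set.genes if isinstance(feature_set, FeatureSet) else feature_set)
    prov = dict(feature_set.provenance) if isinstance(feature_set, FeatureSet) else {}
    if len(genes) < 2:
        raise ValueError("feature set must contain at least 2 genes")
    if proportion == 1.0:
        return FeatureSet(genes=genes, provenance={**prov, "reduction": "identity"})

    expr = normalized.loc[genes].to_numpy(dtype=float)
    n_clusters = int(np.ceil(proportion * len(genes)))
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(expr)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = sch.linkage(squareform(dist, checks=False), method="average")
    labels = sch.fcluster(Z, t=n_clusters, criterion="maxclust")

    if de_pvalues is not None:
        pv = de_pvalues.reindex(genes).fillna(1.0).to_numpy()
    else:
        pv = np.ones(len(genes))
    reps = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        # smallest p-value, ties by gene-id order
        order = sorted(members, key=lambda i: (pv[i], genes[i]))
        reps.append(genes[order[0]])
    reps = sorted(reps, key=genes.index)
    return FeatureSet(
        genes=reps,
        provenance={**prov, "reduction": "hierarchical", "proportion": proportion},
    )
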