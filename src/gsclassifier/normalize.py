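"""Seed-anchored normalization, gene filtering and clinical imputation.

A frozen *seed reference* — per-gene geometric means plus a smoothed
dispersion-mean trend fitted on a fixed reference cohort — allows any later
sample to be normalized one at a time, reproducibly: the size factor is the
median ratio of the sample's counts to the seed geometric means, and
expression values are passed through a variance-stabilizing transform (VST)

    g(x) = integral_0^x  dmu / sqrt(mu + disp(mu) * mu^2)

whose dispersion function comes from the frozen trend.  Because Var(K) is
approximately mu + disp(mu) mu^2 for NB counts, g makes the variance of the
transformed values approximately constant across the expression range.

Gene filtering removes *low expressers* (< 1 transcript per million in more
than 99% of training samples) and *batch-sensitive* genes (excessive
within-identity variance across plates on replicated control/sentinel
samples).  Clinical imputation fills missing smoking history, nodule size and
age with stratum medians (cohort x indication x pre-test risk), inhaled
medication with "no", and specimen collection timing with the genomic timing
classifier's prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._nbglm import DesignError, design_matrix, estimate_dispersions

logger = logging.getLogger(__name__)

__all__ = [
    "SeedReference",
    "SeedNormalizer",
    "build_seed_reference",
    "normalize_sample",
    "normalize_counts",
    "flag_low_expressers",
    "flag_batch_sensitive",
    "gene_filter_mask",
    "impute_clinical",
]

_TREND_FLOOR = 1e-8
FORMAT_VERSION = "1"


@dataclass(frozen=True)
class SeedReference:
    """Frozen normalization state.

    ``geo_means`` holds the per-gene geometric mean over the seed samples
    (zero where any seed count is zero, DESeq-style; such genes are excluded
    from the size-factor median).  The dispersion-mean trend is stored as
    lowess knots on the (log mean, log dispersion) scale; the VST is stored
    as a precomputed integral on a log-spaced grid with linear
    interpolation.
    """

    geo_means: pd.Series
    trend_log_mu: np.ndarray
    trend_log_disp: np.ndarray
    vst_grid: np.ndarray
    vst_values: np.ndarray
    design_covariates: tuple[str, ...]
    seed_sample_ids: tuple[str, ...]
    format_version: str = FORMAT_VERSION
    genewise_dispersions: pd.Series | None = field(default=None, compare=False)

    @property
    def gene_ids(self) -> pd.Index:
        return self.geo_means.index

    def dispersion(self, mu: np.ndarray | float) -> np.ndarray:
        """Trend dispersion at mean ``mu`` (flat extrapolation, floored)."""
        mu = np.atleast_1d(np.asarray(mu, dtype=float))
        log_d = np.interp(np.log(np.maximum(mu, 1e-300)), self.trend_log_mu, self.trend_log_disp)
        return np.maximum(np.exp(log_d), _TREND_FLOOR)

    def vst(self, x: np.ndarray | float) -> np.ndarray:
        """Variance-stabilizing transform, monotone nondecreasing in x."""
        x = np.asarray(x, dtype=float)
        out = np.interp(x, self.vst_grid, self.vst_values)
        # linear extrapolation beyond the grid with the terminal slope
        hi = x > self.vst_grid[-1]
        if np.any(hi):
            slope = (self.vst_values[-1] - self.vst_values[-2]) / (
                self.vst_grid[-1] - self.vst_grid[-2]
            )
            out = np.where(hi, self.vst_values[-1] + slope * (x - self.vst_grid[-1]), out)
        return out


def _geometric_means(counts: pd.DataFrame) -> pd.Series:
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(arr)
    gm = np.where(np.all(arr > 0, axis=1), np.exp(np.mean(logs, axis=1)), 0.0)
    return pd.Series(gm, index=counts.index)


def _size_factor(sample: np.ndarray, geo_means: np.ndarray) -> float:
    pos = geo_means > 0
    if not np.any(pos) or np.all(sample[pos] == 0):
        raise ValueError("size factor undefined: no positive reference genes with counts")
    ratios = sample[pos] / geo_means[pos]
    return float(np.median(ratios))


def build_seed_reference(
    seed_counts: pd.DataFrame,
    clinical: pd.DataFrame,
    design: list[str] = ("label", "smoking_status", "timing"),
    min_trend_mean: float = 1.0,
    lowess_frac: float = 0.4,
    vst_grid_size: int = 10_000,
) -> SeedReference:
    """Fit the frozen seed reference from a seed cohort.

    Gene-wise dispersions are estimated from per-gene NB GLMs with the given
    design (diagnosis label, clinical smoking status and specimen collection
    timing by default) and smoothed by a tricube-weighted local regression of
    log dispersion on log mean, mimicking a local dispersion-mean fit.
    """
    if seed_counts.shape[1] == 0:
        raise ValueError("empty seed set")
    if seed_counts.shape[1] < 20:
        logger.warning(
            "seed set has %d samples; >= 20 recommended for a stable trend",
            seed_counts.shape[1],
        )
    clinical = clinical.loc[seed_counts.columns]
    try:
        X_df = design_matrix(clinical, list(design))
    except DesignError as err:
        if "missing" in str(err):
            raise
        logger.warning("seed design degenerate (%s); using intercept-only design", err)
        X_df = design_matrix(clinical, [])
    if X_df.shape[1] >= seed_counts.shape[1]:
        logger.warning(
            "seed design has %d columns for %d samples; using intercept-only design",
            X_df.shape[1], seed_counts.shape[1],
        )
        X_df = design_matrix(clinical, [])
    X = X_df.to_numpy()

    geo = _geometric_means(seed_counts)
    arr = seed_counts.to_numpy(dtype=float)
    sfs = np.array([_size_factor(arr[:, j], geo.to_numpy()) for j in range(arr.shape[1])])
    offset = np.log(sfs)

    disp = estimate_dispersions(arr, X, offset)
    norm_mean = (arr / sfs[None, :]).mean(axis=1)

    use = norm_mean >= min_trend_mean
    if use.sum() < 10:
        use = norm_mean > 0
    lm = np.log(norm_mean[use])
    ld = np.log(np.maximum(disp[use], _TREND_FLOOR))
    fitted = lowess(ld, lm, frac=lowess_frac, it=3, return_sorted=True)
    trend_x, trend_y = fitted[:, 0], fitted[:, 1]
    # collapse duplicate x for interpolation
    trend_x, idx = np.unique(trend_x, return_index=True)
    trend_y = trend_y[idx]

    grid_hi = max(float(norm_mean.max()) * 50.0, 10.0)
    grid = np.concatenate([[0.0], np.geomspace(1e-8, grid_hi, vst_grid_size)])
    log_d = np.interp(np.log(np.maximum(grid[1:], 1e-300)), trend_x, trend_y)
    d = np.maximum(np.exp(log_d), _TREND_FLOOR)
    integrand = np.concatenate([[0.0], 1.0 / np.sqrt(grid[1:] + d * grid[1:] ** 2)])
    # the integrand ~ mu^-1/2 near 0 is integrable; start the trapezoid at 0
    # with the 1e-8 node carrying the (negligible) head of the integral
    vst_vals = cumulative_trapezoid(integrand, grid, initial=0.0)

    return SeedReference(
        geo_means=geo,
        trend_log_mu=trend_x,
        trend_log_disp=trend_y,
        vst_grid=grid,
        vst_values=vst_vals,
        design_covariates=tuple(design),
        seed_sample_ids=tuple(seed_counts.columns),
        genewise_dispersions=pd.Series(disp, index=seed_counts.index),
    )


def normalize_sample(
    sample_counts: pd.Series, ref: SeedReference
) -> tuple[pd.Series, float]:
    """Normalize one sample against the frozen reference.

    Returns (VST values, size factor).  The size factor is the median over
    reference-positive genes of count / geometric mean; VST values are
    g(count / size factor).
    """
    if not sample_counts.index.equals(ref.gene_ids):
        raise ValueError("gene ids do not match the seed reference")
    arr = sample_counts.to_numpy(dtype=float)
    sf = _size_factor(arr, ref.geo_means.to_numpy())
    vst = ref.vst(arr / sf)
    return pd.Series(vst, index=sample_counts.index), sf


def normalize_counts(counts: pd.DataFrame, ref: SeedReference) -> tuple[pd.DataFrame, pd.Series]:
    """Batch normalization: column-wise :func:`normalize_sample`."""
    if not counts.index.equals(ref.gene_ids):
        raise ValueError("gene ids do not match the seed reference")
    arr = counts.to_numpy(dtype=float)
    geo = ref.geo_means.to_numpy()
    sfs = np.array([_size_factor(arr[:, j], geo) for j in range(arr.shape[1])])
    vst = ref.vst(arr / sfs[None, :])
    return (
        pd.DataFrame(vst, index=counts.index, columns=counts.columns),
        pd.Series(sfs, index=counts.columns, name="size_factor"),
    )


class SeedNormalizer(BaseEstimator, TransformerMixin):
    """Scikit-learn style wrapper over the seed-reference normalization.

    ``fit(X, clinical=...)`` builds the frozen reference from a samples x
    genes count frame; ``transform`` applies one-sample-at-a-time
    normalization and returns VST values on the same orientation.
    """

    def __init__(self, design: tuple[str, ...] = ("label", "smoking_status", "timing")):
        self.design = design

    def fit(self, X: pd.DataFrame, y=None, *, clinical: pd.DataFrame):
        self.reference_ = build_seed_reference(X.T, clinical, list(self.design))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        vst, sfs = normalize_counts(X.T, self.reference_)
        self.size_factors_ = sfs
        return vst.T


def flag_low_expressers(
    counts: pd.DataFrame, lengths: pd.Series, tpm_threshold: float = 1.0, frac: float = 0.99
) -> pd.Series:
    """Flag genes with TPM below ``tpm_threshold`` in more than ``frac`` of
    samples.

    TPM = (count/length) / sum_g(count/length) * 1e6 per sample.
    """
    lengths = lengths.loc[counts.index]
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.to_numpy(dtype=float) / lengths.to_numpy(dtype=float)[:, None]
    denom = rate.sum(axis=0, keepdims=True)
    denom[denom == 0] = 1.0
    tpm = rate / denom * 1e6
    frac_below = (tpm < tpm_threshold).mean(axis=1)
    return pd.Series(frac_below > frac, index=counts.index, name="low_expresser")


def flag_batch_sensitive(
    normalized: pd.DataFrame,
    replicate_design: pd.DataFrame,
    quantile: float = 0.98,
) -> pd.Series:
    """Flag genes with excessive replicate variability across plates.

    ``replicate_design`` must carry ``identity`` and ``plate`` columns for
    the control/sentinel samples (columns of ``normalized``).  The statistic
    per gene is the mean over replicated identities of the variance of its
    normalized expression across plates; genes above the ``quantile`` of
    that statistic are flagged (default: top 2%).
    """
    if not 0.0 <= quantile <= 1.0:
        raise ValueError("quantile must lie in [0, 1]")
    design = replicate_design.loc[replicate_design.index.intersection(normalized.columns)]
    if len(design) == 0:
        raise ValueError("no replicate samples found in the normalized matrix")
    if design["plate"].nunique() < 2:
        raise ValueError("batch-sensitivity detection needs replicates on >= 2 plates")
    per_identity = []
    for _, grp in design.groupby("identity"):
        if len(grp) < 2:
            continue
        sub = normalized[grp.index].to_numpy()
        per_identity.append(sub.var(axis=1, ddof=1))
    if not per_identity:
        raise ValueError("no identity replicated across plates")
    stat = np.mean(per_identity, axis=0)
    if quantile == 0.0:
        cut = -np.inf
    else:
        cut = np.quantile(stat, quantile)
    return pd.Series(stat > cut if quantile > 0 else np.ones(len(stat), bool),
                     index=normalized.index, name="batch_sensitive")


def gene_filter_mask(
    low_expresser: pd.Series, batch_sensitive: pd.Series | None = None
) -> pd.DataFrame:
    """Combine filter flags into a mask with reason codes.

    Reason is ``low_expresser`` where that flag is set (it is applied
    first), else ``batch_sensitive``, else ``kept``.
    """
    mask = pd.DataFrame({"low_expresser": low_expresser.astype(bool)})
    if batch_sensitive is not None:
        mask["batch_sensitive"] = batch_sensitive.reindex(low_expresser.index).fillna(False).astype(bool)
    else:
        mask["batch_sensitive"] = False
    mask["kept"] = ~(mask["low_expresser"] | mask["batch_sensitive"])
    mask["reason"] = np.where(
        mask["low_expresser"], "low_expresser",
        np.where(mask["batch_sensitive"], "batch_sensitive", "kept"),
    )
    return mask


_MEDIAN_IMPUTED = ("years_since_quit", "pack_years", "nodule_size_cm", "age")


def impute_clinical(
    clinical: pd.DataFrame,
    timing_model=None,
    normalized: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Impute missing clinical values.

    Continuous history variables get the median of their stratum
    (cohort x indication x pre-test risk), falling back to the cohort
    median when a stratum has no observed values (logged).  Missing inhaled
    medication becomes ``"no"``.  Missing specimen collection timing is
    predicted by the supplied timing classifier (which needs the normalized
    expression of the affected samples); with no model and missing timing
    values an error is raised.  Observed values are never overwritten.
    """
    out = clinical.copy()
    strata = ["cohort", "indication", "pretest_risk"]
    for col in _MEDIAN_IMPUTED:
        if col not in out.columns or not out[col].isna().any():
            continue
        stratum_median = out.groupby(strata, dropna=False)[col].transform("median")
        cohort_median = out.groupby("cohort", dropna=False)[col].transform("median")
        fill = stratum_median.where(stratum_median.notna(), cohort_median)
        if (out[col].isna() & stratum_median.isna()).any():
            logger.info("impute %s: empty stratum, fell back to cohort median", col)
        out[col] = out[col].where(out[col].notna(), fill)
    if "inhaled_med" in out.columns:
        out["inhaled_med"] = out["inhaled_med"].fillna("no")
    if "timing" in out.columns and out["timing"].isna().any():
        missing = out.index[out["timing"].isna()]
        if timing_model is None:
            raise ValueError(
                f"timing missing for {len(missing)} samples and no timing classifier provided"
            )
        if normalized is None:
            raise ValueError("normalized expression required to impute timing")
        _, calls = timing_model.predict_timing(normalized[missing])
        out.loc[missing, "timing"] = calls.to_numpy()
    return out
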