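"""Seed-reference normalization, VST properties, gene filters, imputation."""

import numpy as np
import pandas as pd
import pytest

from gsclassifier.normalize import (
    SeedNormalizer,
    build_seed_reference,
    flag_batch_sensitive,
    flag_low_expressers,
    gene_filter_mask,
    impute_clinical,
    normalize_counts,
    normalize_sample,
)
from gsclassifier.simulate import simulate_replicate_plates
from .conftest import small_config


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------


def test_size_factor_matches_hand_computed_median_of_ratios():
    genes = [f"g{i}" for i in range(5)]
    seed = pd.DataFrame(
        {"s1": [10, 20, 40, 5, 8], "s2": [10, 20, 40, 5, 8], "s3": [10, 20, 40, 5, 8]},
        index=genes,
    )
    clin = pd.DataFrame(
        {
            "label": ["benign", "malignant", "benign"],
            "smoking_status": ["current", "former", "current"],
            "timing": ["prior", "prior", "after"],
        },
        index=seed.columns,
    )
    ref = build_seed_reference(seed, clin)
    sample = pd.Series([20, 10, 80, 5, 4], index=genes, dtype=float)
    # ratios: 2, 0.5, 2, 1, 0.5 -> median 1
    _, sf = normalize_sample(sample, ref)
    assert sf == pytest.approx(1.0, abs=1e-12)
    sample2 = pd.Series([20, 40, 80, 10, 16], index=genes, dtype=float)
    _, sf2 = normalize_sample(sample2, ref)
    assert sf2 == pytest.approx(2.0, abs=1e-12)


def test_sample_equal_to_seed_profile_has_unit_size_factor():
    """A sample matching the seed's geometric-mean profile gets sf = 1."""
    genes = [f"g{i}" for i in range(4)]
    col = pd.Series([6.0, 12.0, 30.0, 3.0], index=genes)
    seed = pd.DataFrame({f"s{j}": col for j in range(3)})
    clin = pd.DataFrame(
        {"label": ["benign"] * 3, "smoking_status": ["current", "former", "former"],
         "timing": ["prior", "after", "prior"]},
        index=seed.columns,
    )
    ref = build_seed_reference(seed, clin)
    _, sf = normalize_sample(col, ref)
    assert sf == pytest.approx(1.0, abs=1e-12)


def test_doubling_counts_doubles_size_factor_and_preserves_vst(seed_ref, cohort):
    sample = cohort.counts.iloc[:, 0].astype(float)
    v1, sf1 = normalize_sample(sample, seed_ref)
    v2, sf2 = normalize_sample(2 * sample, seed_ref)
    assert sf2 == pytest.approx(2 * sf1, rel=1e-12)
    assert np.allclose(v1, v2, atol=1e-9)


def test_single_sample_path_equals_batch_normalization(seed_ref, cohort):
    seed_ids = list(seed_ref.seed_sample_ids)[:5]
    batch, sfs = normalize_counts(cohort.counts[seed_ids], seed_ref)
    for s in seed_ids:
        single, sf = normalize_sample(cohort.counts[s].astype(float), seed_ref)
        assert sf == pytest.approx(sfs[s], abs=1e-12)
        assert np.allclose(single, batch[s], atol=1e-6)


def test_all_zero_sample_raises(seed_ref, cohort):
    zero = pd.Series(0.0, index=cohort.counts.index)
    with pytest.raises(ValueError, match="size factor undefined"):
        normalize_sample(zero, seed_ref)


def test_gene_id_mismatch_raises(seed_ref):
    bad = pd.Series([1.0, 2.0], index=["x1", "x2"])
    with pytest.raises(ValueError, match="gene ids"):
        normalize_sample(bad, seed_ref)


# ---------------------------------------------------------------------------
# dispersion trend and VST
# ---------------------------------------------------------------------------


def test_dispersion_trend_recovers_simulated_trend(seed_ref):
    """Fitted trend within 25% of disp(mu) = 1/mu + 0.05 mid-range."""
    mu = np.array([10.0, 30.0, 100.0, 300.0, 1000.0])
    truth = 1.0 / mu + 0.05
    fitted = seed_ref.dispersion(mu)
    assert np.all(np.abs(fitted - truth) / truth < 0.25)


def test_identical_seed_columns_give_floor_dispersions():
    genes = [f"g{i}" for i in range(30)]
    col = pd.Series(np.arange(10, 40, dtype=float), index=genes)
    seed = pd.DataFrame({f"s{j}": col for j in range(24)})
    clin = pd.DataFrame(
        {"label": ["benign", "malignant"] * 12,
         "smoking_status": ["current", "current", "former", "former"] * 6,
         "timing": ["prior"] * 24},
        index=seed.columns,
    )
    ref = build_seed_reference(seed, clin)
    assert (ref.genewise_dispersions < 1e-4).all()
    assert np.all(ref.dispersion(np.array([15.0, 30.0])) < 1e-3)


def test_missing_design_covariate_raises(cohort):
    seed = cohort.counts.iloc[:, :24]
    clin = cohort.clinical.loc[seed.columns].drop(columns=["timing"])
    with pytest.raises(Exception, match="timing"):
        build_seed_reference(seed, clin)


def test_vst_is_monotone_nondecreasing(seed_ref):
    x = np.linspace(0, 5000, 2000)
    v = seed_ref.vst(x)
    assert np.all(np.diff(v) >= -1e-12)


def test_vst_stabilizes_variance_across_expression_deciles(cohort, seed_ref, vst, patients):
    """VST decile variances vary < 3x; raw log2 varies far more."""
    benign = [s for s in patients if cohort.clinical.loc[s, "label"] == "benign"
              and cohort.clinical.loc[s, "smoking_status"] == "former"]
    spiked = set(cohort.truth["gene_id"])
    neutral = [g for g in cohort.counts.index
               if g not in spiked
               and cohort.gene_annotation.loc[g, "chromosome"] not in ("chrX", "chrY")]
    counts = cohort.counts.loc[neutral, benign]
    vst = vst.loc[neutral, benign]
    mean = counts.mean(axis=1)
    deciles = pd.qcut(mean, 10, labels=False, duplicates="drop")
    vst_var = vst.var(axis=1).groupby(deciles).mean()
    # drop the lowest decile where counts are mostly zero for both scales
    ratio_vst = vst_var.iloc[1:].max() / vst_var.iloc[1:].min()
    raw_var = np.log2(counts + 1).var(axis=1).groupby(deciles).mean()
    ratio_raw = raw_var.iloc[1:].max() / raw_var.iloc[1:].min()
    assert ratio_vst < 3.0
    assert ratio_raw > ratio_vst


def test_seed_normalizer_sklearn_wrapper(cohort, patients):
    seed_ids = patients[:40]
    X = cohort.counts[seed_ids].T
    tr = SeedNormalizer().fit(X, clinical=cohort.clinical)
    out = tr.transform(X)
    assert out.shape == X.shape
    assert (tr.size_factors_ > 0).all()


# ---------------------------------------------------------------------------
# gene filters
# ---------------------------------------------------------------------------


def test_low_expresser_threshold_semantics():
    # 100 samples; gene TPM >= 1 in exactly 2% of samples -> kept
    n = 100
    genes = ["hi", "borderline", "zero", "low"]
    lengths = pd.Series([1000.0] * 4, index=genes)
    counts = pd.DataFrame(0.0, index=genes, columns=[f"s{i}" for i in range(n)])
    counts.loc["hi"] = 1000.0
    counts.loc["borderline", ["s0", "s1"]] = 1000.0  # TPM >= 1 in 2 samples
    counts.loc["low", "s0"] = 1000.0  # TPM >= 1 in exactly 1 sample (1%)
    mask = flag_low_expressers(counts, lengths)
    assert not mask["hi"]
    assert not mask["borderline"]
    assert mask["zero"]
    # < 1 TPM in exactly 99% of samples, not > 99% -> kept
    assert not mask["low"]


def test_batch_sensitive_spike_in_recovery():
    cfg = small_config(n_genes=2000, plate_sd=0.05, seed=17)
    rep = simulate_replicate_plates(cfg, n_plates=8)
    rng = np.random.default_rng(0)
    counts = rep.counts.copy().astype(float)
    spiked = list(counts.index[100:150])  # 50 genes, gene x plate interaction noise
    for plate, grp in rep.clinical.groupby("plate"):
        noise = np.exp(rng.normal(0.0, 1.0, size=len(spiked)))
        counts.loc[spiked, grp.index] = counts.loc[spiked, grp.index].mul(noise, axis=0)
    counts = counts.round()
    seed_clin = rep.clinical
    ref = build_seed_reference(counts.iloc[:, :30], seed_clin,
                               design=["smoking_status"])
    vst, _ = normalize_counts(counts, ref)
    mask = flag_batch_sensitive(vst, rep.clinical)
    assert mask.loc[spiked].mean() >= 0.8


def test_batch_quantile_zero_flags_everything(vst, cohort):
    reps = cohort.clinical[cohort.clinical["role"] != "patient"]
    mask = flag_batch_sensitive(vst[reps.index], reps, quantile=0.0)
    assert mask.all()


def test_batch_flagging_requires_replicates(vst, cohort):
    pat = cohort.clinical[cohort.clinical["role"] == "patient"].iloc[:0]
    with pytest.raises(ValueError):
        flag_batch_sensitive(vst, pat)


def test_filter_mask_composition(cohort, vst):
    low = flag_low_expressers(cohort.counts, cohort.gene_annotation["length"])
    reps = cohort.clinical[cohort.clinical["role"] != "patient"]
    batch = flag_batch_sensitive(vst[reps.index], reps)
    mask = gene_filter_mask(low, batch)
    overlap = (mask["low_expresser"] & mask["batch_sensitive"]).sum()
    assert mask["kept"].sum() == len(mask) - mask["low_expresser"].sum() - mask[
        "batch_sensitive"
    ].sum() + overlap
    assert set(mask["reason"]) <= {"kept", "low_expresser", "batch_sensitive"}


# ---------------------------------------------------------------------------
# clinical imputation
# ---------------------------------------------------------------------------


def _toy_clinical():
    return pd.DataFrame(
        {
            "cohort": ["A"] * 4 + ["B"] * 2,
            "indication": ["within"] * 6,
            "pretest_risk": ["low"] * 4 + ["high"] * 2,
            "pack_years": [10.0, 30.0, 50.0, np.nan, 20.0, np.nan],
            "age": [60.0] * 6,
            "years_since_quit": [1.0] * 6,
            "nodule_size_cm": [2.0] * 6,
            "inhaled_med": ["yes", None, "no", "no", "yes", "no"],
            "timing": ["prior"] * 6,
        },
        index=[f"s{i}" for i in range(6)],
    )


def test_stratum_median_imputation_by_hand():
    out = impute_clinical(_toy_clinical())
    assert out.loc["s3", "pack_years"] == 30.0  # median of {10, 30, 50}
    assert out.loc["s5", "pack_years"] == 20.0  # single observed value in stratum


def test_missing_inhaled_medication_defaults_to_no():
    out = impute_clinical(_toy_clinical())
    assert out.loc["s1", "inhaled_med"] == "no"
    assert out.loc["s0", "inhaled_med"] == "yes"  # observed values untouched


def test_no_missing_values_returns_table_unchanged():
    clin = _toy_clinical().fillna({"pack_years": 1.0, "inhaled_med": "no"})
    out = impute_clinical(clin)
    pd.testing.assert_frame_equal(out, clin)


def test_missing_timing_without_model_raises():
    clin = _toy_clinical()
    clin.loc["s2", "timing"] = None
    with pytest.raises(ValueError, match="timing"):
        impute_clinical(clin)
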