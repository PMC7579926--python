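"""Post-test risk arithmetic, boundary calibration, CIs, and QC fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu
from statsmodels.stats.proportion import proportion_confint

from gsclassifier.riskstrat import (
    DecisionBoundaries,
    apply_boundaries,
    calibrate_boundaries,
    lot_bias_fit,
    optimize_down_boundary,
    optimize_up_boundary,
    posttest_metrics,
    proportion_ci,
    risk_group_metrics,
    roc_auc,
    score_variance_components,
    specificity_at_sensitivity,
)
from gsclassifier.simulate import simulate_replicate_plates
from .conftest import small_config


# ---------------------------------------------------------------------------
# post-test arithmetic
# ---------------------------------------------------------------------------


def test_posttest_down_bayes_example():
    npv, re = posttest_metrics(0.282, 0.906, 0.373, "down")
    assert round(npv * 100, 1) == 91.0
    assert round(re * 100, 1) == 29.4


def test_posttest_up_bayes_example():
    ppv, re = posttest_metrics(0.736, 0.340, 0.912, "up")
    assert round(ppv * 100, 1) == 91.5
    assert round(re * 100, 1) == 27.3


def test_posttest_zero_prevalence_gives_perfect_npv():
    npv, _ = posttest_metrics(0.0, 0.5, 0.7, "down")
    assert npv == 1.0
    npv, _ = posttest_metrics(0.0, 0.3, 0.0, "down")
    assert npv == 1.0


def test_posttest_undefined_when_nothing_restratified():
    with pytest.raises(ValueError, match="re-stratified"):
        posttest_metrics(0.5, 1.0, 0.0, "down")
    with pytest.raises(ValueError, match="re-stratified"):
        posttest_metrics(0.0, 0.5, 1.0, "up")


def test_posttest_input_validation():
    with pytest.raises(ValueError):
        posttest_metrics(1.2, 0.5, 0.5, "down")
    with pytest.raises(ValueError):
        posttest_metrics(0.5, 0.5, 0.5, "sideways")


def test_bayes_coherence_with_counted_confusion_matrix():
    """Formula values equal directly counted predictive values when there
    are no local-benign subjects."""
    rng = np.random.default_rng(0)
    scores = rng.normal(size=200) + np.repeat([0.0, 1.2], 100)
    labels = np.repeat([0, 1], 100)
    thr = 0.6
    pred = scores > thr
    sens = pred[labels == 1].mean()
    spec = (~pred[labels == 0]).mean()
    p = labels.mean()
    npv, re = posttest_metrics(p, sens, spec, "down")
    neg = ~pred
    assert npv == pytest.approx((neg & (labels == 0)).sum() / neg.sum())
    assert re == pytest.approx(neg.mean())
    ppv, re_up = posttest_metrics(p, sens, spec, "up")
    assert ppv == pytest.approx((pred & (labels == 1)).sum() / pred.sum())
    assert re_up == pytest.approx(pred.mean())


# ---------------------------------------------------------------------------
# boundary calibration
# ---------------------------------------------------------------------------


def _brute_force_down(scores, labels, min_sens):
    u = np.sort(np.unique(scores))
    cands = np.concatenate([[u[0] - 1], (u[:-1] + u[1:]) / 2 if len(u) > 1 else [], [u[-1] + 1]])
    best = None
    for t in cands:
        pred = scores > t
        sens = pred[labels == 1].mean()
        spec = (~pred[labels == 0]).mean()
        if sens >= min_sens:
            key = (spec, sens, -t)
            if best is None or key > best[0]:
                best = (key, t)
    return best[1] if best else None


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_down_boundary_matches_exhaustive_scan(seed):
    rng = np.random.default_rng(seed)
    scores = np.round(rng.normal(size=30), 2)
    labels = rng.integers(0, 2, 30)
    if len(np.unique(labels)) < 2:
        labels[0], labels[1] = 0, 1
    t, feasible = optimize_down_boundary(scores, labels, 0.9)
    brute = _brute_force_down(scores, labels, 0.9)
    if brute is None:
        assert not feasible
    else:
        assert feasible
        assert t == pytest.approx(brute)


def test_perfect_separation_down_boundary():
    scores = np.concatenate([np.zeros(10), np.ones(10)])
    labels = np.concatenate([np.zeros(10), np.ones(10)]).astype(int)
    t, feasible = optimize_down_boundary(scores, labels, 0.9)
    assert feasible
    pred = scores > t
    assert pred[labels == 1].mean() == 1.0
    assert (~pred[labels == 0]).mean() == 1.0
    npv, _ = posttest_metrics(0.5, 1.0, 1.0, "down")
    assert npv == 1.0


def test_degenerate_scores_flagged_infeasible():
    scores = np.zeros(12)
    labels = np.array([0, 1] * 6)
    _, feasible = optimize_up_boundary(scores, labels, prevalence=0.5, ppv_target=0.9)
    assert not feasible


def test_up_boundary_respects_ppv_floor():
    rng = np.random.default_rng(1)
    scores = np.concatenate([rng.normal(0, 1, 60), rng.normal(2, 1, 40)])
    labels = np.concatenate([np.zeros(60), np.ones(40)]).astype(int)
    t, feasible = optimize_up_boundary(scores, labels, prevalence=0.4, ppv_target=0.8)
    assert feasible
    pred = scores > t
    sens = pred[labels == 1].mean()
    spec = (~pred[labels == 0]).mean()
    ppv, _ = posttest_metrics(0.4, sens, spec, "up")
    assert ppv >= 0.8


def test_calibrate_boundaries_orders_thresholds():
    rng = np.random.default_rng(2)
    n = 240
    labels = rng.integers(0, 2, n)
    scores = pd.Series(labels * 1.5 + rng.normal(size=n))
    pretest = pd.Series(rng.choice(["low", "intermediate", "high"], n))
    prev = {"intermediate": 0.3, "high": 0.7}
    b = calibrate_boundaries(scores, pd.Series(labels), pretest, prev)
    assert b.b_down <= b.b_up_int


def test_incoherent_boundaries_rejected():
    with pytest.raises(ValueError):
        DecisionBoundaries(b_down=1.0, b_up_int=0.0, b_up_high=2.0)


# ---------------------------------------------------------------------------
# ROC / AUC and proportion CIs
# ---------------------------------------------------------------------------


def test_auc_with_tie_matches_mann_whitney():
    scores = np.array([0.1, 0.4, 0.35, 0.8, 0.35, 0.9])
    labels = np.array([0, 0, 1, 1, 0, 1])
    _, auc = roc_auc(scores, labels)
    u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
    assert auc == pytest.approx(u / (3 * 3))


def test_perfect_and_chance_auc():
    labels = np.array([0] * 50 + [1] * 50)
    _, auc = roc_auc(np.arange(100, dtype=float), labels)
    assert auc == 1.0
    rng = np.random.default_rng(0)
    _, auc0 = roc_auc(rng.normal(size=2000), rng.integers(0, 2, 2000))
    assert abs(auc0 - 0.5) < 0.05


def test_single_class_roc_raises():
    with pytest.raises(ValueError):
        roc_auc(np.arange(4.0), np.ones(4))


def test_clopper_pearson_four_of_four():
    lo, hi = proportion_ci(4, 4)
    assert lo == pytest.approx(0.025 ** 0.25)
    assert round(lo * 100, 1) == 39.8
    assert hi == 1.0


def test_clopper_pearson_zero_successes():
    lo, hi = proportion_ci(0, 10)
    assert lo == 0.0
    assert hi < 0.35


def test_clopper_pearson_matches_beta_oracle():
    lo, hi = proportion_ci(5, 10)
    olo, ohi = proportion_confint(5, 10, alpha=0.05, method="beta")
    assert lo == pytest.approx(olo)
    assert hi == pytest.approx(ohi)


def test_proportion_ci_input_validation():
    with pytest.raises(ValueError):
        proportion_ci(1, 0)
    with pytest.raises(ValueError):
        proportion_ci(5, 4)


# ---------------------------------------------------------------------------
# technical QC
# ---------------------------------------------------------------------------


def test_variance_components_recover_plate_effect():
    cfg = small_config(n_genes=300, n_cancer_genes=30, n_smoking_genes=20,
                       n_cohort_genes=10, n_inhaled_genes=10, n_celltype_genes=10,
                       n_chrx_genes=10, plate_sd=0.3, size_factor_sd=0.0, seed=13)
    rep = simulate_replicate_plates(cfg, n_plates=10)
    high = rep.counts.mean(axis=1) > 20
    scores = np.log(rep.counts[high.to_numpy()] + 0.5).mean(axis=0)
    out = score_variance_components(scores, rep.clinical["identity"], rep.clinical["plate"])
    assert abs(out["plate_var"] - 0.09) / 0.09 < 0.5


def test_variance_components_null_plate_effect():
    cfg = small_config(n_genes=300, n_cancer_genes=30, n_smoking_genes=20,
                       n_cohort_genes=10, n_inhaled_genes=10, n_celltype_genes=10,
                       n_chrx_genes=10, plate_sd=0.0, seed=19)
    rep = simulate_replicate_plates(cfg, n_plates=20)
    scores = np.log1p(rep.counts).mean(axis=0)
    out = score_variance_components(scores, rep.clinical["identity"], rep.clinical["plate"])
    assert out["plate_var"] <= 0.1 * max(out["residual_var"], 1e-12) + 1e-8


def test_variance_components_identical_scores_are_zero():
    idents = ["a", "b", "c"] * 4
    plates = np.repeat(["p1", "p2", "p3", "p4"], 3)
    out = score_variance_components(pd.Series(np.ones(12)), pd.Series(idents), pd.Series(plates))
    assert out["biological_var"] == 0.0
    assert out["plate_var"] == 0.0
    assert out["residual_var"] == 0.0


def test_variance_components_single_plate_raises():
    with pytest.raises(ValueError):
        score_variance_components(
            pd.Series([1.0, 2.0]), pd.Series(["a", "b"]), pd.Series(["p", "p"])
        )


def test_lot_bias_identity_and_constructed_line():
    dev = np.linspace(-2, 2, 20)
    out = lot_bias_fit(dev, dev)
    assert out["shift"] == pytest.approx(0.0, abs=1e-10)
    assert out["rotation"] == pytest.approx(1.0, abs=1e-10)
    out2 = lot_bias_fit(dev, 0.2 + 1.1 * dev)
    assert out2["shift"] == pytest.approx(0.2, abs=1e-10)
    assert out2["rotation"] == pytest.approx(1.1, abs=1e-10)


def test_lot_bias_preconditions():
    with pytest.raises(ValueError):
        lot_bias_fit([0.0, 1.0], [0.0, 1.0])
    with pytest.raises(ValueError):
        lot_bias_fit(np.ones(5), np.arange(5.0))


# ---------------------------------------------------------------------------
# risk-group application
# ---------------------------------------------------------------------------


def test_apply_boundaries_category_mapping():
    b = DecisionBoundaries(b_down=0.0, b_up_int=1.0, b_up_high=2.0)
    scores = pd.Series([-1.0, 0.5, -1.0, 0.5, 1.5, 1.0, 2.5, 1.5],
                       index=list("abcdefgh"))
    pretest = pd.Series(["low", "low", "intermediate", "intermediate",
                         "intermediate", "intermediate", "high", "high"],
                        index=list("abcdefgh"))
    out = apply_boundaries(scores, pretest, b)
    assert list(out) == ["very_low", "low", "low", "intermediate", "high",
                         "intermediate", "very_high", "high"]


def test_risk_group_metrics_excludes_local_benign_from_sens_spec():
    rng = np.random.default_rng(4)
    n = 120
    labels = pd.Series(rng.integers(0, 2, n))
    scores = pd.Series(labels * 2.0 + rng.normal(size=n))
    pretest = pd.Series(["intermediate"] * n)
    local = pd.Series([False] * n)
    local.iloc[:10] = True
    b = DecisionBoundaries(b_down=0.5, b_up_int=1.5, b_up_high=1.5)
    rows = risk_group_metrics(scores, labels, pretest, local, b)
    inter_down = [r for r in rows if r.group == "intermediate" and r.direction == "down"][0]
    adj = ~local
    n_m = int(labels[adj].sum())
    assert inter_down.n_malignant == n_m
    assert inter_down.n_local_benign == 10
    assert inter_down.prevalence == pytest.approx(n_m / n)
    npv, re = posttest_metrics(inter_down.prevalence, inter_down.sensitivity,
                               inter_down.specificity, "down")
    assert inter_down.predictive_value == pytest.approx(npv)
    assert inter_down.re_stratified == pytest.approx(re)
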