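"""Decision boundaries, post-test risk metrics, and technical-variability QC.

Post-test predictive values and re-stratified fractions follow the closed
forms (p = prevalence, computed as #malignant / (#malignant + #benign +
#local-benign); sensitivity and specificity exclude local-benign subjects):

    down-classification (low -> very low, intermediate -> low):
        %re  = (1 - p) * spec + p * (1 - sens)
        NPV  = (1 - p) * spec / %re
    up-classification (intermediate -> high, high -> very high):
        %re  = p * sens + (1 - p) * (1 - spec)
        PPV  = p * sens / %re

Decision boundaries are calibrated by an exhaustive scan over the midpoints
of consecutive unique scores: the down boundary maximizes specificity
subject to sensitivity >= 0.90; the up boundaries maximize the
up-classification rate subject to a post-test PPV floor (0.90 for the high
group, 0.65 for intermediate).  Confidence intervals for proportions are
exact Clopper-Pearson.  QC utilities estimate plate variance components on
replicated control/sentinel scores (REML) and probe-lot shift/rotation by a
paired linear fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "posttest_metrics",
    "DecisionBoundaries",
    "calibrate_boundaries",
    "specificity_at_sensitivity",
    "roc_auc",
    "proportion_ci",
    "score_variance_components",
    "lot_bias_fit",
    "RiskGroupMetrics",
    "risk_group_metrics",
    "apply_boundaries",
]


def posttest_metrics(
    p: float, sens: float, spec: float, direction: str
) -> tuple[float, float]:
    """Post-test predictive value and re-stratified fraction.

    ``direction`` is "down" (returns NPV) or "up" (returns PPV); the second
    element is the re-stratified fraction.  All inputs in [0, 1].  A zero
    re-stratified fraction leaves the predictive value undefined and raises.
    """
    for name, v in (("p", p), ("sens", sens), ("spec", spec)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} = {v} outside [0, 1]")
    if direction == "down":
        re = (1.0 - p) * spec + p * (1.0 - sens)
        if re == 0.0:
            if p == 0.0:
                # no disease: any down-classified subject is truly benign
                return 1.0, 0.0
            raise ValueError("no samples re-stratified: NPV undefined")
        return (1.0 - p) * spec / re, re
    if direction == "up":
        re = p * sens + (1.0 - p) * (1.0 - spec)
        if re == 0.0:
            raise ValueError("no samples re-stratified: PPV undefined")
        return p * sens / re, re
    raise ValueError(f"direction must be 'down' or 'up', got {direction!r}")


@dataclass
class DecisionBoundaries:
    """Calibrated score thresholds for the three re-stratification moves."""

    b_down: float
    b_up_int: float
    b_up_high: float
    feasible_down: bool = True
    feasible_up_int: bool = True
    feasible_up_high: bool = True

    def __post_init__(self):
        if self.b_down > self.b_up_int:
            raise ValueError(
                f"b_down ({self.b_down}) must not exceed b_up_int ({self.b_up_int})"
            )


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0 if len(u) > 1 else np.array([])
    return np.concatenate([[u[0] - 1.0], mids, [u[-1] + 1.0]])


def optimize_down_boundary(
    scores: np.ndarray, labels: np.ndarray, min_sensitivity: float = 0.90
) -> tuple[float, bool]:
    """Threshold maximizing specificity subject to sensitivity >= target.

    Samples with score <= threshold are down-classified (called benign);
    sensitivity = P(score > t | malignant), specificity = P(score <= t |
    benign).  Ties prefer higher sensitivity, then the lower threshold.
    Returns (threshold, feasible); when no threshold attains the target
    sensitivity the nearest-feasible (highest-sensitivity) threshold is
    returned with ``feasible=False``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required")
    best, best_key, fallback, fb_key = None, None, None, None
    for t in _candidate_thresholds(scores):
        pred_pos = scores > t
        sens = float(np.mean(pred_pos[labels == 1]))
        spec = float(np.mean(~pred_pos[labels == 0]))
        if sens >= min_sensitivity:
            key = (spec, sens, -t)
            if best is None or key > best_key:
                best, best_key = t, key
        key = (sens, spec, -t)
        if fallback is None or key > fb_key:
            fallback, fb_key = t, key
    if best is not None:
        return float(best), True
    return float(fallback), False


def optimize_up_boundary(
    scores: np.ndarray,
    labels: np.ndarray,
    prevalence: float,
    ppv_target: float,
) -> tuple[float, bool]:
    """Threshold maximizing the up-classification rate subject to a
    post-test PPV floor at the given group prevalence.

    Samples with score > threshold are up-classified.  Returns (threshold,
    feasible); infeasible targets yield the highest-PPV threshold with
    ``feasible=False`` (never a silent relaxation).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required")
    best, best_key, fallback, fb_key = None, None, None, None
    for t in _candidate_thresholds(scores):
        pred_pos = scores > t
        if not pred_pos.any():
            continue
        sens = float(np.mean(pred_pos[labels == 1]))
        spec = float(np.mean(~pred_pos[labels == 0]))
        try:
            ppv, rate = posttest_metrics(prevalence, sens, spec, "up")
        except ValueError:
            continue
        if ppv >= ppv_target:
            key = (rate, ppv, t)
            if best is None or key > best_key:
                best, best_key = t, key
        key = (ppv, rate, t)
        if fallback is None or key > fb_key:
            fallback, fb_key = t, key
    if best is not None:
        return float(best), True
    if fallback is None:
        raise ValueError("scores are degenerate: no admissible threshold")
    return float(fallback), False


def calibrate_boundaries(
    scores: pd.Series,
    labels: pd.Series,
    pretest: pd.Series,
    prevalence: dict[str, float],
    min_sensitivity: float = 0.90,
    ppv_target_int: float = 0.65,
    ppv_target_high: float = 0.90,
) -> DecisionBoundaries:
    """Calibrate the three decision boundaries on their pre-test risk groups.

    The down boundary is fit on the pooled low+intermediate group; up
    boundaries on the intermediate and high groups with their respective
    post-test PPV floors, using each group's prevalence (computed with
    local-benign subjects included).
    """
    labels = pd.Series(labels).astype(int)
    low_int = pretest.isin(["low", "intermediate"]).to_numpy()
    b_down, f_down = optimize_down_boundary(
        scores[low_int].to_numpy(), labels[low_int].to_numpy(), min_sensitivity
    )
    inter = (pretest == "intermediate").to_numpy()
    b_int, f_int = optimize_up_boundary(
        scores[inter].to_numpy(), labels[inter].to_numpy(),
        prevalence["intermediate"], ppv_target_int,
    )
    high = (pretest == "high").to_numpy()
    b_high, f_high = optimize_up_boundary(
        scores[high].to_numpy(), labels[high].to_numpy(),
        prevalence["high"], ppv_target_high,
    )
    if b_down > b_int:  # incoherent ordering can only arise from infeasibility
        b_int = b_down
        f_int = False
    return DecisionBoundaries(b_down, b_int, b_high, f_down, f_int, f_high)


def specificity_at_sensitivity(
    scores: np.ndarray, labels: np.ndarray, min_sensitivity: float = 0.90
) -> tuple[float, float]:
    """Best specificity at sensitivity >= target; returns (spec, threshold)."""
    t, feasible = optimize_down_boundary(scores, labels, min_sensitivity)
    pred_pos = np.asarray(scores) > t
    labels = np.asarray(labels).astype(int)
    spec = float(np.mean(~pred_pos[labels == 0])) if feasible else 0.0
    return spec, t


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[pd.DataFrame, float]:
    """ROC points and AUC (trapezoid; equals Mann-Whitney U with ties at 1/2)."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required for ROC")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}), auc


def proportion_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact Clopper-Pearson two-sided interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"x = {x} outside [0, {n}]")
    a = (1.0 - level) / 2.0
    lower = 0.0 if x == 0 else float(beta_dist.ppf(a, x, n - x + 1))
    upper = 1.0 if x == n else float(beta_dist.ppf(1 - a, x + 1, n - x))
    return lower, upper


def score_variance_components(
    scores: pd.Series, identity: pd.Series, plate: pd.Series
) -> dict[str, float]:
    """REML variance components of replicated scores.

    Fits score ~ 1 + (1 | identity) + (1 | plate) on the crossed replicate
    design, returning biological (identity), plate and residual variances
    plus the total technical s.d. (plate + residual) as a fraction of the
    1%-trimmed score range.
    """
    df = pd.DataFrame(
        {
            "score": np.asarray(scores, dtype=float),
            "identity": np.asarray(identity).astype(str),
            "plate": np.asarray(plate).astype(str),
        }
    )
    if df["plate"].nunique() < 2:
        raise ValueError("variance components need >= 2 plates")
    if df["identity"].nunique() < 2:
        raise ValueError("variance components need >= 2 replicated identities")
    if np.allclose(df["score"].var(ddof=0), 0.0):
        return {
            "biological_var": 0.0,
            "plate_var": 0.0,
            "residual_var": 0.0,
            "technical_sd_fraction": 0.0,
        }
    import statsmodels.formula.api as smf

    df["one"] = 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "score ~ 1",
            df,
            groups="one",
            vc_formula={"identity": "0 + C(identity)", "plate": "0 + C(plate)"},
        )
        res = model.fit(reml=True, method="lbfgs", maxiter=200)
    vc = res.vcomp
    bio = float(max(vc[0], 0.0))
    pl = float(max(vc[1], 0.0))
    resid = float(max(res.scale, 0.0))
    lo, hi = np.percentile(df["score"], [1, 99])
    rng = hi - lo
    tech_sd = float(np.sqrt(pl + resid))
    return {
        "biological_var": bio,
        "plate_var": pl,
        "residual_var": resid,
        "technical_sd_fraction": tech_sd / rng if rng > 0 else np.inf,
    }


def lot_bias_fit(dev_scores: np.ndarray, new_scores: np.ndarray) -> dict[str, float]:
    """Probe-lot systematic bias: OLS fit new = shift + rotation * dev."""
    dev = np.asarray(dev_scores, dtype=float)
    new = np.asarray(new_scores, dtype=float)
    if len(dev) != len(new):
        raise ValueError("paired scores required")
    if len(dev) < 3:
        raise ValueError("at least 3 pairs required")
    if np.allclose(dev.var(ddof=0), 0.0):
        raise ValueError("development scores have zero variance")
    import statsmodels.api as sm

    X = sm.add_constant(dev)
    res = sm.OLS(new, X).fit()
    return {
        "shift": float(res.params[0]),
        "rotation": float(res.params[1]),
        "shift_se": float(res.bse[0]),
        "rotation_se": float(res.bse[1]),
    }


@dataclass
class RiskGroupMetrics:
    """Validation metrics for one pre-test risk group and direction."""

    group: str
    direction: str
    prevalence: float
    sensitivity: float
    specificity: float
    predictive_value: float
    re_stratified: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    predictive_value_ci: tuple[float, float]
    n_malignant: int
    n_benign: int
    n_local_benign: int


def _group_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    n_local_benign: int,
    threshold: float,
    direction: str,
    group: str,
) -> RiskGroupMetrics:
    pred_pos = scores > threshold
    labels = labels.astype(int)
    n_m = int((labels == 1).sum())
    n_b = int((labels == 0).sum())
    tp = int(pred_pos[labels == 1].sum())
    tn = int((~pred_pos[labels == 0]).sum())
    sens = tp / n_m if n_m else np.nan
    spec = tn / n_b if n_b else np.nan
    p = n_m / (n_m + n_b + n_local_benign)
    pv, re = posttest_metrics(p, sens, spec, direction)
    sens_ci = proportion_ci(tp, n_m) if n_m else (np.nan, np.nan)
    spec_ci = proportion_ci(tn, n_b) if n_b else (np.nan, np.nan)
    # predictive-value CI: propagate the exact sens/spec interval endpoints
    # at fixed prevalence (the interval-valued inputs give the extreme PVs)
    pv_lo, pv_hi = _propagate_pv_ci(p, sens_ci, spec_ci, direction)
    return RiskGroupMetrics(
        group=group,
        direction=direction,
        prevalence=p,
        sensitivity=sens,
        specificity=spec,
        predictive_value=pv,
        re_stratified=re,
        sensitivity_ci=sens_ci,
        specificity_ci=spec_ci,
        predictive_value_ci=(pv_lo, pv_hi),
        n_malignant=n_m,
        n_benign=n_b,
        n_local_benign=n_local_benign,
    )


def _propagate_pv_ci(p, sens_ci, spec_ci, direction) -> tuple[float, float]:
    vals = []
    for s in sens_ci:
        for sp in spec_ci:
            try:
                pv, _ = posttest_metrics(p, s, sp, direction)
                vals.append(pv)
            except ValueError:
                vals.append(1.0 if direction == "down" else np.nan)
    vals = [v for v in vals if np.isfinite(v)]
    return (min(vals), max(vals)) if vals else (np.nan, np.nan)


def apply_boundaries(
    scores: pd.Series, pretest: pd.Series, boundaries: DecisionBoundaries
) -> pd.Series:
    """Map ensemble scores to post-test risk categories.

    Low/intermediate subjects with score <= b_down move to very low / low;
    intermediate subjects with score > b_up_int move to high; high subjects
    with score > b_up_high move to very high; everyone else keeps their
    pre-test category.
    """
    out = []
    for s, g in zip(scores, pretest):
        if g == "low":
            out.append("very_low" if s <= boundaries.b_down else "low")
        elif g == "intermediate":
            if s <= boundaries.b_down:
                out.append("low")
            elif s > boundaries.b_up_int:
                out.append("high")
            else:
                out.append("intermediate")
        elif g == "high":
            out.append("very_high" if s > boundaries.b_up_high else "high")
        else:
            out.append(str(g))
    return pd.Series(out, index=scores.index, name="posttest_risk")


def risk_group_metrics(
    scores: pd.Series,
    labels: pd.Series,
    pretest: pd.Series,
    local_benign: pd.Series,
    boundaries: DecisionBoundaries,
) -> list[RiskGroupMetrics]:
    """Per-group validation metrics in the Table-3 layout.

    ``labels`` is 1 = malignant / 0 = benign for adjudicated subjects;
    ``local_benign`` flags subjects counted in prevalence only (excluded
    from sensitivity/specificity).
    """
    labels = pd.Series(labels).astype("Int64")
    lb = pd.Series(local_benign).astype(bool)
    rows = []
    moves = [
        ("low", "down", boundaries.b_down),
        ("intermediate", "down", boundaries.b_down),
        ("intermediate", "up", boundaries.b_up_int),
        ("high", "up", boundaries.b_up_high),
    ]
    for group, direction, thr in moves:
        in_group = (pretest == group).to_numpy()
        adjud = in_group & ~lb.to_numpy()
        if adjud.sum() == 0:
            continue
        rows.append(
            _group_metrics(
                scores[adjud].to_numpy(),
                labels[adjud].to_numpy(dtype=float),
                int((in_group & lb.to_numpy()).sum()),
                thr,
                direction,
                group,
            )
        )
    return rows
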