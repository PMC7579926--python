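"""Benign/malignant component models, their ensemble, and nested CV.

Four component models are combined by averaging probabilities:

1. *clinical-dominant*: elastic-net logistic regression on age, gender,
   pack-years and the genomic smoking index, with all pairwise interactions
   among the four;
2. *genomic-dominant*: linear SVM (Platt-calibrated) on gender, smoking
   index and a gene panel;
3. *clinical-genomic*: elastic-net logistic regression on age, gender,
   inhaled medication, collection timing and smoking index plus genes and
   clinical x gene interactions;
4. *hierarchical GLM*: an unpenalized clinical logistic stage whose logit
   enters a second elastic-net logistic stage as a fixed offset
   (coefficient 1, not re-estimated), so the genomic terms fit only risk
   unexplained by the clinical factors.

The ensemble score is logit(mean of the four probabilities), probabilities
clipped to [1e-6, 1 - 1e-6] before the logit.  Model evaluation uses
repeated balanced nested cross-validation with random hyperparameter search
and the one-standard-error rule; the selection metric is the primary
endpoint, specificity at sensitivity >= 0.9 on within-indication
low/intermediate pre-test-risk samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from ._learners import ElasticNetLogistic, PlattSVM, balanced_folds, one_se_select
from .riskstrat import specificity_at_sensitivity

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSpec",
    "DesignBuilder",
    "build_design",
    "fit_component",
    "GSCEnsemble",
    "score_ensemble",
    "CVConfig",
    "CVResult",
    "run_nested_cv",
]

PROB_CLIP = 1e-6

CLINICAL_DOMINANT_COVARIATES = ("age", "gender", "pack_years", "smoking_index")
CLINICAL_GENOMIC_COVARIATES = ("age", "gender", "inhaled_med", "timing", "smoking_index")
GENOMIC_SVM_COVARIATES = ("gender", "smoking_index")
HIERARCHICAL_STAGE1_COVARIATES = ("age", "gender", "pack_years", "smoking_index")


@dataclass(frozen=True)
class FeatureSpec:
    """Feature specification for one component model.

    ``interactions`` lists ordered (a, b) pairs of main-effect names; the
    design column is the elementwise product of the standardized mains,
    named "a:b".
    """

    clinical: tuple[str, ...] = ()
    genes: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()

    @staticmethod
    def pairwise(names) -> tuple[tuple[str, str], ...]:
        names = list(names)
        return tuple((a, b) for i, a in enumerate(names) for b in names[i + 1 :])


class DesignBuilder:
    """Numeric design matrix builder with frozen training statistics.

    Continuous mains are standardized by training mean/s.d.; binary
    categorical mains are coded 0/1 (second sorted level = 1); interaction
    columns are products of the encoded mains.  Column order is
    deterministic: clinical mains, genes, then interactions, each in spec
    order.  Unseen categories at transform time raise.
    """

    def __init__(self, spec: FeatureSpec):
        self.spec = spec

    def fit(self, table: pd.DataFrame) -> "DesignBuilder":
        self.encoders_: dict[str, tuple] = {}
        for name in (*self.spec.clinical, *self.spec.genes):
            if name not in table.columns:
                raise KeyError(f"feature {name!r} missing from input table")
            col = table[name]
            if pd.api.types.is_numeric_dtype(col):
                m = float(col.mean())
                s = float(col.std(ddof=0))
                self.encoders_[name] = ("continuous", m, s if s > 0 else 1.0)
            else:
                levels = sorted(col.astype(str).unique())
                if len(levels) > 2:
                    raise ValueError(f"covariate {name!r} has >2 levels: {levels}")
                one = levels[-1] if len(levels) == 2 else levels[0]
                self.encoders_[name] = ("binary", tuple(levels), one)
        return self

    def _encode(self, table: pd.DataFrame, name: str) -> np.ndarray:
        kind, *info = self.encoders_[name]
        col = table[name]
        if kind == "continuous":
            m, s = info
            return (col.to_numpy(dtype=float) - m) / s
        levels, one = info
        vals = col.astype(str)
        unseen = set(vals.unique()) - set(levels)
        if unseen:
            raise ValueError(f"unseen category {sorted(unseen)} for covariate {name!r}")
        return (vals == one).to_numpy(dtype=float)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {}
        for name in (*self.spec.clinical, *self.spec.genes):
            cols[name] = self._encode(table, name)
        for a, b in self.spec.interactions:
            cols[f"{a}:{b}"] = cols[a] * cols[b]
        return pd.DataFrame(cols, index=table.index)

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self.fit(table).transform(table)


def build_design(table: pd.DataFrame, spec: FeatureSpec) -> tuple[pd.DataFrame, DesignBuilder]:
    """Fit-and-transform convenience over :class:`DesignBuilder`."""
    b = DesignBuilder(spec)
    return b.fit_transform(table), b


# ---------------------------------------------------------------------------
# component models
# ---------------------------------------------------------------------------


class _ComponentBase(BaseEstimator, ClassifierMixin):
    """Shared fit/predict plumbing: spec -> design -> learner."""

    kind: str = ""

    def _spec(self) -> FeatureSpec:  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, table: pd.DataFrame, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary labels required")
        self.builder_ = DesignBuilder(self._spec()).fit(table)
        X = self.builder_.transform(table).to_numpy()
        self._fit_design(X, (y == self.classes_[1]).astype(int))
        return self

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        X = self.builder_.transform(table).to_numpy()
        p = self._proba_design(X)
        return np.column_stack([1 - p, p])

    def decision_function(self, table: pd.DataFrame) -> np.ndarray:
        p = np.clip(self.predict_proba(table)[:, 1], PROB_CLIP, 1 - PROB_CLIP)
        return np.log(p / (1 - p))

    def predict(self, table: pd.DataFrame):
        return self.classes_[(self.predict_proba(table)[:, 1] > 0.5).astype(int)]


class ClinicalDominantLR(_ComponentBase):
    """Elastic-net LR on the four clinical covariates + pairwise interactions."""

    kind = "clinical_dominant_lr"

    def __init__(self, alpha: float = 0.5, lam: float = 0.05):
        self.alpha = alpha
        self.lam = lam

    def _spec(self) -> FeatureSpec:
        return FeatureSpec(
            clinical=CLINICAL_DOMINANT_COVARIATES,
            interactions=FeatureSpec.pairwise(CLINICAL_DOMINANT_COVARIATES),
        )

    def _fit_design(self, X, y):
        self.model_ = ElasticNetLogistic(alpha=self.alpha, lam=self.lam).fit(X, y)

    def _proba_design(self, X):
        return self.model_.predict_proba(X)[:, 1]


class GenomicSVM(_ComponentBase):
    """Platt-calibrated linear SVM on gender, smoking index and genes."""

    kind = "genomic_svm"

    def __init__(self, genes: tuple[str, ...] = (), C: float = 1.0):
        self.genes = genes
        self.C = C

    def _spec(self) -> FeatureSpec:
        return FeatureSpec(clinical=GENOMIC_SVM_COVARIATES, genes=tuple(self.genes))

    def _fit_design(self, X, y):
        self.model_ = PlattSVM(C=self.C).fit(X, y)

    def _proba_design(self, X):
        return self.model_.predict_proba(X)[:, 1]


class ClinicalGenomicLR(_ComponentBase):
    """Elastic-net LR on five clinical covariates, genes, and clinical x gene
    interactions."""

    kind = "clinical_genomic_lr"

    def __init__(self, genes: tuple[str, ...] = (), alpha: float = 0.5, lam: float = 0.05):
        self.genes = genes
        self.alpha = alpha
        self.lam = lam

    def _spec(self) -> FeatureSpec:
        inter = tuple(
            (c, g) for c in CLINICAL_GENOMIC_COVARIATES for g in self.genes
        )
        return FeatureSpec(
            clinical=CLINICAL_GENOMIC_COVARIATES, genes=tuple(self.genes), interactions=inter
        )

    def _fit_design(self, X, y):
        self.model_ = ElasticNetLogistic(alpha=self.alpha, lam=self.lam).fit(X, y)

    def _proba_design(self, X):
        return self.model_.predict_proba(X)[:, 1]


class HierarchicalGLM(_ComponentBase):
    """Two-stage hierarchical logistic model.

    Stage 1 is an unpenalized logistic regression on clinical main effects;
    its linear predictor enters stage 2 as a fixed offset (coefficient 1,
    never penalized or re-estimated) in an elastic-net logistic fit over
    clinical mains and genes.  Separation in stage 1 triggers a
    ridge-stabilized fallback fit (logged).
    """

    kind = "hierarchical_glm"

    def __init__(self, genes: tuple[str, ...] = (), alpha: float = 0.5, lam: float = 0.05):
        self.genes = genes
        self.alpha = alpha
        self.lam = lam

    def _spec(self) -> FeatureSpec:
        return FeatureSpec(
            clinical=HIERARCHICAL_STAGE1_COVARIATES, genes=tuple(self.genes)
        )

    def fit(self, table: pd.DataFrame, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary labels required")
        yb = (y == self.classes_[1]).astype(int)
        self.builder_ = DesignBuilder(self._spec()).fit(table)
        X = self.builder_.transform(table)
        n_clin = len(HIERARCHICAL_STAGE1_COVARIATES)
        X1 = X.iloc[:, :n_clin].to_numpy()

        stage1 = LogisticRegression(C=np.inf, max_iter=2000)
        try:
            stage1.fit(X1, yb)
            separated = np.max(np.abs(stage1.coef_)) > 30
        except Exception:
            separated = True
        if separated:
            logger.warning("stage-1 separation detected; ridge-stabilized fallback fit")
            stage1 = LogisticRegression(C=1.0, max_iter=2000).fit(X1, yb)
        self.stage1_ = stage1
        offset = stage1.decision_function(X1)

        # stage 2: elastic-net logistic with the stage-1 logit as fixed offset
        X2 = X.to_numpy()
        self._x2_mean = X2.mean(axis=0)
        sd = X2.std(axis=0, ddof=0)
        self._x2_sd = np.where(sd > 0, sd, 1.0)
        X2s = (X2 - self._x2_mean) / self._x2_sd
        exog = sm.add_constant(X2s, has_constant="add")
        pen = np.full(exog.shape[1], self.lam)
        pen[0] = 0.0  # do not penalize the intercept
        model = sm.GLM(yb, exog, family=sm.families.Binomial(), offset=offset)
        res = model.fit_regularized(
            method="elastic_net", alpha=pen, L1_wt=float(np.clip(self.alpha, 0.0, 1.0)),
            maxiter=200,
        )
        self.stage2_params_ = np.asarray(res.params)
        return self

    def _stage1_logit(self, table: pd.DataFrame) -> np.ndarray:
        X = self.builder_.transform(table)
        n_clin = len(HIERARCHICAL_STAGE1_COVARIATES)
        return self.stage1_.decision_function(X.iloc[:, :n_clin].to_numpy())

    def decision_logit(self, table: pd.DataFrame) -> np.ndarray:
        X2 = self.builder_.transform(table).to_numpy()
        X2s = (X2 - self._x2_mean) / self._x2_sd
        exog = sm.add_constant(X2s, has_constant="add")
        return self._stage1_logit(table) + exog @ self.stage2_params_

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        from scipy.special import expit

        p = expit(self.decision_logit(table))
        return np.column_stack([1 - p, p])


_COMPONENTS = {
    "clinical_dominant_lr": ClinicalDominantLR,
    "genomic_svm": GenomicSVM,
    "clinical_genomic_lr": ClinicalGenomicLR,
    "hierarchical_glm": HierarchicalGLM,
}


def fit_component(kind: str, table: pd.DataFrame, y, **params):
    """Fit one component model by kind name."""
    if kind not in _COMPONENTS:
        raise ValueError(f"unknown component kind {kind!r}; choose from {sorted(_COMPONENTS)}")
    return _COMPONENTS[kind](**params).fit(table, y)


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------


class GSCEnsemble(BaseEstimator, ClassifierMixin):
    """Four-model clinical-genomic ensemble.

    ``X`` is a samples x features table holding the clinical covariates
    (age, gender, pack_years, inhaled_med, timing, smoking_index) together
    with normalized gene-expression columns.  The ensemble score is
    logit(mean probability) across the four components.
    """

    def __init__(
        self,
        genes_svm: tuple[str, ...] = (),
        genes_cg: tuple[str, ...] = (),
        genes_hier: tuple[str, ...] = (),
        alpha: float = 0.5,
        lam: float = 0.05,
        svm_C: float = 1.0,
    ):
        self.genes_svm = genes_svm
        self.genes_cg = genes_cg
        self.genes_hier = genes_hier
        self.alpha = alpha
        self.lam = lam
        self.svm_C = svm_C

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.components_ = {
            "clinical_dominant_lr": ClinicalDominantLR(alpha=self.alpha, lam=self.lam),
            "genomic_svm": GenomicSVM(genes=tuple(self.genes_svm), C=self.svm_C),
            "clinical_genomic_lr": ClinicalGenomicLR(
                genes=tuple(self.genes_cg), alpha=self.alpha, lam=self.lam
            ),
            "hierarchical_glm": HierarchicalGLM(
                genes=tuple(self.genes_hier), alpha=self.alpha, lam=self.lam
            ),
        }
        for name, comp in self.components_.items():
            try:
                comp.fit(X, y)
            except Exception as exc:  # noqa: BLE001 - reported with component name
                raise RuntimeError(f"component {name!r} failed to fit: {exc}") from exc
        return self

    def component_probabilities(self, X: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for name, comp in self.components_.items():
            try:
                cols[name] = comp.predict_proba(X)[:, 1]
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(f"component {name!r} failed to score: {exc}") from exc
        return pd.DataFrame(cols, index=X.index)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p = self.component_probabilities(X).mean(axis=1).to_numpy()
        return np.column_stack([1 - p, p])

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        """Ensemble score: logit of the mean component probability."""
        p = np.clip(self.predict_proba(X)[:, 1], PROB_CLIP, 1 - PROB_CLIP)
        return np.log(p / (1 - p))

    def predict(self, X: pd.DataFrame):
        return self.classes_[(self.predict_proba(X)[:, 1] > 0.5).astype(int)]


def score_ensemble(model: GSCEnsemble, X: pd.DataFrame) -> np.ndarray:
    """Module-level wrapper: ensemble logit score for samples in ``X``."""
    return model.decision_function(X)


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVConfig:
    """Repeated balanced nested CV settings."""

    n_folds: int = 5
    outer_repeats: int = 10
    inner_folds: int = 5
    search_budget: int = 50
    min_sensitivity: float = 0.9
    strata: tuple[str, ...] = ("label", "smoking_status", "timing")
    seed: int = 0


@dataclass
class CVResult:
    per_repeat_specificity: list[float]
    per_repeat_auc: list[float]
    median_specificity: float
    iqr_specificity: float
    fold_assignments: list[list[np.ndarray]]
    selected_configs: list[dict] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "median_specificity": self.median_specificity,
            "iqr_specificity": self.iqr_specificity,
            "median_auc": float(np.median(self.per_repeat_auc)),
        }


def _default_sampler(rng: np.random.Generator) -> dict:
    return {
        "alpha": float(rng.uniform(0.05, 1.0)),
        "lam": float(np.exp(rng.uniform(np.log(1e-3), np.log(0.5)))),
        "svm_C": float(np.exp(rng.uniform(np.log(1e-2), np.log(10.0)))),
    }


def run_nested_cv(
    X: pd.DataFrame,
    y,
    clinical: pd.DataFrame,
    config: CVConfig,
    model_builder,
    config_sampler=_default_sampler,
) -> CVResult:
    """Repeated balanced nested cross-validation of a model builder.

    ``model_builder(cfg)`` returns an unfitted estimator with
    ``fit(X, y)`` / ``decision_function(X)``.  Within each outer split,
    hyperparameters are tuned on an inner CV by random search; the inner
    metric is specificity at sensitivity >= ``config.min_sensitivity`` on
    pooled inner out-of-fold scores of the evaluation subset
    (within-indication, low/intermediate pre-test risk), and the
    one-standard-error rule prefers more-regularized configurations.  Each
    repeat reports that same specificity on the pooled outer out-of-fold
    scores, plus the AUC.
    """
    y = pd.Series(np.asarray(y), index=X.index)
    clin = clinical.loc[X.index]
    rng = np.random.default_rng(config.seed)
    strata = clin[list(config.strata)].astype(str).agg("|".join, axis=1)
    eligible = (
        clin["indication"].astype(str).eq("within")
        & clin["pretest_risk"].astype(str).isin(["low", "intermediate"])
    ).to_numpy()
    positive = (y == np.unique(y)[-1]).astype(int).to_numpy()

    configs = [config_sampler(rng) for _ in range(max(config.search_budget, 1))]

    per_repeat_spec, per_repeat_auc = [], []
    assignments, selected = [], []
    for rep in range(config.outer_repeats):
        folds = balanced_folds(strata, y.to_numpy(), config.n_folds, rng)
        assignments.append(folds)
        oof = np.full(len(y), np.nan)
        for test_idx in folds:
            train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
            cfg = _tune_inner(
                X, y, positive, eligible, train_idx, configs, config, model_builder, rng
            )
            selected.append(cfg)
            model = model_builder(cfg).fit(X.iloc[train_idx], y.iloc[train_idx])
            oof[test_idx] = model.decision_function(X.iloc[test_idx])
        mask = eligible & ~np.isnan(oof)
        spec, _ = specificity_at_sensitivity(
            oof[mask], positive[mask], config.min_sensitivity
        )
        per_repeat_spec.append(spec)
        per_repeat_auc.append(float(roc_auc_score(positive[mask], oof[mask])))

    q1, q3 = np.percentile(per_repeat_spec, [25, 75])
    return CVResult(
        per_repeat_specificity=per_repeat_spec,
        per_repeat_auc=per_repeat_auc,
        median_specificity=float(np.median(per_repeat_spec)),
        iqr_specificity=float(q3 - q1),
        fold_assignments=assignments,
        selected_configs=selected,
    )


def _tune_inner(X, y, positive, eligible, train_idx, configs, config, model_builder, rng):
    if len(configs) == 1:
        return configs[0]
    ytr = y.iloc[train_idx]
    inner_folds = balanced_folds(
        ytr.astype(str), ytr.to_numpy(), config.inner_folds, rng
    )
    results = []
    for cfg in configs:
        specs = []
        for in_test in inner_folds:
            in_train = np.setdiff1d(np.arange(len(train_idx)), in_test)
            gtr = train_idx[in_train]
            gte = train_idx[in_test]
            try:
                m = model_builder(cfg).fit(X.iloc[gtr], y.iloc[gtr])
                sc = m.decision_function(X.iloc[gte])
            except Exception:
                specs.append(0.0)
                continue
            mask = eligible[gte]
            if mask.sum() < 4 or len(np.unique(positive[gte][mask])) < 2:
                mask = np.ones(len(gte), dtype=bool)
            s, _ = specificity_at_sensitivity(
                sc[mask], positive[gte][mask], config.min_sensitivity
            )
            specs.append(s)
        mean = float(np.mean(specs))
        se = float(np.std(specs, ddof=1) / np.sqrt(len(specs))) if len(specs) > 1 else 0.0
        results.append({"mean": mean, "se": se, "reg": cfg.get("lam", 0.0), "cfg": cfg})
    return one_se_select(results)["cfg"]
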