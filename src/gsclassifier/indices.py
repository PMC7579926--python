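"""Genomic indexes: gender, cell-type enrichment, and the smoking index.

The *genomic gender index* verifies sample identity against clinical
annotation from raw counts of a chrY/chrX gene panel:

    index = sum_i log2(y_i + 1) / log2(sum_j x_j)

with y the chrY counts and x the chrX counts; the call is Male iff the index
exceeds the threshold (default 3.16, strict).

*Cell-type indexes* are single-sample GSEA (ssGSEA) enrichment scores of
cell-type signature gene sets (basal, ciliated, secretory, blood, immune),
computed from the within-sample expression ranking only, hence invariant to
any strictly monotone transform of the expression values.

The *genomic smoking index* is the continuous logit score of an elastic-net
logistic model of current-vs-former smoking trained on normalized
expression, with per-split DE feature selection, clustering-based feature
reduction, and nested cross-validated hyperparameter tuning.  It is used as
a continuous covariate by the benign/malignant classifiers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score

from ._learners import ElasticNetLogistic, PlattSVM, balanced_folds, one_se_select
from .features import FeatureSet, de_analysis, reduce_features

__all__ = [
    "GenderPanel",
    "genomic_gender_index",
    "ssgsea_score",
    "celltype_indexes",
    "SmokingIndexClassifier",
    "score_smoking_index",
]


@dataclass(frozen=True)
class GenderPanel:
    """chrY / chrX gene panel for the genomic gender index."""

    chry_genes: tuple[str, ...]
    chrx_genes: tuple[str, ...]
    threshold: float = 3.16

    def __post_init__(self):
        if not self.chry_genes or not self.chrx_genes:
            raise ValueError("both chrY and chrX panels must be non-empty")
        if set(self.chry_genes) & set(self.chrx_genes):
            raise ValueError("chrY and chrX panels must be disjoint")

    @classmethod
    def from_annotation(cls, annotation: pd.DataFrame, threshold: float = 3.16) -> "GenderPanel":
        chry = tuple(annotation.index[annotation["chromosome"] == "chrY"])
        chrx = tuple(annotation.index[annotation["chromosome"] == "chrX"])
        return cls(chry, chrx, threshold)


def genomic_gender_index(
    raw_counts: pd.Series, panel: GenderPanel
) -> tuple[float, str]:
    """Genomic gender index and call from raw counts.

    Returns (index, call); the call is "Male" iff the index strictly exceeds
    the panel threshold.  Requires the chrX counts to sum to at least 2 so
    the denominator is positive.
    """
    missing = [g for g in itertools.chain(panel.chry_genes, panel.chrx_genes)
               if g not in raw_counts.index]
    if missing:
        raise KeyError(f"panel genes missing from counts: {missing[:5]}")
    y = raw_counts.loc[list(panel.chry_genes)].to_numpy(dtype=float)
    x_sum = float(raw_counts.loc[list(panel.chrx_genes)].sum())
    if x_sum < 2:
        raise ValueError(f"chrX count sum {x_sum} < 2: gender index undefined")
    index = float(np.sum(np.log2(y + 1.0)) / np.log2(x_sum))
    call = "Male" if index > panel.threshold else "Female"
    return index, call


def ssgsea_score(values: pd.Series, gene_set, alpha: float = 0.25) -> float:
    """Single-sample GSEA enrichment score of ``gene_set`` in one sample.

    Genes are ranked by expression (descending; ties broken by gene-id
    order); the score is the sum over the ranked list of the difference
    between the weighted in-set ECDF (weight |rank statistic|^alpha) and the
    uniform out-of-set ECDF.  When the set covers every measured gene the
    out-of-set ECDF is undefined and the score is 0 by convention.
    """
    in_set = [g for g in gene_set if g in values.index]
    if len(in_set) == 0:
        raise ValueError("gene set does not resolve against the measured genes")
    n = len(values)
    order = sorted(values.index, key=lambda g: (-values[g], g))
    ranks = np.arange(n, 0, -1, dtype=float)  # top gene gets rank statistic n
    member = np.array([g in set(in_set) for g in order])
    n_out = int((~member).sum())
    if n_out == 0:
        return 0.0
    w = np.where(member, np.abs(ranks) ** alpha, 0.0)
    w_total = w.sum()
    p_in = np.cumsum(w) / w_total
    p_out = np.cumsum(~member) / n_out
    return float(np.sum(p_in - p_out))


def celltype_indexes(
    normalized: pd.DataFrame, signatures: dict[str, list[str]], alpha: float = 0.25
) -> pd.DataFrame:
    """ssGSEA cell-type index per sample (rows) and signature (columns)."""
    out = {}
    for name, genes in signatures.items():
        resolved = [g for g in genes if g in normalized.index]
        if not resolved:
            raise ValueError(f"signature {name!r} has no genes in the matrix")
        out[name] = [
            ssgsea_score(normalized[s], resolved, alpha=alpha) for s in normalized.columns
        ]
    return pd.DataFrame(out, index=normalized.columns)


class SmokingIndexClassifier(BaseEstimator, ClassifierMixin):
    """Current-vs-former smoking model whose logit is the smoking index.

    Training follows a three-step scheme inside each outer CV split: (1) DE
    feature selection for smoking status (FDR < ``fdr``) with gender and
    cohort in the design; (2) feature reduction retaining a proportion of
    0.1, 0.2 or 0.5 of the genes by hierarchical clustering, giving four
    candidate sets including the unreduced one; (3) elastic-net logistic
    regression and a linear SVM per set, hyperparameters tuned by inner CV
    random search with the one-standard-error rule.  The configuration with
    the best mean outer AUC is refit on all training data.  The shipped
    default hyperparameters are (alpha, lambda) = (0.129, 0.131).

    Fitted attributes: ``genes_``, ``coef_``, ``intercept_``, ``alpha_``,
    ``lambda_``, ``cv_auc_`` (per repeat, for the selected configuration),
    ``config_`` (feature option and learner chosen).
    """

    def __init__(
        self,
        alpha: float = 0.129,
        lam: float = 0.131,
        fdr: float = 0.05,
        proportions: tuple[float, ...] = (0.1, 0.2, 0.5),
        n_folds: int = 5,
        n_repeats: int = 5,
        inner_folds: int = 5,
        search_budget: int = 8,
        de_design: tuple[str, ...] = ("sex", "cohort"),
        learners: tuple[str, ...] = ("enet", "svm"),
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.lam = lam
        self.fdr = fdr
        self.proportions = proportions
        self.n_folds = n_folds
        self.n_repeats = n_repeats
        self.inner_folds = inner_folds
        self.search_budget = search_budget
        self.de_design = de_design
        self.learners = learners
        self.random_state = random_state

    # -- hyperparameter search ------------------------------------------------
    def _sample_configs(self, learner: str, rng: np.random.Generator) -> list[dict]:
        configs = []
        if learner == "enet":
            configs.append({"alpha": self.alpha, "lam": self.lam})
            for _ in range(max(self.search_budget - 1, 0)):
                configs.append(
                    {
                        "alpha": float(rng.uniform(0.05, 1.0)),
                        "lam": float(np.exp(rng.uniform(np.log(1e-3), np.log(1.0)))),
                    }
                )
        else:
            configs.append({"C": 1.0})
            for _ in range(max(self.search_budget - 1, 0)):
                configs.append({"C": float(np.exp(rng.uniform(np.log(1e-3), np.log(10.0))))})
        return configs

    @staticmethod
    def _make(learner: str, cfg: dict):
        if learner == "enet":
            return ElasticNetLogistic(alpha=cfg["alpha"], lam=cfg["lam"])
        return PlattSVM(C=cfg["C"])

    def _tune(self, Xtr: np.ndarray, ytr: np.ndarray, learner: str, rng: np.random.Generator) -> dict:
        configs = self._sample_configs(learner, rng)
        if len(configs) == 1 or self.search_budget <= 1:
            return configs[0]
        folds = balanced_folds(ytr.astype(str), ytr, min(self.inner_folds, 3 if len(ytr) < 60 else self.inner_folds), rng)
        results = []
        for cfg in configs:
            aucs = []
            for test in folds:
                tr = np.setdiff1d(np.arange(len(ytr)), test)
                try:
                    m = self._make(learner, cfg).fit(Xtr[tr], ytr[tr])
                    aucs.append(roc_auc_score((ytr[test] == m.classes_[1]).astype(int),
                                              m.decision_function(Xtr[test])))
                except Exception:
                    aucs.append(0.5)
            mean = float(np.mean(aucs))
            se = float(np.std(aucs, ddof=1) / np.sqrt(len(aucs))) if len(aucs) > 1 else 0.0
            reg = cfg.get("lam", 0.0) if learner == "enet" else -cfg.get("C", 1.0)
            results.append({"mean": mean, "se": se, "reg": reg, "cfg": cfg})
        return one_se_select(results)["cfg"]

    # -- candidate feature sets -----------------------------------------------
    def _candidate_sets(self, counts, clinical, normalized, ref, train_ids) -> dict[str, FeatureSet]:
        de = de_analysis(
            counts[train_ids], clinical, "smoking_status", list(self.de_design), ref
        )
        sig = list(de.significant(self.fdr))
        if len(sig) < 2:
            # fall back to the strongest genes so training can proceed
            sig = list(de.table.nsmallest(20, "pvalue").index)
        full = FeatureSet(genes=sig, provenance={"contrast": "smoking_status", "fdr": self.fdr})
        sets = {"full": full}
        for prop in self.proportions:
            if len(sig) >= 2:
                sets[f"reduce_{prop}"] = reduce_features(
                    normalized.loc[sig, train_ids], full, prop, de.table["pvalue"]
                )
        return sets

    # -- fitting ----------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y, *, clinical: pd.DataFrame, counts: pd.DataFrame, ref):
        """Train on normalized expression X (samples x genes).

        ``counts`` (genes x samples) and the seed reference drive the DE
        feature-selection step; ``clinical`` provides the DE design and the
        CV balancing strata (smoking status x pre-test risk x cohort).
        """
        y = pd.Series(np.asarray(y), index=X.index)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"binary smoking labels required, got {list(classes)}")
        # higher index = current smoker
        pos = "current" if "current" in classes else classes[1]
        neg = classes[classes != pos][0]
        self.classes_ = np.array([neg, pos])
        ybin = (y == pos).astype(int)
        rng = np.random.default_rng(self.random_state)
        clin = clinical.loc[X.index]
        strata = (
            y.astype(str)
            + "|" + clin["pretest_risk"].astype(str)
            + "|" + clin["cohort"].astype(str)
        )
        norm_gxs = X.T  # genes x samples

        pooled: dict[tuple[str, str], dict[int, tuple[list, list]]] = {}
        for rep in range(self.n_repeats):
            folds = balanced_folds(strata, y.to_numpy(), self.n_folds, rng)
            for test_idx in folds:
                test_ids = X.index[test_idx]
                train_ids = X.index.difference(test_ids, sort=False)
                sets = self._candidate_sets(counts, clin, norm_gxs, ref, train_ids)
                ytr = ybin.loc[train_ids].to_numpy()
                yte = ybin.loc[test_ids].to_numpy()
                for set_name, fs in sets.items():
                    Xtr = X.loc[train_ids, fs.genes].to_numpy()
                    Xte = X.loc[test_ids, fs.genes].to_numpy()
                    for learner in self.learners:
                        cfg = self._tune(Xtr, ytr, learner, rng)
                        model = self._make(learner, cfg).fit(Xtr, ytr)
                        scores = model.decision_function(Xte)
                        store = pooled.setdefault((set_name, learner), {}).setdefault(
                            rep, ([], [])
                        )
                        store[0].extend(scores)
                        store[1].extend(yte)

        summary = {}
        for key, reps in pooled.items():
            aucs = [roc_auc_score(lab, sc) for sc, lab in reps.values()]
            summary[key] = aucs
        best_key = max(summary, key=lambda k: float(np.mean(summary[k])))
        self.cv_auc_ = {f"repeat_{r}": a for r, a in enumerate(summary[best_key])}
        self.config_ = {"feature_set": best_key[0], "learner": best_key[1]}
        self.cv_auc_all_ = {f"{k[0]}/{k[1]}": list(v) for k, v in summary.items()}

        # final refit on all training data with the selected configuration
        sets = self._candidate_sets(counts, clin, norm_gxs, ref, X.index)
        fs = sets.get(best_key[0], sets["full"])
        Xall = X.loc[:, fs.genes].to_numpy()
        yall = ybin.to_numpy()
        cfg = self._tune(Xall, yall, best_key[1], rng)
        model = self._make(best_key[1], cfg).fit(Xall, yall)
        self.genes_ = list(fs.genes)
        self.coef_ = pd.Series(model.coef_[0], index=self.genes_)
        self.intercept_ = float(model.intercept_[0])
        if best_key[1] == "enet":
            self.alpha_, self.lambda_ = cfg["alpha"], cfg["lam"]
        else:
            self.alpha_, self.lambda_ = None, None
            self.svm_C_ = cfg["C"]
        self._final_model = model
        return self

    # -- scoring ----------------------------------------------------------------
    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        """Continuous smoking index (linear predictor, unbounded logit)."""
        missing = [g for g in self.genes_ if g not in X.columns]
        if missing:
            raise KeyError(f"model genes missing from input: {missing[:10]}")
        return X[self.genes_].to_numpy() @ self.coef_.to_numpy() + self.intercept_

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        from scipy.special import expit

        p = expit(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X: pd.DataFrame):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def score_smoking_index(model: SmokingIndexClassifier, normalized: pd.DataFrame | pd.Series) -> np.ndarray:
    """Continuous smoking index for one or more normalized samples.

    Accepts a samples x genes frame or a single sample Series (genes as
    index).  Raises KeyError listing any model gene absent from the input.
    """
    if isinstance(normalized, pd.Series):
        normalized = normalized.to_frame().T
    return model.decision_function(normalized)
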