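"""Genomic classifier for specimen collection timing (prior vs. after).

Whether a bronchial brushing was collected before or after other
cytology/pathology sampling shifts its cell-type composition (more basal and
blood signal, less ciliated), so timing can be predicted from expression and
used to impute the timing covariate where it was not recorded.  Input
features are restricted to genes belonging to the airway epithelial, blood
or immune cell signatures.  The decision boundary is fixed at 0.5 on the
probability scale: a sample is called "after" iff its probability strictly
exceeds 0.5.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score

from ._learners import (
    ElasticNetLogistic,
    PlattSVM,
    ProbabilityEnsemble,
    balanced_folds,
    one_se_select,
)
from .features import FeatureSet, de_analysis, reduce_features

__all__ = ["TimingClassifier", "predict_timing"]

DECISION_BOUNDARY = 0.5


class TimingClassifier(BaseEstimator, ClassifierMixin):
    """Binary prior/after collection-timing classifier.

    Four feature-selection options (no selection; DE at adjusted p < 0.05;
    DE plus clustering-based reduction at two proportions) are each fit with
    elastic-net logistic regression, a linear SVM, and their uniform
    probability ensemble; the configuration with the best cross-validated
    AUC is refit on all data.  Every candidate feature set is restricted to
    the union of the cell-type signatures; a fitted model whose genes leave
    that union is invalid by construction.
    """

    def __init__(
        self,
        fdr: float = 0.05,
        proportions: tuple[float, ...] = (0.2, 0.5),
        n_folds: int = 5,
        n_repeats: int = 10,
        search_budget: int = 8,
        inner_folds: int = 3,
        de_design: tuple[str, ...] = (),
        boundary: float = DECISION_BOUNDARY,
        random_state: int = 0,
    ):
        self.fdr = fdr
        self.proportions = proportions
        self.n_folds = n_folds
        self.n_repeats = n_repeats
        self.search_budget = search_budget
        self.inner_folds = inner_folds
        self.de_design = de_design
        self.boundary = boundary
        self.random_state = random_state

    def _learner(self, name: str, cfg: dict):
        if name == "enet":
            return ElasticNetLogistic(alpha=cfg.get("alpha", 0.5), lam=cfg.get("lam", 0.1))
        if name == "svm":
            return PlattSVM(C=cfg.get("C", 1.0))
        return ProbabilityEnsemble(
            [
                ElasticNetLogistic(alpha=cfg.get("alpha", 0.5), lam=cfg.get("lam", 0.1)),
                PlattSVM(C=cfg.get("C", 1.0)),
            ]
        )

    def _tune(self, Xtr, ytr, learner, rng) -> dict:
        configs = [{"alpha": 0.5, "lam": 0.1, "C": 1.0}]
        for _ in range(max(self.search_budget - 1, 0)):
            configs.append(
                {
                    "alpha": float(rng.uniform(0.05, 1.0)),
                    "lam": float(np.exp(rng.uniform(np.log(1e-3), np.log(1.0)))),
                    "C": float(np.exp(rng.uniform(np.log(1e-3), np.log(10.0)))),
                }
            )
        if len(configs) == 1:
            return configs[0]
        folds = balanced_folds(ytr.astype(str), ytr, self.inner_folds, rng)
        results = []
        for cfg in configs:
            aucs = []
            for test in folds:
                tr = np.setdiff1d(np.arange(len(ytr)), test)
                try:
                    m = self._learner(learner, cfg).fit(Xtr[tr], ytr[tr])
                    p = m.predict_proba(Xtr[test])[:, 1]
                    aucs.append(roc_auc_score((ytr[test] == m.classes_[1]).astype(int), p))
                except Exception:
                    aucs.append(0.5)
            mean = float(np.mean(aucs))
            se = float(np.std(aucs, ddof=1) / np.sqrt(len(aucs))) if len(aucs) > 1 else 0.0
            results.append({"mean": mean, "se": se, "reg": cfg["lam"] - cfg["C"] * 1e-6, "cfg": cfg})
        return one_se_select(results)["cfg"]

    def _candidate_sets(
        self, signature_genes, counts, clinical, normalized, ref, train_ids
    ) -> dict[str, FeatureSet]:
        sets = {"none": FeatureSet(genes=list(signature_genes), provenance={"selection": "none"})}
        if counts is not None and ref is not None:
            de = de_analysis(
                counts.loc[signature_genes, train_ids],
                clinical,
                "timing",
                list(self.de_design),
                ref,
            )
            sig = [g for g in de.significant(self.fdr)]
            if len(sig) >= 2:
                full = FeatureSet(genes=sig, provenance={"selection": "de", "fdr": self.fdr})
                sets["de"] = full
                for prop in self.proportions:
                    sets[f"de_reduce_{prop}"] = reduce_features(
                        normalized.loc[sig, train_ids], full, prop, de.table["pvalue"]
                    )
        return sets

    def fit(
        self,
        X: pd.DataFrame,
        y,
        *,
        signatures: dict[str, list[str]],
        clinical: pd.DataFrame | None = None,
        counts: pd.DataFrame | None = None,
        ref=None,
    ):
        """Train on normalized expression X (samples x genes).

        ``y`` holds 'prior'/'after' labels; ``signatures`` the cell-type
        signature gene sets whose union bounds the feature space.  Raw
        ``counts`` plus the seed reference enable the DE-based feature
        options; without them only the no-selection option is examined.
        """
        y = pd.Series(np.asarray(y), index=X.index)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"both timing classes required, got {list(classes)}")
        union = sorted(set().union(*signatures.values()))
        sig_genes = [g for g in union if g in X.columns]
        if not sig_genes:
            raise ValueError("signature-restricted feature set is empty")
        self.signature_union_ = sig_genes
        self.classes_ = classes
        rng = np.random.default_rng(self.random_state)
        norm_gxs = X.T
        clin = clinical.loc[X.index] if clinical is not None else None

        pooled: dict[tuple[str, str], dict[int, tuple[list, list]]] = {}
        for rep in range(self.n_repeats):
            folds = balanced_folds(y, y.to_numpy(), self.n_folds, rng)
            for test_idx in folds:
                test_ids = X.index[test_idx]
                train_ids = X.index.difference(test_ids, sort=False)
                clin_tr = clin if clin is not None else _timing_frame(y)
                sets = self._candidate_sets(
                    sig_genes, counts, clin_tr, norm_gxs, ref, train_ids
                )
                ytr = y.loc[train_ids].to_numpy()
                yte = (y.loc[test_ids] == "after").astype(int).to_numpy()
                for set_name, fs in sets.items():
                    Xtr = X.loc[train_ids, fs.genes].to_numpy()
                    Xte = X.loc[test_ids, fs.genes].to_numpy()
                    for learner in ("enet", "svm", "ensemble"):
                        cfg = self._tune(Xtr, ytr, learner, rng)
                        model = self._learner(learner, cfg).fit(Xtr, ytr)
                        p = model.predict_proba(Xte)[:, 1]
                        if model.classes_[1] != "after":
                            p = 1 - p
                        store = pooled.setdefault((set_name, learner), {}).setdefault(rep, ([], []))
                        store[0].extend(p)
                        store[1].extend(yte)

        summary = {k: [roc_auc_score(lab, sc) for sc, lab in reps.values()] for k, reps in pooled.items()}
        best_key = max(summary, key=lambda k: float(np.mean(summary[k])))
        self.cv_auc_ = {f"repeat_{r}": a for r, a in enumerate(summary[best_key])}
        self.config_ = {"feature_set": best_key[0], "learner": best_key[1]}

        clin_all = clin if clin is not None else _timing_frame(y)
        sets = self._candidate_sets(sig_genes, counts, clin_all, norm_gxs, ref, X.index)
        fs = sets.get(best_key[0], sets["none"])
        assert set(fs.genes) <= set(sig_genes)
        Xall = X.loc[:, fs.genes].to_numpy()
        cfg = self._tune(Xall, y.to_numpy(), best_key[1], rng)
        model = self._learner(best_key[1], cfg).fit(Xall, y.to_numpy())
        self.genes_ = list(fs.genes)
        self._final_model = model
        if hasattr(model, "coef_"):
            self.coef_ = pd.Series(model.coef_[0], index=self.genes_)
            self.intercept_ = float(model.intercept_[0])
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of collection *after* other sampling (column 1)."""
        missing = [g for g in self.genes_ if g not in X.columns]
        if missing:
            raise KeyError(f"model genes missing from input: {missing[:10]}")
        p = self._final_model.predict_proba(X[self.genes_].to_numpy())[:, 1]
        if self._final_model.classes_[1] != "after":
            p = 1 - p
        return np.column_stack([1 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """'after' iff P(after) strictly exceeds the 0.5 boundary."""
        p = self.predict_proba(X)[:, 1]
        return np.where(p > self.boundary, "after", "prior")

    def predict_timing(self, normalized_gxs: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
        """Predict from a genes x samples normalized matrix.

        Returns (probability of 'after', call) indexed by sample.
        """
        X = normalized_gxs.T
        p = self.predict_proba(X)[:, 1]
        calls = np.where(p > self.boundary, "after", "prior")
        return (
            pd.Series(p, index=X.index, name="p_after"),
            pd.Series(calls, index=X.index, name="timing"),
        )


def _timing_frame(y: pd.Series) -> pd.DataFrame:
    return pd.DataFrame({"timing": y})


def predict_timing(model: TimingClassifier, normalized_gxs: pd.DataFrame):
    """Module-level wrapper over :meth:`TimingClassifier.predict_timing`."""
    return model.predict_timing(normalized_gxs)
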