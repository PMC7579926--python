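"""Readers and writers for the pipeline's plain-text formats.

Counts travel as TSV (genes x samples) or MatrixMarket with row/column index
files; clinical tables as CSV; gene signatures as GMT; the frozen seed
reference and fitted model bundles as versioned JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .normalize import SeedReference

BUNDLE_VERSION = "1"

__all__ = [
    "read_counts_tsv",
    "read_counts_mtx",
    "read_clinical",
    "read_gmt",
    "write_gmt",
    "save_seed_reference",
    "load_seed_reference",
    "save_model",
    "load_model",
]


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_counts_mtx(path: str | Path) -> pd.DataFrame:
    """Read an MTX matrix with sibling ``.rows.txt`` / ``.cols.txt`` files."""
    path = Path(path)
    mat = scipy.io.mmread(path)
    stem = path.with_suffix("")
    rows = stem.with_suffix(".rows.txt").read_text().split()
    cols = stem.with_suffix(".cols.txt").read_text().split()
    arr = mat.toarray() if scipy.sparse.issparse(mat) else np.asarray(mat)
    return pd.DataFrame(arr, index=rows, columns=cols)


def read_clinical(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(signatures: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in signatures.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


# ---------------------------------------------------------------------------
# seed reference
# ---------------------------------------------------------------------------


def save_seed_reference(ref: SeedReference, path: str | Path) -> None:
    payload = {
        "format_version": ref.format_version,
        "gene_ids": list(ref.geo_means.index),
        "geo_means": ref.geo_means.to_numpy().tolist(),
        "trend_log_mu": ref.trend_log_mu.tolist(),
        "trend_log_disp": ref.trend_log_disp.tolist(),
        "vst_grid": ref.vst_grid.tolist(),
        "vst_values": ref.vst_values.tolist(),
        "design_covariates": list(ref.design_covariates),
        "seed_sample_ids": list(ref.seed_sample_ids),
    }
    Path(path).write_text(json.dumps(payload))


def load_seed_reference(path: str | Path) -> SeedReference:
    d = json.loads(Path(path).read_text())
    if d.get("format_version") != "1":
        raise ValueError(f"unsupported seed-reference format {d.get('format_version')!r}")
    return SeedReference(
        geo_means=pd.Series(d["geo_means"], index=pd.Index(d["gene_ids"], name="gene_id")),
        trend_log_mu=np.asarray(d["trend_log_mu"]),
        trend_log_disp=np.asarray(d["trend_log_disp"]),
        vst_grid=np.asarray(d["vst_grid"]),
        vst_values=np.asarray(d["vst_values"]),
        design_covariates=tuple(d["design_covariates"]),
        seed_sample_ids=tuple(d["seed_sample_ids"]),
    )


# ---------------------------------------------------------------------------
# model bundles (versioned JSON of the linear model state)
# ---------------------------------------------------------------------------


def _arr(x):
    return np.asarray(x).tolist()


def _learner_state(m) -> dict:
    from ._learners import ElasticNetLogistic, PlattSVM, ProbabilityEnsemble

    if isinstance(m, ElasticNetLogistic):
        return {
            "type": "enet",
            "alpha": m.alpha,
            "lam": m.lam,
            "coef": _arr(m.coef_),
            "intercept": _arr(m.intercept_),
            "classes": _arr(m.classes_),
        }
    if isinstance(m, PlattSVM):
        return {
            "type": "svm",
            "C": m.C,
            "coef": _arr(m.coef_),
            "intercept": _arr(m.intercept_),
            "platt_a": m.platt_a_,
            "platt_b": m.platt_b_,
            "classes": _arr(m.classes_),
        }
    if isinstance(m, ProbabilityEnsemble):
        return {
            "type": "ensemble",
            "members": [_learner_state(x) for x in m.members_],
            "classes": _arr(m.classes_),
        }
    raise TypeError(f"cannot serialize learner of type {type(m).__name__}")


def _learner_restore(d: dict):
    from ._learners import ElasticNetLogistic, PlattSVM, ProbabilityEnsemble

    if d["type"] == "enet":
        m = ElasticNetLogistic(alpha=d["alpha"], lam=d["lam"])
    elif d["type"] == "svm":
        m = PlattSVM(C=d["C"])
        m.platt_a_ = d["platt_a"]
        m.platt_b_ = d["platt_b"]
    elif d["type"] == "ensemble":
        members = [_learner_restore(x) for x in d["members"]]
        m = ProbabilityEnsemble(members)
        m.members_ = members
    else:
        raise ValueError(f"unknown learner type {d['type']!r}")
    if d["type"] != "ensemble":
        m.coef_ = np.asarray(d["coef"])
        m.intercept_ = np.asarray(d["intercept"])
    m.classes_ = np.asarray(d["classes"])
    return m


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted smoking-index or timing classifier to JSON."""
    from .indices import SmokingIndexClassifier
    from .timing import TimingClassifier

    if isinstance(model, SmokingIndexClassifier):
        payload = {
            "bundle_version": BUNDLE_VERSION,
            "model": "smoking_index",
            "genes": list(model.genes_),
            "coef": _arr(model.coef_),
            "intercept": model.intercept_,
            "alpha": model.alpha_,
            "lambda": model.lambda_,
            "classes": _arr(model.classes_),
            "config": model.config_,
            "cv_auc": model.cv_auc_,
        }
    elif isinstance(model, TimingClassifier):
        payload = {
            "bundle_version": BUNDLE_VERSION,
            "model": "timing",
            "genes": list(model.genes_),
            "boundary": model.boundary,
            "classes": _arr(model.classes_),
            "final": _learner_state(model._final_model),
            "config": model.config_,
            "cv_auc": model.cv_auc_,
        }
    else:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path):
    from .indices import SmokingIndexClassifier
    from .timing import TimingClassifier

    d = json.loads(Path(path).read_text())
    if d.get("bundle_version") != BUNDLE_VERSION:
        raise ValueError(f"unsupported bundle version {d.get('bundle_version')!r}")
    if d["model"] == "smoking_index":
        m = SmokingIndexClassifier()
        m.genes_ = list(d["genes"])
        m.coef_ = pd.Series(np.asarray(d["coef"]), index=m.genes_)
        m.intercept_ = float(d["intercept"])
        m.alpha_ = d["alpha"]
        m.lambda_ = d["lambda"]
        m.classes_ = np.asarray(d["classes"])
        m.config_ = d["config"]
        m.cv_auc_ = d["cv_auc"]
        return m
    if d["model"] == "timing":
        m = TimingClassifier(boundary=d["boundary"])
        m.genes_ = list(d["genes"])
        m.classes_ = np.asarray(d["classes"])
        m._final_model = _learner_restore(d["final"])
        m.config_ = d["config"]
        m.cv_auc_ = d["cv_auc"]
        return m
    raise ValueError(f"unknown model kind {d['model']!r}")
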