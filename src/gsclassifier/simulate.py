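"""Synthetic bronchial-brushing cohort simulator.

Generates negative-binomial count matrices with the covariate structure the
classifier pipeline assumes: smoking status, benign/malignant label, specimen
collection timing, cohort, inhaled-medication use and sex-chromosome effects,
plus replicated control and sentinel samples laid out on sequencing plates for
batch-effect QC.

The count model for gene g in sample s is

    K_gs ~ NB(mu_gs, disp(mu_gs)),   Var = mu + disp * mu^2
    mu_gs = sf_s * plate_s * baseline_g * 2^(sum of active covariate effects)

with a two-parameter dispersion trend disp(mu) = a0/mu + a1, the same family
the seed-reference normalization stage fits.  Specimen collection timing acts
through cell-type mixing proportions (basal and blood cell signature genes up,
ciliated down in samples collected after other sampling) rather than a flat
fold change, mirroring the mechanism seen in real brushings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "SimConfig",
    "SimCohort",
    "simulate_cohort",
    "simulate_replicate_plates",
    "write_cohort",
]

CELL_TYPES = ("basal", "ciliated", "secretory", "blood", "immune")

# baseline cell-type mixing of a brushing collected prior to other sampling,
# and the mix it drifts toward when collected after (ciliated sloughed off,
# basal exposed, bleeding adds blood cells)
_MIX_PRIOR = {"basal": 0.25, "ciliated": 0.40, "secretory": 0.20, "blood": 0.10, "immune": 0.05}
_MIX_AFTER = {"basal": 0.33, "ciliated": 0.25, "secretory": 0.20, "blood": 0.17, "immune": 0.05}


class SimConfigError(ValueError):
    """Raised for invalid simulator configuration."""


@dataclass
class SimConfig:
    """Configuration of a synthetic cohort.

    Effect sizes are log2 fold changes applied to dedicated gene blocks;
    the timing effect is a mixing-proportion shift (``timing_shift`` in
    [0, 1] interpolates between the prior-collection and after-collection
    cell mixes).  ``frac_after`` is given per cohort so the cohort-timing
    confounding of the real data (97% vs 38% collected prior) can be
    reproduced or switched off.
    """

    n_genes: int = 2000
    cohorts: tuple[str, ...] = ("AEGIS", "Registry")
    n_samples: dict[str, int] = field(default_factory=lambda: {"AEGIS": 300, "Registry": 300})
    frac_malignant: dict[str, float] = field(default_factory=lambda: {"AEGIS": 0.4, "Registry": 0.4})
    frac_current_smoker: dict[str, float] = field(default_factory=lambda: {"AEGIS": 0.45, "Registry": 0.45})
    frac_after: dict[str, float] = field(default_factory=lambda: {"AEGIS": 0.03, "Registry": 0.62})
    frac_inhaled_med: dict[str, float] = field(default_factory=lambda: {"AEGIS": 0.30, "Registry": 0.30})
    frac_male: float = 0.55

    # log2 fold changes and block sizes
    cancer_lfc: float = 1.0
    n_cancer_genes: int = 200
    smoking_lfc: float = 1.5
    n_smoking_genes: int = 150
    cohort_lfc: float = 0.5
    n_cohort_genes: int = 100
    inhaled_lfc: float = 0.75
    n_inhaled_genes: int = 100
    timing_shift: float = 1.0
    n_celltype_genes: int = 60  # per cell type

    # NB dispersion trend disp(mu) = a0/mu + a1
    disp_a0: float = 1.0
    disp_a1: float = 0.05

    # sex chromosomes
    n_chry_genes: int = 9
    n_chrx_genes: int = 60
    chry_male_mean: float = 50.0
    chry_female_mean: float = 0.1

    # plate layout (96-well plates)
    patients_per_plate: int = 87
    controls_per_plate: int = 4
    sentinels_per_plate: int = 5
    plate_sd: float = 0.1

    # auxiliary out-of-indication malignant samples (flagged, all cohorts pooled)
    n_aux_malignant: int = 0

    baseline_log_mean: float = 3.5
    baseline_log_sd: float = 1.2
    size_factor_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_malignant", "frac_current_smoker", "frac_after", "frac_inhaled_med"):
            for cohort, p in getattr(self, name).items():
                if not 0.0 <= p <= 1.0:
                    raise SimConfigError(f"{name}[{cohort}] = {p} outside [0, 1]")
        if not 0.0 <= self.frac_male <= 1.0:
            raise SimConfigError(f"frac_male = {self.frac_male} outside [0, 1]")
        if not 0.0 <= self.timing_shift <= 1.0:
            raise SimConfigError(f"timing_shift = {self.timing_shift} outside [0, 1]")
        if self.disp_a0 < 0 or self.disp_a1 <= 0:
            raise SimConfigError("dispersion trend parameters must give disp > 0")
        n_special = (
            self.n_chry_genes
            + self.n_chrx_genes
            + self.n_cancer_genes
            + self.n_smoking_genes
            + self.n_cohort_genes
            + self.n_inhaled_genes
            + len(CELL_TYPES) * self.n_celltype_genes
        )
        if n_special > self.n_genes:
            raise SimConfigError(
                f"gene blocks ({n_special}) exceed n_genes ({self.n_genes})"
            )
        for cohort in self.cohorts:
            if cohort not in self.n_samples:
                raise SimConfigError(f"n_samples missing cohort {cohort!r}")


@dataclass
class SimCohort:
    """A simulated cohort: counts, clinical covariates, ground truth.

    ``counts`` is genes x samples (integer).  ``clinical`` is indexed by
    sample id.  ``truth`` records every spiked gene with its effect type and
    signed log2 fold change; genes absent from ``truth`` carry no effect.
    ``plates`` / ``roles`` give the replicate design (role in
    {patient, control, sentinel}); replicated identities share the
    ``identity`` value in ``clinical``.
    """

    counts: pd.DataFrame
    gene_annotation: pd.DataFrame
    clinical: pd.DataFrame
    truth: pd.DataFrame
    signatures: dict[str, list[str]]
    config: SimConfig

    @property
    def plates(self) -> pd.Series:
        return self.clinical["plate"]

    @property
    def roles(self) -> pd.Series:
        return self.clinical["role"]


def _gene_annotation(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]
    chrom = np.array(["autosome"] * n, dtype=object)
    block = np.array(["none"] * n, dtype=object)
    i = 0

    def take(k: int, label: str) -> np.ndarray:
        nonlocal i
        idx = np.arange(i, i + k)
        block[idx] = label
        i += k
        return idx

    chry = take(cfg.n_chry_genes, "chrY")
    chrx = take(cfg.n_chrx_genes, "chrX")
    chrom[chry] = "chrY"
    chrom[chrx] = "chrX"
    take(cfg.n_cancer_genes, "cancer")
    take(cfg.n_smoking_genes, "smoking")
    take(cfg.n_cohort_genes, "cohort")
    take(cfg.n_inhaled_genes, "inhaled_med")
    for ct in CELL_TYPES:
        take(cfg.n_celltype_genes, f"celltype_{ct}")

    lengths = np.round(rng.lognormal(mean=7.3, sigma=0.5, size=n)).astype(int) + 200
    # autosomal chromosome labels for the remainder, purely annotation
    auto = chrom == "autosome"
    chrom[auto] = [f"chr{c}" for c in rng.integers(1, 23, size=int(auto.sum()))]
    return pd.DataFrame(
        {"chromosome": chrom, "length": lengths, "block": block},
        index=pd.Index(gene_ids, name="gene_id"),
    )


def _patient_clinical(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for cohort in cfg.cohorts:
        n = cfg.n_samples[cohort]
        for k in range(n):
            malignant = rng.random() < cfg.frac_malignant[cohort]
            current = rng.random() < cfg.frac_current_smoker[cohort]
            after = rng.random() < cfg.frac_after[cohort]
            inhaled = rng.random() < cfg.frac_inhaled_med[cohort]
            male = rng.random() < cfg.frac_male
            # physician pre-test risk correlates with the label
            probs = (0.15, 0.45, 0.40) if malignant else (0.45, 0.45, 0.10)
            risk = rng.choice(["low", "intermediate", "high"], p=probs)
            rows.append(
                {
                    "sample_id": f"{cohort}_{k:04d}",
                    "cohort": cohort,
                    "label": "malignant" if malignant else "benign",
                    "smoking_status": "current" if current else "former",
                    "timing": "after" if after else "prior",
                    "inhaled_med": "yes" if inhaled else "no",
                    "sex": "male" if male else "female",
                    "age": float(np.clip(rng.normal(63, 9), 35, 90).round(1)),
                    "pack_years": float(np.clip(rng.gamma(3.0, 13.0), 1, 150).round(1)),
                    "years_since_quit": (
                        0.0 if current else float(np.clip(rng.gamma(2.0, 6.0), 0.2, 45).round(1))
                    ),
                    "nodule_size_cm": float(np.clip(rng.lognormal(0.7, 0.5), 0.4, 8).round(2)),
                    "pretest_risk": risk,
                    "indication": "within",
                    "role": "patient",
                    "identity": f"{cohort}_{k:04d}",
                }
            )
    for k in range(cfg.n_aux_malignant):
        cohort = cfg.cohorts[k % len(cfg.cohorts)]
        current = rng.random() < cfg.frac_current_smoker[cohort]
        rows.append(
            {
                "sample_id": f"AUX_{k:04d}",
                "cohort": cohort,
                "label": "malignant",
                "smoking_status": "current" if current else "former",
                "timing": "after" if rng.random() < cfg.frac_after[cohort] else "prior",
                "inhaled_med": "yes" if rng.random() < cfg.frac_inhaled_med[cohort] else "no",
                "sex": "male" if rng.random() < cfg.frac_male else "female",
                "age": float(np.clip(rng.normal(65, 9), 35, 90).round(1)),
                "pack_years": float(np.clip(rng.gamma(3.0, 13.0), 1, 150).round(1)),
                "years_since_quit": 0.0 if current else float(np.clip(rng.gamma(2.0, 6.0), 0.2, 45).round(1)),
                "nodule_size_cm": float(np.clip(rng.lognormal(0.9, 0.5), 0.4, 8).round(2)),
                "pretest_risk": "high",
                "indication": "ooi",
                "role": "patient",
                "identity": f"AUX_{k:04d}",
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def _replicate_identities(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Fixed biological identities replicated on every plate."""
    rows = []
    specs = [("control", "CTRL", cfg.controls_per_plate), ("sentinel", "SENT", cfg.sentinels_per_plate)]
    for role, prefix, n in specs:
        for k in range(n):
            current = rng.random() < 0.5
            rows.append(
                {
                    "identity": f"{prefix}{k}",
                    "role": role,
                    "cohort": "QC",
                    "label": "benign",
                    "smoking_status": "current" if current else "former",
                    "timing": "prior",
                    "inhaled_med": "no",
                    "sex": "male" if rng.random() < 0.5 else "female",
                    "age": float(np.clip(rng.normal(60, 8), 35, 90).round(1)),
                    "pack_years": float(np.clip(rng.gamma(3.0, 13.0), 1, 150).round(1)),
                    "years_since_quit": 0.0 if current else float(np.clip(rng.gamma(2.0, 6.0), 0.2, 45).round(1)),
                    "nodule_size_cm": 1.0,
                    "pretest_risk": "intermediate",
                    "indication": "qc",
                }
            )
    return pd.DataFrame(rows)


def _log2_effects(
    cfg: SimConfig, ann: pd.DataFrame, clinical: pd.DataFrame, rng: np.random.Generator
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per gene x sample log2 multiplier matrix plus the truth table."""
    n_genes, n_samples = len(ann), len(clinical)
    log2fx = np.zeros((n_genes, n_samples))
    truth_rows = []

    def spike(block: str, indicator: np.ndarray, lfc: float, effect: str) -> None:
        idx = np.flatnonzero(ann["block"].to_numpy() == block)
        signs = np.where(np.arange(len(idx)) % 2 == 0, 1.0, -1.0)
        log2fx[np.ix_(idx, np.flatnonzero(indicator))] += (signs * lfc)[:, None]
        for j, s in zip(idx, signs):
            truth_rows.append({"gene_id": ann.index[j], "effect": effect, "log2fc": s * lfc})

    spike("cancer", (clinical["label"] == "malignant").to_numpy(), cfg.cancer_lfc, "cancer")
    spike("smoking", (clinical["smoking_status"] == "current").to_numpy(), cfg.smoking_lfc, "smoking")
    if len(cfg.cohorts) > 1:
        spike("cohort", (clinical["cohort"] == cfg.cohorts[1]).to_numpy(), cfg.cohort_lfc, "cohort")
    spike("inhaled_med", (clinical["inhaled_med"] == "yes").to_numpy(), cfg.inhaled_lfc, "inhaled_med")

    # timing: cell-type mixing shift on the signature blocks
    after = (clinical["timing"] == "after").to_numpy()
    for ct in CELL_TYPES:
        mix = _MIX_PRIOR[ct] + cfg.timing_shift * (_MIX_AFTER[ct] - _MIX_PRIOR[ct])
        lfc = float(np.log2(mix / _MIX_PRIOR[ct]))
        if lfc == 0.0:
            continue
        idx = np.flatnonzero(ann["block"].to_numpy() == f"celltype_{ct}")
        log2fx[np.ix_(idx, np.flatnonzero(after))] += lfc
        for j in idx:
            truth_rows.append({"gene_id": ann.index[j], "effect": "timing", "log2fc": lfc})

    truth = pd.DataFrame(truth_rows, columns=["gene_id", "effect", "log2fc"])
    return log2fx, truth


def _draw_counts(
    cfg: SimConfig,
    ann: pd.DataFrame,
    clinical: pd.DataFrame,
    baseline: np.ndarray,
    log2fx: np.ndarray,
    plate_effects: pd.Series,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_genes, n_samples = len(ann), len(clinical)
    sf = rng.lognormal(0.0, cfg.size_factor_sd, size=n_samples)
    plate_mult = np.exp(plate_effects.loc[clinical["plate"]].to_numpy())
    mu = baseline[:, None] * np.exp2(log2fx) * (sf * plate_mult)[None, :]

    # sex chromosomes: chrY expressed at the male mean in males, leaky in females
    chry = (ann["chromosome"] == "chrY").to_numpy()
    male = (clinical["sex"] == "male").to_numpy()
    mu[np.ix_(chry, male)] = cfg.chry_male_mean * (sf * plate_mult)[male][None, :]
    mu[np.ix_(chry, ~male)] = cfg.chry_female_mean * (sf * plate_mult)[~male][None, :]

    mu = np.maximum(mu, 1e-8)
    disp = cfg.disp_a0 / mu + cfg.disp_a1
    r = 1.0 / disp
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    return pd.DataFrame(counts, index=ann.index, columns=clinical.index)


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Simulate a full cohort with patients and per-plate control/sentinel
    replicates.

    Deterministic given ``config.seed``; identical configs give bit-identical
    count matrices.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ann = _gene_annotation(config, rng)
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=config.n_genes)

    patients = _patient_clinical(config, rng)
    n_plates = max(1, int(np.ceil(len(patients) / config.patients_per_plate)))
    plate_ids = [f"P{p:02d}" for p in range(n_plates)]
    order = rng.permutation(len(patients))
    plate_assign = np.empty(len(patients), dtype=object)
    for pos, row in enumerate(order):
        plate_assign[row] = plate_ids[pos // config.patients_per_plate]
    patients = patients.assign(plate=plate_assign)

    reps = _replicate_identities(config, rng)
    rep_rows = []
    for plate in plate_ids:
        for _, r in reps.iterrows():
            rec = r.to_dict()
            rec["sample_id"] = f"{r['identity']}_{plate}"
            rec["plate"] = plate
            rep_rows.append(rec)
    rep_clin = pd.DataFrame(rep_rows).set_index("sample_id") if rep_rows else pd.DataFrame()

    clinical = pd.concat([patients, rep_clin]) if len(rep_clin) else patients
    log2fx, truth = _log2_effects(config, ann, clinical, rng)
    plate_effects = pd.Series(
        rng.normal(0.0, config.plate_sd, size=n_plates), index=plate_ids
    )
    counts = _draw_counts(config, ann, clinical, baseline, log2fx, plate_effects, rng)

    signatures = {
        ct: list(ann.index[ann["block"] == f"celltype_{ct}"]) for ct in CELL_TYPES
    }
    return SimCohort(
        counts=counts,
        gene_annotation=ann,
        clinical=clinical,
        truth=truth,
        signatures=signatures,
        config=dataclasses.replace(config),
    )


def simulate_replicate_plates(config: SimConfig, n_plates: int) -> SimCohort:
    """Simulate only the replicated control/sentinel samples across plates.

    Each biological identity appears exactly once per plate; every sample on a
    plate shares that plate's additive log-scale effect (s.d.
    ``config.plate_sd``).  Requires at least two plates, otherwise the plate
    variance component is unidentifiable.
    """
    config.validate()
    if n_plates < 2:
        raise SimConfigError("n_plates must be >= 2 for replicate-plate designs")
    if config.controls_per_plate + config.sentinels_per_plate < 1:
        raise SimConfigError("at least one control or sentinel per plate is required")
    rng = np.random.default_rng(config.seed)
    ann = _gene_annotation(config, rng)
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=config.n_genes)

    reps = _replicate_identities(config, rng)
    plate_ids = [f"P{p:02d}" for p in range(n_plates)]
    rows = []
    for plate in plate_ids:
        for _, r in reps.iterrows():
            rec = r.to_dict()
            rec["sample_id"] = f"{r['identity']}_{plate}"
            rec["plate"] = plate
            rows.append(rec)
    clinical = pd.DataFrame(rows).set_index("sample_id")
    log2fx, truth = _log2_effects(config, ann, clinical, rng)
    plate_effects = pd.Series(rng.normal(0.0, config.plate_sd, size=n_plates), index=plate_ids)
    counts = _draw_counts(config, ann, clinical, baseline, log2fx, plate_effects, rng)
    signatures = {ct: list(ann.index[ann["block"] == f"celltype_{ct}"]) for ct in CELL_TYPES}
    return SimCohort(counts, ann, clinical, truth, signatures, dataclasses.replace(config))


def write_cohort(cohort: SimCohort, outdir: str | Path, matrix_format: str = "tsv") -> None:
    """Write a cohort to plain-text files (counts TSV or MTX, clinical CSV,
    truth TSV, signatures GMT)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if matrix_format == "tsv":
        cohort.counts.to_csv(out / "counts.tsv", sep="\t")
    elif matrix_format == "mtx":
        scipy.io.mmwrite(out / "counts.mtx", scipy.sparse.csr_matrix(cohort.counts.to_numpy()))
        (out / "counts.rows.txt").write_text("\n".join(cohort.counts.index) + "\n")
        (out / "counts.cols.txt").write_text("\n".join(cohort.counts.columns) + "\n")
    else:
        raise ValueError(f"unknown matrix format {matrix_format!r}")
    cohort.gene_annotation.to_csv(out / "genes.tsv", sep="\t")
    cohort.clinical.to_csv(out / "clinical.csv")
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "signatures.gmt", "w") as fh:
        for name, genes in cohort.signatures.items():
            fh.write("\t".join([name, f"{name} cell-type signature"] + list(genes)) + "\n")
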