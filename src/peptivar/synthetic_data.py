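"""Synthetic feature tables with the statistical structure the analysis assumes.

Every generator works on the log2 scale and exponentiates at the end: a
multiplicative measurement error model on the raw intensity scale is an
additive normal error model on the log scale, which is how log-normally
distributed MALDI-TOF/MS signals behave.  All variance parameters
(``sigma_b2`` between subjects, ``sigma_w2`` within subjects, run/replicate
components of the precision design) are therefore log2-scale variances.

Three study designs are emulated:

* a repeatability study (subjects sampled repeatedly, spots per sample) —
  defaults mirror a 20-donor urine design with 16 subjects x 2 samples plus
  4 subjects x 3, spotted in quintuplicate;
* a 5 x 5 analytical precision study (5 runs, 5 replicate spots per run);
* a case-control cohort in which disease depends on the TRUE (error-free)
  feature levels through a logistic model — the classical-error assumption
  that regression calibration and SIMEX require — while the observed table
  adds replicate noise and left-censors intensities below an sLOD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_table import FeatureTable

__all__ = [
    "RepeatabilityDesign",
    "PrecisionDesign",
    "CaseControlDesign",
    "generate_repeatability_study",
    "generate_precision_study",
    "generate_case_control_study",
    "DesignError",
    "DegenerateOutcomeError",
]

#: Histology labels with cohort-like frequencies used for synthetic phenotypes.
CONTROL_HISTOLOGY = (("no alteration", 57), ("BPH", 7), ("inflammation", 12))
CASE_HISTOLOGY = (("PCa", 55), ("ASAP", 11), ("HGPIN", 4))


class DesignError(ValueError):
    """Invalid study design parameters."""


class DegenerateOutcomeError(RuntimeError):
    """The disease model yields (essentially) a single outcome class."""


def _per_feature(value, n_features, name):
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n_features,)).copy()
    if not np.all(np.isfinite(arr)):
        raise DesignError(f"{name} must be finite")
    return arr


@dataclass
class RepeatabilityDesign:
    """Subjects sampled repeatedly; within-subject variance on the log2 scale.

    ``samples_per_subject`` may be unbalanced (list of counts); the default
    16 x 2 + 4 x 3 mirrors a urine repeatability study.  ``sigma_spot2``
    adds optional spot-level technical noise below the sample level
    (default 0: spots replicate the sample value exactly).
    """

    n_subjects: int = 20
    samples_per_subject: tuple = tuple([2] * 16 + [3] * 4)
    spots_per_sample: int = 5
    n_features: int = 10
    mu: float | np.ndarray = 10.0
    sigma_b2: float | np.ndarray = 0.170
    sigma_w2: float | np.ndarray = 0.184
    sigma_spot2: float | np.ndarray = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.spots_per_sample < 1 or self.n_features < 1:
            raise DesignError("counts must be >= 1")
        if len(self.samples_per_subject) != self.n_subjects:
            raise DesignError("samples_per_subject must list one count per subject")
        if any(s < 1 for s in self.samples_per_subject):
            raise DesignError("each subject needs >= 1 sample")
        for name in ("sigma_b2", "sigma_w2", "sigma_spot2"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise DesignError(f"{name} must be non-negative")
        self.mu = _per_feature(self.mu, self.n_features, "mu")
        self.sigma_b2 = _per_feature(self.sigma_b2, self.n_features, "sigma_b2")
        self.sigma_w2 = _per_feature(self.sigma_w2, self.n_features, "sigma_w2")
        self.sigma_spot2 = _per_feature(self.sigma_spot2, self.n_features, "sigma_spot2")


@dataclass
class PrecisionDesign:
    """Runs x replicate-spots nested design (default 5 x 5, pooled material)."""

    n_runs: int = 5
    reps_per_run: int = 5
    n_features: int = 10
    mu: float | np.ndarray = 10.0
    sigma_run2: float | np.ndarray = 0.05
    sigma_rep2: float | np.ndarray = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.n_runs < 1 or self.reps_per_run < 1 or self.n_features < 1:
            raise DesignError("counts must be >= 1")
        if np.any(np.asarray(self.sigma_run2) < 0) or np.any(np.asarray(self.sigma_rep2) < 0):
            raise DesignError("variances must be non-negative")
        self.mu = _per_feature(self.mu, self.n_features, "mu")
        self.sigma_run2 = _per_feature(self.sigma_run2, self.n_features, "sigma_run2")
        self.sigma_rep2 = _per_feature(self.sigma_rep2, self.n_features, "sigma_rep2")


@dataclass
class CaseControlDesign:
    """Case-control cohort with a logistic disease model on true levels.

    ``slod`` censors the observed intensity scale directly; alternatively
    ``lod_fraction`` places the threshold at the requested marginal
    quantile of the generated intensities.  ``n_aah`` adds subjects with
    the AAH histology label, generated like controls but excluded by the
    two-group assignment downstream.
    """

    n_cases: int = 70
    n_controls: int = 76
    n_features: int = 10
    mu: float | np.ndarray = 0.0
    sigma_b2: float | np.ndarray = 1.0
    sigma_w2: float | np.ndarray = 0.5
    beta_true: float | np.ndarray = 0.0
    alpha_true: float = 0.0
    slod: float | None = None
    lod_fraction: float | None = None
    n_aah: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1 or self.n_controls < 1 or self.n_features < 1:
            raise DesignError("counts must be >= 1")
        if np.any(np.asarray(self.sigma_b2) < 0) or np.any(np.asarray(self.sigma_w2) < 0):
            raise DesignError("variances must be non-negative")
        if self.slod is not None and self.lod_fraction is not None:
            raise DesignError("give either slod or lod_fraction, not both")
        if self.lod_fraction is not None and not (0 <= self.lod_fraction < 1):
            raise DesignError("lod_fraction must lie in [0, 1)")
        if self.n_aah < 0:
            raise DesignError("n_aah must be >= 0")
        self.mu = _per_feature(self.mu, self.n_features, "mu")
        self.sigma_b2 = _per_feature(self.sigma_b2, self.n_features, "sigma_b2")
        self.sigma_w2 = _per_feature(self.sigma_w2, self.n_features, "sigma_w2")
        self.beta_true = _per_feature(self.beta_true, self.n_features, "beta_true")


def _default_mz(n_features: int) -> np.ndarray:
    """Evenly spaced m/z grid in the analysed 1000-4000 Da window."""
    return np.linspace(1000.0, 4000.0, n_features + 2)[1:-1].round(1)


def generate_repeatability_study(design: RepeatabilityDesign) -> FeatureTable:
    """Generate a raw-intensity table from the repeatability design.

    Log2 model per feature:  value = mu + b_subject + e_sample (+ e_spot),
    with b ~ N(0, sigma_b2) and e ~ N(0, sigma_w2).  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(design.seed)
    p = design.n_features
    rows, log2_vals = [], []
    for i in range(design.n_subjects):
        b = design.mu + np.sqrt(design.sigma_b2) * rng.standard_normal(p)
        for s in range(design.samples_per_subject[i]):
            e = np.sqrt(design.sigma_w2) * rng.standard_normal(p)
            for k in range(design.spots_per_sample):
                spot_noise = (
                    np.sqrt(design.sigma_spot2) * rng.standard_normal(p)
                    if np.any(design.sigma_spot2 > 0)
                    else 0.0
                )
                rows.append({
                    "sample_id": f"S{i + 1:02d}_c{s + 1}_sp{k + 1}",
                    "subject_id": f"S{i + 1:02d}",
                    "run_id": f"S{i + 1:02d}_c{s + 1}",
                    "spot_id": f"sp{k + 1}",
                })
                log2_vals.append(b + e + spot_noise)
    values = np.exp2(np.asarray(log2_vals))
    return FeatureTable(values, _default_mz(p), pd.DataFrame(rows), state="raw")


def generate_precision_study(design: PrecisionDesign) -> FeatureTable:
    """Generate a raw-intensity runs x replicates precision table."""
    rng = np.random.default_rng(design.seed)
    p = design.n_features
    rows, log2_vals = [], []
    for r in range(design.n_runs):
        a = np.sqrt(design.sigma_run2) * rng.standard_normal(p)
        for j in range(design.reps_per_run):
            e = np.sqrt(design.sigma_rep2) * rng.standard_normal(p)
            rows.append({
                "sample_id": f"run{r + 1}_rep{j + 1}",
                "subject_id": "pool",
                "run_id": f"run{r + 1}",
                "spot_id": f"rep{j + 1}",
            })
            log2_vals.append(design.mu + a + e)
    values = np.exp2(np.asarray(log2_vals))
    return FeatureTable(values, _default_mz(p), pd.DataFrame(rows), state="raw")


def _sample_phenotype_row(rng, histology: str, outcome: int) -> dict:
    """Cohort-flavoured covariates; f/tPSA runs lower and PCA3 higher in cases."""
    age = float(np.clip(rng.normal(66.0, 7.0), 40, 90))
    tpsa = float(np.exp(rng.normal(np.log(5.5), 0.6)))
    ft_med = 8.1 if outcome == 1 else 15.0
    ft = float(np.clip(np.exp(rng.normal(np.log(ft_med), 0.45)), 1.0, 60.0))
    fpsa = tpsa * ft / 100.0
    pca3_med = 50.0 if outcome == 1 else 24.0
    pca3 = float(np.exp(rng.normal(np.log(pca3_med), 0.7)))
    creatinine = float(np.clip(rng.normal(11.0, 4.0), 1.0, 30.0))
    return {
        "histology": histology, "outcome": outcome, "age": age,
        "tpsa": tpsa, "fpsa": fpsa, "ft_psa": ft, "pca3_score": pca3,
        "creatinine": creatinine,
    }


def generate_case_control_study(design: CaseControlDesign):
    """Generate a case-control cohort: (FeatureTable, phenotype DataFrame).

    Subjects are drawn until the requested numbers of cases and controls are
    reached: true log2 levels x ~ N(mu, sigma_b2), disease via
    logit P(D=1) = alpha + sum_f beta_f x_f, observation W = 2^(x + eps)
    with eps ~ N(0, sigma_w2).  The naive slope fitted on log2(W) is
    attenuated relative to ``beta_true`` by roughly the reliability
    ICC = sigma_b2 / (sigma_b2 + sigma_w2).

    Raises
    ------
    DegenerateOutcomeError
        If one outcome class is so rare under (alpha, beta) that the
        requested counts cannot be reached within a generous draw budget.
    """
    rng = np.random.default_rng(design.seed)
    p = design.n_features
    need = {1: design.n_cases, 0: design.n_controls}
    got = {1: [], 0: []}
    budget = 400 * (design.n_cases + design.n_controls) + 1000
    drawn = 0
    sd_b = np.sqrt(design.sigma_b2)
    while (len(got[1]) < need[1] or len(got[0]) < need[0]) and drawn < budget:
        batch = 256
        x = design.mu + sd_b * rng.standard_normal((batch, p))
        logits = design.alpha_true + x @ design.beta_true
        d = (rng.random(batch) < 1.0 / (1.0 + np.exp(-logits))).astype(int)
        drawn += batch
        for xi, di in zip(x, d):
            if len(got[di]) < need[di]:
                got[di].append(xi)
    if len(got[1]) < need[1] or len(got[0]) < need[0]:
        raise DegenerateOutcomeError(
            "disease model produced (almost) only one outcome class; "
            f"after {drawn} draws: {len(got[1])} cases, {len(got[0])} controls"
        )
    # interleave deterministically: cases first then controls then AAH
    true_x, pheno_rows = [], []
    sid = 0
    for outcome, pool, labels in (
        (1, got[1], CASE_HISTOLOGY),
        (0, got[0], CONTROL_HISTOLOGY),
    ):
        names = [l for l, _ in labels]
        weights = np.array([w for _, w in labels], dtype=float)
        weights /= weights.sum()
        for xi in pool:
            sid += 1
            hist = names[rng.choice(len(names), p=weights)]
            row = _sample_phenotype_row(rng, hist, outcome)
            row["sample_id"] = row["subject_id"] = f"P{sid:04d}"
            pheno_rows.append(row)
            true_x.append(xi)
    for _ in range(design.n_aah):
        sid += 1
        xi = design.mu + sd_b * rng.standard_normal(p)
        row = _sample_phenotype_row(rng, "AAH", 0)
        row["sample_id"] = row["subject_id"] = f"P{sid:04d}"
        pheno_rows.append(row)
        true_x.append(xi)
    true_x = np.asarray(true_x)
    eps = np.sqrt(design.sigma_w2) * rng.standard_normal(true_x.shape)
    values = np.exp2(true_x + eps)
    if design.lod_fraction is not None and design.lod_fraction > 0:
        slod = float(np.quantile(values, design.lod_fraction))
    else:
        slod = design.slod if design.slod is not None else 0.0
    below = values < slod if slod > 0 else np.zeros(values.shape, dtype=bool)
    pheno = pd.DataFrame(pheno_rows)
    cols = ["sample_id", "subject_id", "histology", "outcome", "age",
            "tpsa", "fpsa", "ft_psa", "pca3_score", "creatinine"]
    pheno = pheno[cols]
    meta = pheno[["sample_id", "subject_id", "creatinine"]].copy()
    meta["group"] = pheno["histology"].to_numpy()
    table = FeatureTable(values, _default_mz(p), meta, below_lod=below, state="raw")
    table.meta.attrs["slod"] = slod
    return table, pheno
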