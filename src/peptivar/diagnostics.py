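"""Diagnostic biomarker performance metrics.

ROC AUC by the Mann-Whitney statistic with a DeLong confidence interval,
sensitivity/specificity at a cutoff with exact (Clopper-Pearson) intervals,
likelihood ratios with log-method intervals, and the urinary PCA3 score.

The ``direction`` argument states whether larger or smaller marker values
indicate disease (f/tPSA, for instance, is *lower* in prostate cancer); it
is always explicit, never inferred from the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DiagnosticMetrics",
    "roc_auc",
    "metrics_at_cutoff",
    "pca3_score",
    "DiagnosticsError",
]


class DiagnosticsError(ValueError):
    """Invalid input to a diagnostic metric computation."""


@dataclass
class DiagnosticMetrics:
    """Cutoff-based test performance with confidence intervals."""

    cutoff: float
    direction: str
    sensitivity: float
    sensitivity_ci: tuple
    specificity: float
    specificity_ci: tuple
    lr_pos: float
    lr_pos_ci: tuple
    lr_neg: float
    lr_neg_ci: tuple
    n_cases: int
    n_controls: int

    def summary(self) -> str:
        def fmt(v, ci):
            return f"{v:.3g} (95% CI {ci[0]:.3g}-{ci[1]:.3g})"

        return "\n".join([
            f"Cutoff {self.cutoff:g} ({self.direction} indicates disease); "
            f"{self.n_cases} cases, {self.n_controls} controls",
            f"  sensitivity: {fmt(self.sensitivity, self.sensitivity_ci)}",
            f"  specificity: {fmt(self.specificity, self.specificity_ci)}",
            f"  LR+: {fmt(self.lr_pos, self.lr_pos_ci)}",
            f"  LR-: {fmt(self.lr_neg, self.lr_neg_ci)}",
        ])


def _check_classes(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise DiagnosticsError("scores and labels must align")
    y = labels.astype(float)
    if not np.all(np.isin(y, [0.0, 1.0])):
        raise DiagnosticsError("labels must be binary 0/1")
    if y.min() == y.max():
        raise DiagnosticsError("both classes must be present")
    return scores, y.astype(int)


def roc_auc(scores, labels, direction: str = "greater", level: float = 0.95):
    """AUC via the Mann-Whitney statistic (ties count half), DeLong CI.

    Parameters
    ----------
    scores, labels : arrays; labels binary with 1 = diseased.
    direction : "greater" if larger scores indicate disease, else "less".

    Returns
    -------
    (auc, (low, high))
    """
    scores, y = _check_classes(scores, labels)
    if direction == "less":
        scores = -scores
    elif direction != "greater":
        raise DiagnosticsError("direction must be 'greater' or 'less'")
    cases = scores[y == 1]
    controls = scores[y == 0]
    m, n = cases.size, controls.size
    # placement values: for each case, fraction of controls it beats
    diff = cases[:, None] - controls[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    v10 = psi.mean(axis=1)          # per-case placements
    v01 = psi.mean(axis=0)          # per-control placements
    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return auc, (float(max(auc - half, 0.0)), float(min(auc + half, 1.0)))


def _clopper_pearson(successes: int, total: int, level: float = 0.95):
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, total - successes + 1))
    hi = 1.0 if successes == total else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, total - successes))
    return lo, hi


def metrics_at_cutoff(
    scores, labels, cutoff: float, direction: str = "greater", level: float = 0.95
) -> DiagnosticMetrics:
    """Sensitivity, specificity and likelihood ratios at a decision cutoff.

    A sample tests positive when its score is >= cutoff (direction
    "greater") or <= cutoff (direction "less").  Proportions get exact
    binomial intervals; the likelihood ratios

        LR+ = sens / (1 - spec),    LR- = (1 - sens) / spec

    get log-method intervals.  With perfect specificity LR+ is reported as
    infinity with a one-sided interval (and symmetrically for LR-).
    """
    scores, y = _check_classes(scores, labels)
    if direction == "greater":
        positive = scores >= cutoff
    elif direction == "less":
        positive = scores <= cutoff
    else:
        raise DiagnosticsError("direction must be 'greater' or 'less'")
    cases, controls = y == 1, y == 0
    m, n = int(cases.sum()), int(controls.sum())
    tp = int(np.sum(positive & cases))
    tn = int(np.sum(~positive & controls))
    sens, spec = tp / m, tn / n
    z = stats.norm.ppf(0.5 + level / 2.0)

    def lr_ci(lr, se_log, defined):
        if not defined or lr == 0.0:
            return (0.0, np.inf)
        return (float(lr * np.exp(-z * se_log)), float(lr * np.exp(z * se_log)))

    if spec < 1.0 and sens > 0.0:
        lr_pos = sens / (1.0 - spec)
        se_pos = np.sqrt((1.0 - sens) / (sens * m) + spec / ((1.0 - spec) * n))
        lr_pos_ci = lr_ci(lr_pos, se_pos, True)
    elif spec == 1.0:
        lr_pos, lr_pos_ci = np.inf, (0.0, np.inf)
    else:  # sens == 0
        lr_pos, lr_pos_ci = 0.0, (0.0, np.inf)
    if spec > 0.0 and sens < 1.0:
        lr_neg = (1.0 - sens) / spec
        se_neg = np.sqrt(sens / ((1.0 - sens) * m) + (1.0 - spec) / (spec * n))
        lr_neg_ci = lr_ci(lr_neg, se_neg, True)
    elif sens == 1.0:
        lr_neg, lr_neg_ci = 0.0, (0.0, np.inf)
    else:
        lr_neg, lr_neg_ci = np.inf, (0.0, np.inf)
    return DiagnosticMetrics(
        cutoff=float(cutoff),
        direction=direction,
        sensitivity=float(sens),
        sensitivity_ci=_clopper_pearson(tp, m, level),
        specificity=float(spec),
        specificity_ci=_clopper_pearson(tn, n, level),
        lr_pos=float(lr_pos),
        lr_pos_ci=lr_pos_ci,
        lr_neg=float(lr_neg),
        lr_neg_ci=lr_neg_ci,
        n_cases=m,
        n_controls=n,
    )


def pca3_score(pca3_mrna, psa_mrna):
    """Urinary PCA3 score: PCA3 mRNA / PSA mRNA x 1000."""
    pca3 = np.asarray(pca3_mrna, dtype=float)
    psa = np.asarray(psa_mrna, dtype=float)
    if np.any(psa <= 0):
        raise DiagnosticsError("PSA mRNA must be positive")
    out = pca3 / psa * 1000.0
    return float(out) if out.ndim == 0 else out
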