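"""Variance components, ICC and assay precision from replicate designs.

The reliability of a repeatedly measured feature is summarised by the
intraclass correlation coefficient

    ICC = sigma_b^2 / (sigma_b^2 + sigma_w^2),

where sigma_b^2 is the between-subject and sigma_w^2 the within-subject
variance on the analysis (log2) scale.  Under the classical measurement
error model the ICC doubles as the attenuation factor of a naive
regression slope, which is what makes it the calibration constant of
regression calibration (see :mod:`peptivar.association`).

Two model classes are provided, in the statsmodels idiom (construct from
data, ``fit()`` returns a results object with a ``summary()``):

:class:`OneWayRandomEffects`
    One-way random-effects ANOVA on possibly unbalanced subject groupings;
    method-of-moments estimators with the unbalanced design constant n0 and
    an F-based (Searle) confidence interval for the ICC.

:class:`NestedPrecisionModel`
    Two-level nested ANOVA for a runs x replicates precision design
    (e.g. 5 days x 5 spots), yielding intra- and inter-assay coefficients
    of variation on the intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarianceComponents",
    "PrecisionEstimate",
    "OneWayRandomEffects",
    "NestedPrecisionModel",
    "variance_components",
    "icc_confidence_interval",
    "assay_cv",
    "summarize_features",
    "EstimationError",
]


class EstimationError(ValueError):
    """The design does not identify the requested variance components."""


@dataclass
class VarianceComponents:
    """Point estimates from a one-way random-effects ANOVA.

    ``negative_clipped`` records that the raw between-subject moment
    estimate was negative and has been clipped to zero.
    """

    sigma_b2: float
    sigma_w2: float
    icc: float
    n_subjects: int
    group_sizes: tuple
    n0: float
    msb: float
    msw: float
    negative_clipped: bool = False

    def summary(self) -> str:
        lines = [
            "One-way random effects variance components",
            f"  subjects: {self.n_subjects}   observations: {sum(self.group_sizes)}",
            f"  sigma_b2 (between): {self.sigma_b2:.6g}"
            + ("  [clipped from negative]" if self.negative_clipped else ""),
            f"  sigma_w2 (within):  {self.sigma_w2:.6g}",
            f"  ICC: {self.icc:.4f}",
        ]
        return "\n".join(lines)


@dataclass
class PrecisionEstimate:
    """Intra-/inter-assay precision of one feature from a nested design."""

    intra_cv: float          # % within-run
    inter_cv: float          # % total (between-run + within-run)
    grand_mean: float
    sigma_run2: float
    sigma_rep2: float
    inversion_flag: bool = False  # raw between-run estimate was negative


def _groups_to_arrays(groups):
    """Accept a list of 1-D arrays, or (values, labels) pair, or DataFrame."""
    if isinstance(groups, pd.DataFrame):
        if not {"value", "subject"} <= set(groups.columns):
            raise EstimationError("DataFrame input needs 'value' and 'subject' columns")
        return [g.to_numpy(dtype=float) for _, g in groups.groupby("subject")["value"]]
    if (
        isinstance(groups, tuple)
        and len(groups) == 2
        and np.ndim(groups[0]) == 1
        and len(groups[0]) == len(groups[1])
    ):
        values = np.asarray(groups[0], dtype=float)
        labels = np.asarray(groups[1])
        return [values[labels == lab] for lab in pd.unique(labels)]
    return [np.asarray(g, dtype=float).ravel() for g in groups]


class OneWayRandomEffects:
    """One-way random-effects model  y_ij = mu + b_i + e_ij.

    b_i ~ N(0, sigma_b2) are subject effects, e_ij ~ N(0, sigma_w2) the
    within-subject (replicate) deviations.  Unbalanced group sizes are
    allowed; estimation is ANOVA method-of-moments.

    Parameters
    ----------
    groups : sequence of 1-D arrays, or (values, labels), or DataFrame
        Observations grouped by subject.
    """

    def __init__(self, groups):
        self.groups = [g for g in _groups_to_arrays(groups) if g.size > 0]
        k = len(self.groups)
        if k < 2:
            raise EstimationError("at least 2 subjects are required")
        if all(g.size < 2 for g in self.groups):
            raise EstimationError(
                "all subject groups are singletons; within-subject variance inestimable"
            )

    def fit(self) -> "OneWayRandomEffectsResults":
        groups = self.groups
        k = len(groups)
        ni = np.array([g.size for g in groups], dtype=float)
        N = ni.sum()
        grand = np.concatenate(groups).mean()
        means = np.array([g.mean() for g in groups])
        ssb = float(np.sum(ni * (means - grand) ** 2))
        ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
        msb = ssb / (k - 1)
        msw = ssw / (N - k)
        n0 = (N - np.sum(ni**2) / N) / (k - 1)
        sigma_b2_raw = (msb - msw) / n0
        clipped = sigma_b2_raw < 0
        sigma_b2 = max(sigma_b2_raw, 0.0)
        denom = sigma_b2 + msw
        icc = sigma_b2 / denom if denom > 0 else 0.0
        vc = VarianceComponents(
            sigma_b2=sigma_b2,
            sigma_w2=msw,
            icc=icc,
            n_subjects=k,
            group_sizes=tuple(int(n) for n in ni),
            n0=float(n0),
            msb=msb,
            msw=msw,
            negative_clipped=bool(clipped),
        )
        return OneWayRandomEffectsResults(self, vc)


class OneWayRandomEffectsResults:
    """Results of :class:`OneWayRandomEffects`; carries the ICC interval."""

    def __init__(self, model, vc: VarianceComponents):
        self.model = model
        self.vc = vc

    @property
    def icc(self) -> float:
        return self.vc.icc

    def icc_conf_int(self, level: float = 0.95):
        """F-based confidence interval for the ICC (Searle form).

        For unbalanced data the balanced formula is applied with the design
        constant n0 in place of the common group size.  Bounds are clipped
        to [0, 1]; the interval always contains the point estimate.
        """
        vc = self.vc
        k = vc.n_subjects
        N = int(sum(vc.group_sizes))
        df1, df2 = k - 1, N - k
        if df2 <= 0 or vc.msw <= 0:
            raise EstimationError("ICC interval requires within-subject replication")
        alpha = 1.0 - level
        F = vc.msb / vc.msw
        FL = F / stats.f.ppf(1 - alpha / 2, df1, df2)
        FU = F * stats.f.ppf(1 - alpha / 2, df2, df1)
        n0 = vc.n0
        lo = (FL - 1.0) / (FL + n0 - 1.0)
        hi = (FU - 1.0) / (FU + n0 - 1.0)
        lo = float(min(max(lo, 0.0), 1.0))
        hi = float(min(max(hi, 0.0), 1.0))
        lo = min(lo, vc.icc)
        hi = max(hi, vc.icc)
        return lo, hi

    def summary(self, level: float = 0.95) -> str:
        lo, hi = self.icc_conf_int(level)
        return self.vc.summary() + f"\n  ICC {level:.0%} CI: ({lo:.4f}, {hi:.4f})"


class NestedPrecisionModel:
    """Balanced (or mildly unbalanced) runs x replicates nested ANOVA.

    Decomposes intensity variance into between-run (sigma_run2) and
    within-run (sigma_rep2) components and reports them as coefficients of
    variation relative to the grand mean, on the (normalized, pre-log)
    intensity scale:

        intra-assay CV = 100 * sqrt(sigma_rep2) / mean
        inter-assay CV = 100 * sqrt(sigma_run2 + sigma_rep2) / mean
    """

    def __init__(self, values, runs):
        values = np.asarray(values, dtype=float)
        runs = np.asarray(runs)
        if values.shape != runs.shape:
            raise EstimationError("values and run labels must align")
        self.groups = [values[runs == r] for r in pd.unique(runs)]
        if len(self.groups) < 2:
            raise EstimationError("at least 2 runs needed for the inter-run component")
        if all(g.size < 2 for g in self.groups):
            raise EstimationError("at least one run needs >= 2 replicates")

    def fit(self) -> PrecisionEstimate:
        groups = self.groups
        a = len(groups)
        ni = np.array([g.size for g in groups], dtype=float)
        N = ni.sum()
        grand = np.concatenate(groups).mean()
        means = np.array([g.mean() for g in groups])
        ss_run = float(np.sum(ni * (means - grand) ** 2))
        ss_rep = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
        ms_run = ss_run / (a - 1)
        ms_rep = ss_rep / (N - a)
        n0 = (N - np.sum(ni**2) / N) / (a - 1)
        sigma_run2_raw = (ms_run - ms_rep) / n0
        inversion = sigma_run2_raw < 0
        sigma_run2 = max(sigma_run2_raw, 0.0)
        if grand == 0:
            raise EstimationError("grand mean is zero; CV undefined")
        intra = 100.0 * np.sqrt(ms_rep) / abs(grand)
        inter = 100.0 * np.sqrt(sigma_run2 + ms_rep) / abs(grand)
        return PrecisionEstimate(
            intra_cv=float(intra),
            inter_cv=float(inter),
            grand_mean=float(grand),
            sigma_run2=float(sigma_run2),
            sigma_rep2=float(ms_rep),
            inversion_flag=bool(inversion),
        )


# ---------------------------------------------------------------------------
# Functional surface


def variance_components(groups) -> VarianceComponents:
    """One-way random-effects variance components for one feature.

    See :class:`OneWayRandomEffects`; this is the functional shorthand.
    """
    return OneWayRandomEffects(groups).fit().vc


def icc_confidence_interval(groups, level: float = 0.95):
    """Point estimate and F-based CI for the ICC of a one-way design.

    Returns ``(icc, (low, high))``.
    """
    res = OneWayRandomEffects(groups).fit()
    return res.icc, res.icc_conf_int(level)


def assay_cv(values, runs) -> PrecisionEstimate:
    """Intra-/inter-assay CV for one feature from a runs x replicates design."""
    return NestedPrecisionModel(values, runs).fit()


def summarize_features(stats_per_feature):
    """Median and IQR of a per-feature statistic (e.g. ICC or CV).

    Quantiles use linear interpolation (numpy default, R type-7) so the
    reported IQRs are reproducible.

    Returns
    -------
    dict with ``median``, ``q25``, ``q75``, ``iqr``, ``n``.
    """
    x = np.asarray(stats_per_feature, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise EstimationError("no finite values to summarize")
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    return {
        "median": float(med),
        "q25": float(q25),
        "q75": float(q75),
        "iqr": float(q75 - q25),
        "n": int(x.size),
    }


def feature_table_icc(table, level: float = 0.95) -> pd.DataFrame:
    """Per-feature variance components / ICC for a subject-replicate table.

    Spot-level replicates (rows sharing subject_id AND a sample label in
    ``run_id``) are averaged per sample before the subject-level ANOVA, so
    the two reported components are subject-vs-sample level.

    Returns a DataFrame with columns
    ``mz, sigma_b2, sigma_w2, icc, ci_low, ci_high``.
    """
    meta = table.meta
    if "subject_id" not in meta.columns:
        raise EstimationError("feature table has no subject_id metadata")
    # average spots: one row per (subject, run/sample collection)
    key_cols = ["subject_id"] + (["run_id"] if "run_id" in meta.columns else [])
    rows = []
    for j in range(table.n_features):
        df = pd.DataFrame({
            "value": table.values[:, j],
            "subject": meta["subject_id"].to_numpy(),
        })
        if "run_id" in meta.columns:
            df["sample"] = meta["run_id"].to_numpy()
            df = df.groupby(["subject", "sample"], sort=False, as_index=False)["value"].mean()
        try:
            res = OneWayRandomEffects(
                (df["value"].to_numpy(), df["subject"].to_numpy())
            ).fit()
            lo, hi = res.icc_conf_int(level)
            rows.append((table.mz[j], res.vc.sigma_b2, res.vc.sigma_w2, res.icc, lo, hi))
        except EstimationError:
            rows.append((table.mz[j], np.nan, np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["mz", "sigma_b2", "sigma_w2", "icc", "ci_low", "ci_high"]
    )
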