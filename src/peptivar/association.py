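"""Measurement-error-corrected logistic screening of peptidomic features.

A feature measured with error attenuates its fitted log-odds slope toward
the null: under the classical (multiplicative-on-raw, additive-on-log)
error model with reliability ICC = sigma_b2/(sigma_b2+sigma_w2), the naive
univariate slope satisfies E[beta_naive] ~ ICC * beta_true.  Two
corrections are implemented:

RCAL (regression calibration)
    beta* = beta_naive / ICC, with the confidence interval obtained by
    dividing the naive Wald interval endpoints by the same ICC (Rosner's
    construction).

SIMEX (simulation and extrapolation, Cook & Stefanski)
    Additional noise of variance lambda * sigma_w2 is added to the
    predictor for a grid of lambda > 0; the mean refitted coefficient,
    as a function of the total error multiplier (1 + lambda), is
    extrapolated back to lambda = -1, i.e. zero measurement error.
    Variances are extrapolated by the difference method (mean model-based
    variance minus the between-simulation variance of the coefficients).

The model class :class:`MeasurementErrorLogit` follows the statsmodels
idiom; the module-level functions (:func:`fit_logistic`, :func:`rcal`,
:func:`simex`, :func:`bh_adjust`, :func:`univariate_screen`,
:func:`multivariate_fit`, :func:`assign_groups`) are the pipeline surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LogisticFit",
    "CorrectedFit",
    "GroupAssignment",
    "MeasurementErrorLogit",
    "fit_logistic",
    "rcal",
    "simex",
    "bh_adjust",
    "assign_groups",
    "univariate_screen",
    "multivariate_fit",
    "AssociationError",
    "ConvergenceWarning",
    "HISTOLOGY_LABELS",
]

HISTOLOGY_LABELS = (
    "no alteration", "BPH", "inflammation", "AAH", "ASAP", "HGPIN", "PCa",
)
REFERENCE_LABELS = frozenset({"no alteration", "BPH", "inflammation"})
CANCER_LABELS = frozenset({"PCa", "HGPIN", "ASAP"})
FOUR_GROUP_MAP = {
    "no alteration": "A",
    "BPH": "B",
    "inflammation": "B",
    "HGPIN": "C",
    "ASAP": "C",
    "PCa": "D",
}


class AssociationError(ValueError):
    """Invalid input to a regression or grouping operation."""


class ConvergenceWarning(UserWarning):
    """A logistic fit failed to converge or showed separation."""


# ---------------------------------------------------------------------------
# Core ML fit


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression fit.

    ``params``/``se``/``wald_p`` include the intercept at index 0; the
    scalar views ``beta``/``or_`` expose the (single) predictor coefficient
    for the univariate screens.
    """

    params: np.ndarray
    se: np.ndarray
    wald_p: np.ndarray
    converged: bool
    separated: bool
    n: int
    names: tuple

    @property
    def beta(self):
        b = self.params[1:]
        return float(b[0]) if b.size == 1 else b

    @property
    def beta_se(self):
        s = self.se[1:]
        return float(s[0]) if s.size == 1 else s

    @property
    def p(self):
        p = self.wald_p[1:]
        return float(p[0]) if p.size == 1 else p

    @property
    def or_(self):
        return np.exp(self.beta)

    def conf_int(self, level: float = 0.95):
        """Wald interval(s) for the predictor coefficient(s)."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        lo = self.params[1:] - z * self.se[1:]
        hi = self.params[1:] + z * self.se[1:]
        if lo.size == 1:
            return float(lo[0]), float(hi[0])
        return np.column_stack([lo, hi])

    def summary(self) -> str:
        lines = [
            f"Logistic regression (IRLS), n={self.n}, "
            f"converged={self.converged}, separated={self.separated}",
            f"{'term':>12} {'coef':>10} {'SE':>10} {'OR':>10} {'Wald p':>10}",
        ]
        for name, b, s, p in zip(self.names, self.params, self.se, self.wald_p):
            lines.append(
                f"{name:>12} {b:>10.4f} {s:>10.4f} {np.exp(b):>10.4f} {p:>10.4g}"
            )
        return "\n".join(lines)


def _irls(X, y, tol=1e-8, maxiter=50):
    """Newton/IRLS for the logistic likelihood.

    Returns (params, cov, converged, separated).  Separation is flagged
    when the linear predictor perfectly classifies the outcome at a large
    margin, the signature of coefficients diverging to +-infinity.
    """
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        XtW = X.T * w
        H = XtW @ X
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = X @ beta
    separated = bool(
        np.all(eta[y == 1] > 0) and np.all(eta[y == 0] < 0) and np.max(np.abs(eta)) > 15
    )
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    H = (X.T * w) @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, converged, separated


def fit_logistic(predictors, outcome, names=None, tol=1e-8, maxiter=50) -> LogisticFit:
    """Fit a logistic regression of a binary outcome on one or more predictors.

    An intercept is always included.  Non-convergence or separation is
    flagged on the returned :class:`LogisticFit` (and warned about), not
    raised: screening loops drop flagged fits.

    Parameters
    ----------
    predictors : (n,) or (n, p) array
    outcome : (n,) array of 0/1
    """
    x = np.asarray(predictors, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(outcome, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise AssociationError("predictors and outcome lengths differ")
    if not np.all(np.isin(y, [0.0, 1.0])):
        raise AssociationError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise AssociationError("both outcome classes must be present")
    if np.any(np.ptp(x, axis=0) == 0):
        raise AssociationError("constant predictor column")
    X = np.column_stack([np.ones(len(y)), x])
    params, cov, converged, separated = _irls(X, y, tol=tol, maxiter=maxiter)
    se = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore"):
        z = params / se
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    if names is None:
        names = tuple(f"x{i}" for i in range(1, x.shape[1] + 1))
    if separated or not converged:
        warnings.warn(
            "logistic fit did not converge cleanly (separation or iteration limit)",
            ConvergenceWarning,
            stacklevel=2,
        )
    return LogisticFit(
        params=params,
        se=se,
        wald_p=wald_p,
        converged=converged,
        separated=separated,
        n=int(len(y)),
        names=("intercept",) + tuple(names),
    )


# ---------------------------------------------------------------------------
# Corrections


@dataclass
class CorrectedFit:
    """Measurement-error-corrected coefficient for one predictor."""

    method: str                       # "RCAL" | "SIMEX"
    beta_star: float
    ci_star: tuple
    or_star: float
    calibration: dict = field(default_factory=dict)

    def summary(self) -> str:
        lo, hi = self.ci_star
        return (
            f"{self.method}: beta*={self.beta_star:.4f} "
            f"(95% CI {lo:.4f} to {hi:.4f}), OR*={self.or_star:.4f}"
        )


def rcal(fit: LogisticFit, icc: float, level: float = 0.95) -> CorrectedFit:
    """Regression calibration: divide the naive slope and its Wald CI by ICC."""
    if not (0.0 < icc <= 1.0):
        raise AssociationError(f"ICC must lie in (0, 1], got {icc}")
    if not fit.converged or fit.separated:
        raise AssociationError("refusing to calibrate a non-converged fit")
    if np.ndim(fit.beta) != 0:
        raise AssociationError("RCAL applies to a single-predictor fit")
    lo, hi = fit.conf_int(level)
    beta_star = fit.beta / icc
    return CorrectedFit(
        method="RCAL",
        beta_star=float(beta_star),
        ci_star=(float(lo / icc), float(hi / icc)),
        or_star=float(np.exp(beta_star)),
        calibration={"icc": float(icc), "level": level},
    )


def _quadratic_extrapolate(lams, values, target=-1.0):
    lams = np.asarray(lams, dtype=float)
    values = np.asarray(values, dtype=float)
    if lams.size < 3:
        raise AssociationError("quadratic extrapolation needs >= 3 lambda points")
    coefs = np.polyfit(lams, values, 2)
    return float(np.polyval(coefs, target))


def simex(
    predictor,
    outcome,
    sigma_w2: float,
    lambdas=(0.5, 1.0, 1.5, 2.0),
    B: int = 100,
    extrapolant: str = "quadratic",
    seed: int = 0,
    level: float = 0.95,
) -> CorrectedFit:
    """Cook-Stefanski SIMEX for a univariate logistic slope.

    For each lambda in the grid, ``B`` datasets are formed by adding
    independent N(0, lambda * sigma_w2) noise to the predictor and refit;
    the per-lambda mean coefficient (with the naive fit anchoring
    lambda = 0) is extrapolated quadratically to lambda = -1.  The variance
    is extrapolated by the difference method: tau(lambda) = mean of the
    model-based variances minus the between-simulation variance.

    With ``sigma_w2 = 0`` the naive fit is returned unchanged (as a
    SIMEX-labelled :class:`CorrectedFit`).
    """
    if sigma_w2 < 0:
        raise AssociationError("sigma_w2 must be non-negative")
    if extrapolant != "quadratic":
        raise AssociationError("only the quadratic extrapolant is implemented")
    if B < 2:
        raise AssociationError("B must be >= 2")
    lambdas = tuple(float(l) for l in lambdas)
    if any(l <= 0 for l in lambdas):
        raise AssociationError("lambda grid must be strictly positive")
    x = np.asarray(predictor, dtype=float)
    naive = fit_logistic(x, outcome)
    if not naive.converged or naive.separated:
        raise AssociationError("naive fit not converged; SIMEX aborted")
    z = stats.norm.ppf(0.5 + level / 2.0)
    if sigma_w2 == 0.0:
        lo, hi = naive.conf_int(level)
        return CorrectedFit(
            method="SIMEX",
            beta_star=naive.beta,
            ci_star=(lo, hi),
            or_star=float(np.exp(naive.beta)),
            calibration={"sigma_w2": 0.0, "lambdas": lambdas, "B": B,
                         "extrapolant": extrapolant},
        )
    rng = np.random.default_rng(seed)
    lam_points = [0.0]
    beta_means = [naive.beta]
    tau_points = [naive.beta_se**2]
    sd = np.sqrt(sigma_w2)
    for lam in lambdas:
        betas, variances = [], []
        for _ in range(B):
            xb = x + np.sqrt(lam) * sd * rng.standard_normal(x.shape)
            try:
                f = fit_logistic(xb, outcome)
            except AssociationError:
                continue
            if not f.converged or f.separated:
                continue  # drop non-convergent refits (warned inside)
            betas.append(f.beta)
            variances.append(f.beta_se**2)
        if len(betas) < 2:
            warnings.warn(
                f"SIMEX lambda={lam}: fewer than 2 convergent refits; cell dropped",
                ConvergenceWarning,
                stacklevel=2,
            )
            continue
        betas = np.asarray(betas)
        lam_points.append(lam)
        beta_means.append(float(betas.mean()))
        tau_points.append(float(np.mean(variances) - betas.var(ddof=1)))
    if len(lam_points) < 3:
        raise AssociationError("fewer than 3 usable lambda points; cannot extrapolate")
    beta_star = _quadratic_extrapolate(lam_points, beta_means)
    tau_star = _quadratic_extrapolate(lam_points, tau_points)
    se_star = float(np.sqrt(max(tau_star, 0.0)))
    return CorrectedFit(
        method="SIMEX",
        beta_star=beta_star,
        ci_star=(beta_star - z * se_star, beta_star + z * se_star),
        or_star=float(np.exp(beta_star)),
        calibration={
            "sigma_w2": float(sigma_w2),
            "lambdas": lambdas,
            "B": B,
            "extrapolant": extrapolant,
            "lambda_points": tuple(lam_points),
            "beta_means": tuple(beta_means),
            "seed": seed,
        },
    )


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise AssociationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Group assignment


@dataclass
class GroupAssignment:
    """Binary (or four-level) outcome derived from biopsy histology.

    Two-group scheme: Reference = {no alteration, BPH, inflammation} vs
    cancer lesions = {PCa, HGPIN, ASAP}; AAH is excluded.  Four-group
    scheme: A = no alteration, B = BPH + inflammation, C = HGPIN + ASAP,
    D = PCa; AAH again excluded.
    """

    outcome: np.ndarray          # int for two-group, str codes for four-group
    excluded: np.ndarray         # bool mask of excluded (AAH) samples
    scheme: str
    labels: np.ndarray

    @property
    def n_cases(self) -> int:
        if self.scheme != "two-group":
            raise AssociationError("n_cases defined for the two-group scheme only")
        return int(np.sum(self.outcome[~self.excluded] == 1))

    @property
    def n_reference(self) -> int:
        if self.scheme != "two-group":
            raise AssociationError("n_reference defined for the two-group scheme only")
        return int(np.sum(self.outcome[~self.excluded] == 0))


def assign_groups(phenotypes, scheme: str = "two-group") -> GroupAssignment:
    """Map histology labels to analysis groups.

    Parameters
    ----------
    phenotypes : DataFrame with a ``histology`` column, or a label sequence.
    scheme : "two-group" or "four-group"
    """
    if isinstance(phenotypes, pd.DataFrame):
        if "histology" not in phenotypes.columns:
            raise AssociationError("phenotype table has no 'histology' column")
        labels = phenotypes["histology"].to_numpy()
    else:
        labels = np.asarray(phenotypes)
    unknown = set(labels) - set(HISTOLOGY_LABELS)
    if unknown:
        raise AssociationError(f"unknown histology label(s): {sorted(unknown)}")
    excluded = labels == "AAH"
    if scheme == "two-group":
        outcome = np.where(np.isin(labels, list(CANCER_LABELS)), 1, 0)
        outcome = np.asarray(outcome, dtype=int)
    elif scheme == "four-group":
        outcome = np.array([FOUR_GROUP_MAP.get(l, "excluded") for l in labels])
    else:
        raise AssociationError(f"unknown scheme {scheme!r}")
    return GroupAssignment(outcome=outcome, excluded=excluded, scheme=scheme,
                           labels=labels)


# ---------------------------------------------------------------------------
# statsmodels-style model object


class MeasurementErrorLogit:
    """Logistic disease model with an error-contaminated feature predictor.

    Parameters
    ----------
    endog : (n,) binary outcome
    exog : (n,) observed predictor (log2 feature level)
    icc : float, optional
        Reliability coefficient for RCAL.
    sigma_w2 : float, optional
        Within-subject (replicate) variance of the predictor for SIMEX.
    name : str
        Predictor label used in summaries.
    """

    def __init__(self, endog, exog, icc=None, sigma_w2=None, name="feature"):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        self.icc = icc
        self.sigma_w2 = sigma_w2
        self.name = name

    def fit(self, method: str = "naive", **kwargs):
        """Fit and optionally correct; ``method`` is naive | rcal | simex."""
        naive = fit_logistic(self.exog, self.endog, names=(self.name,))
        if method == "naive":
            return MeasurementErrorLogitResults(self, naive, None)
        if method == "rcal":
            if self.icc is None:
                raise AssociationError("RCAL requires an ICC")
            return MeasurementErrorLogitResults(self, naive, rcal(naive, self.icc))
        if method == "simex":
            if self.sigma_w2 is None:
                raise AssociationError("SIMEX requires sigma_w2")
            corrected = simex(self.exog, self.endog, self.sigma_w2, **kwargs)
            return MeasurementErrorLogitResults(self, naive, corrected)
        raise AssociationError(f"unknown method {method!r}")


class MeasurementErrorLogitResults:
    def __init__(self, model, naive: LogisticFit, corrected):
        self.model = model
        self.naive = naive
        self.corrected = corrected

    @property
    def params(self):
        return self.naive.params

    def summary(self) -> str:
        out = self.naive.summary()
        if self.corrected is not None:
            out += "\n" + self.corrected.summary()
        return out


# ---------------------------------------------------------------------------
# Screens


def univariate_screen(
    table,
    outcome,
    icc_per_feature=None,
    sigma_w2_per_feature=None,
    methods=("rcal", "simex"),
    simex_kwargs=None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-feature naive fit + corrections + BH adjustment.

    ``table`` must be an sLMNLT (log2-state) :class:`FeatureTable`.  Feature
    ICC / sigma_w2 vectors may contain NaN where the error structure was not
    estimable; those features fall back to the median of the finite values,
    mirroring how a cohort analysis proceeds when only some features have
    replicate data.

    Returns one row per screened feature with columns
    ``mz, beta, se, or_, p, bh_p, beta_star_rcal, rcal_lo, rcal_hi,
    or_star_rcal, icc_used, beta_star_simex, simex_lo, simex_hi,
    or_star_simex, sigma_w2_used``; degenerate features are skipped and
    reported via a ``skipped`` attribute on the frame.
    """
    from .feature_table import FeatureTable  # local import to avoid cycle at module load

    if isinstance(table, FeatureTable):
        if table.state != "log2":
            raise AssociationError(
                f"univariate screen expects a log2 table, got state {table.state!r}"
            )
        values, mz = table.values, table.mz
    else:
        values = np.asarray(table, dtype=float)
        mz = np.arange(values.shape[1], dtype=float)
    y = np.asarray(outcome, dtype=float)
    p_feat = values.shape[1]
    icc_vec = np.full(p_feat, np.nan) if icc_per_feature is None else np.asarray(
        icc_per_feature, dtype=float)
    sw2_vec = np.full(p_feat, np.nan) if sigma_w2_per_feature is None else np.asarray(
        sigma_w2_per_feature, dtype=float)
    median_icc = np.nanmedian(icc_vec) if np.any(np.isfinite(icc_vec)) else np.nan
    median_sw2 = np.nanmedian(sw2_vec) if np.any(np.isfinite(sw2_vec)) else np.nan
    simex_kwargs = dict(simex_kwargs or {})
    rows, skipped = [], []
    for j in range(p_feat):
        x = values[:, j]
        try:
            f = fit_logistic(x, y)
        except AssociationError as exc:
            skipped.append((mz[j], str(exc)))
            continue
        if not f.converged or f.separated:
            skipped.append((mz[j], "non-convergent or separated"))
            continue
        row = {
            "mz": mz[j], "beta": f.beta, "se": f.beta_se, "or_": f.or_, "p": f.p,
        }
        if "rcal" in methods:
            icc_j = icc_vec[j] if np.isfinite(icc_vec[j]) else median_icc
            if np.isfinite(icc_j) and 0 < icc_j <= 1:
                c = rcal(f, icc_j, level)
                row.update(beta_star_rcal=c.beta_star, rcal_lo=c.ci_star[0],
                           rcal_hi=c.ci_star[1], or_star_rcal=c.or_star,
                           icc_used=icc_j)
        if "simex" in methods:
            sw2_j = sw2_vec[j] if np.isfinite(sw2_vec[j]) else median_sw2
            if np.isfinite(sw2_j) and sw2_j >= 0:
                try:
                    c = simex(x, y, sw2_j, level=level, **simex_kwargs)
                    row.update(beta_star_simex=c.beta_star, simex_lo=c.ci_star[0],
                               simex_hi=c.ci_star[1], or_star_simex=c.or_star,
                               sigma_w2_used=sw2_j)
                except AssociationError:
                    pass
        rows.append(row)
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["bh_p"] = bh_adjust(frame["p"].to_numpy())
    frame.attrs["skipped"] = skipped
    return frame


def multivariate_fit(predictors, outcome, names=None) -> LogisticFit:
    """Joint logistic fit of several selected features with Wald tests.

    Collinear predictor sets are rejected with the offending columns named.
    """
    X = np.asarray(predictors, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise AssociationError("multivariate fit needs a non-empty n x p matrix")
    n, p = X.shape
    if n <= p + 1:
        raise AssociationError(f"n={n} too small for p={p} predictors")
    if names is None:
        names = tuple(f"x{i}" for i in range(1, p + 1))
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < p:
        # identify involved columns via correlation of residuals
        corr = np.corrcoef(Xc, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise AssociationError(
            f"collinear predictors (e.g. {names[i]!r} and {names[j]!r}); "
            "remove duplicates before fitting"
        )
    return fit_logistic(X, outcome, names=names)
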