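"""The sLMNLT normalization stack and m/z feature matching.

MALDI-TOF/MS signals are label-free and only semi-quantitative: spectra
differ in overall intensity (spotting, crystallization, laser energy) and
weak peaks drop below the instrument's signal limit of detection (sLOD).
The stack implemented here — sLOD adjustment of left-censored cells,
per-spectrum median normalization, log2 transformation ("sLMNLT") — is the
combination that maximises the reliability (ICC) of repeated peptidomic
measurements.  Urine tables may alternatively be normalized by urinary
creatinine to account for dilution.

Below-LOD substitution strategies
---------------------------------
``lod_half``            replace by sLOD/2 (the default throughout).
``zero``                replace by 0 (documented pathology: breaks log2).
``richardson_ciampi``   replace by the conditional mean below the limit,
                        E(W | W < sLOD), under a log-scale normal model.
``schisterman``         replace by E(W | W > sLOD) — conditioning *above*
                        the limit, implemented literally as published.

The truncated-normal expectations are computed on the log scale with
plug-in mean/SD from the uncensored cells of each feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .feature_table import FeatureTable, FeatureTableError
from .lod_simulation import richardson_ciampi_expectation, schisterman_expectation

__all__ = [
    "LodModel",
    "estimate_slod",
    "substitute_below_lod",
    "median_normalize",
    "creatinine_normalize",
    "log2_transform",
    "slmnlt",
    "match_features",
    "NormalizationError",
]

STRATEGIES = ("lod_half", "zero", "richardson_ciampi", "schisterman")


class NormalizationError(ValueError):
    """A normalization step could not be applied to the given table."""


@dataclass
class LodModel:
    """Signal limit of detection model.

    Attributes
    ----------
    slod : float or (n_features,) array
        Intensity threshold below which a signal is indistinguishable from
        noise; global scalar or per-feature vector.
    strategy : str
        Below-LOD substitution strategy (one of :data:`STRATEGIES`).
    k : float
        Noise multiplier used at estimation time (slod = mean + k*SD).
    """

    slod: float | np.ndarray
    strategy: str = "lod_half"
    k: float = 3.0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise NormalizationError(
                f"unknown below-LOD strategy {self.strategy!r}; choose from {STRATEGIES}"
            )
        if np.any(np.asarray(self.slod) <= 0):
            raise NormalizationError("slod must be positive")


def estimate_slod(noise_intensities, k: float = 3.0, strategy: str = "lod_half") -> LodModel:
    """Estimate the signal LOD from blank/noise intensity observations.

    The threshold is ``mean(noise) + k * SD(noise)`` with ``k = 3`` by
    default, pooling all supplied per-spectrum noise readings.

    Parameters
    ----------
    noise_intensities : array-like of non-negative floats
        Noise-region intensity observations; at least two required.
    k : float
        Standard-deviation multiplier.
    strategy : str
        Substitution strategy to record on the returned :class:`LodModel`.
    """
    noise = np.asarray(noise_intensities, dtype=float)
    if noise.size < 2:
        raise NormalizationError("sLOD estimation needs at least 2 noise observations")
    if np.any(noise < 0):
        raise NormalizationError("noise intensities must be non-negative")
    slod = float(noise.mean() + k * noise.std(ddof=1))
    return LodModel(slod=slod, strategy=strategy, k=k)


def substitute_below_lod(table: FeatureTable, lod: LodModel) -> FeatureTable:
    """Replace below-LOD cells according to the model's strategy.

    Only cells flagged ``below_lod`` are touched; flags are preserved so the
    provenance of every imputed cell remains visible downstream.  For the
    truncated-normal strategies the plug-in mean/SD are estimated per
    feature from the log of the uncensored cells.
    """
    out = table.copy()
    out.with_state("lod-adjusted")
    slod = np.broadcast_to(np.asarray(lod.slod, dtype=float), (table.n_features,))
    flags = out.below_lod
    if lod.strategy == "lod_half":
        fill = np.broadcast_to(slod / 2.0, out.values.shape)
        out.values[flags] = fill[flags]
    elif lod.strategy == "zero":
        out.values[flags] = 0.0
    else:
        # log-scale normal model per feature, plug-in parameters
        for j in range(out.n_features):
            col_flags = flags[:, j]
            if not col_flags.any():
                continue
            uncens = out.values[~col_flags, j]
            uncens = uncens[np.isfinite(uncens) & (uncens > 0)]
            if uncens.size < 2:
                out.values[col_flags, j] = slod[j] / 2.0  # fall back: too few donors
                continue
            logu = np.log(uncens)
            mu, sigma = logu.mean(), logu.std(ddof=1)
            c = np.log(slod[j])
            if sigma <= 0:
                fill_log = mu
            elif lod.strategy == "richardson_ciampi":
                fill_log = richardson_ciampi_expectation(c, mu, sigma)
            else:  # schisterman
                fill_log = schisterman_expectation(c, mu, sigma)
            out.values[col_flags, j] = np.exp(fill_log)
    return out


def median_normalize(table: FeatureTable) -> FeatureTable:
    """Divide each sample's intensities by that sample's median.

    The median is taken over non-missing feature intensities only.  After
    the call every sample's median normalized intensity equals 1.
    """
    out = table.copy()
    out.with_state("median-normalized")
    med = np.nanmedian(out.values, axis=1)
    bad = ~np.isfinite(med) | (med == 0)
    if bad.any():
        culprits = out.sample_ids[bad].tolist()
        raise NormalizationError(
            f"sample median is zero or undefined for sample(s) {culprits[:5]}"
        )
    out.values = out.values / med[:, None]
    return out


def creatinine_normalize(table: FeatureTable, creatinine=None) -> FeatureTable:
    """Divide each sample's intensities by its urinary creatinine (mmol/L).

    ``creatinine`` defaults to the table's ``creatinine`` metadata column.
    Within-sample relative intensities are unchanged (pure rescaling).
    """
    out = table.copy()
    out.with_state("creatinine-normalized")
    if creatinine is None:
        if "creatinine" not in out.meta.columns:
            raise NormalizationError("no creatinine column in sample metadata")
        creatinine = out.meta["creatinine"].to_numpy()
    crea = np.asarray(creatinine, dtype=float)
    if crea.shape != (out.n_samples,):
        raise NormalizationError("one creatinine value per sample is required")
    bad = ~np.isfinite(crea) | (crea <= 0)
    if bad.any():
        culprits = out.sample_ids[bad].tolist()
        raise NormalizationError(
            f"missing or non-positive creatinine for sample(s) {culprits[:5]}"
        )
    out.values = out.values / crea[:, None]
    return out


def log2_transform(table: FeatureTable) -> FeatureTable:
    """Entrywise log2.  Requires strictly positive intensities.

    Zero cells can only arise from the ``zero`` substitution strategy; the
    error message points there.
    """
    out = table.copy()
    out.with_state("log2")
    nonpos = np.isfinite(out.values) & (out.values <= 0)
    if nonpos.any():
        raise NormalizationError(
            f"{int(nonpos.sum())} non-positive intensities cannot be log2-transformed "
            "(did a 'zero' below-LOD substitution precede?)"
        )
    out.values = np.log2(out.values)
    return out


def slmnlt(table: FeatureTable, lod: LodModel) -> FeatureTable:
    """sLOD adjustment -> median normalization -> log2, in that order."""
    return log2_transform(median_normalize(substitute_below_lod(table, lod)))


def match_features(mz_a, mz_b, tolerance_da: float = 0.3):
    """Greedy one-to-one matching of two sorted m/z lists.

    Candidate pairs within ``tolerance_da`` are accepted best-first:
    smallest absolute m/z difference wins, ties broken by lower m/z.  Each
    feature is matched at most once.

    Returns
    -------
    list of (index_a, index_b) pairs, sorted by index_a.
    """
    a = np.asarray(mz_a, dtype=float)
    b = np.asarray(mz_b, dtype=float)
    for name, arr in (("mz_a", a), ("mz_b", b)):
        if arr.size > 1 and np.any(np.diff(arr) < 0):
            raise FeatureTableError(f"{name} must be sorted ascending")
    if tolerance_da < 0:
        raise ValueError("tolerance must be non-negative")
    candidates = []
    start = 0
    for i, x in enumerate(a):
        # advance window over b (both lists sorted)
        while start < b.size and b[start] < x - tolerance_da:
            start += 1
        j = start
        while j < b.size and b[j] <= x + tolerance_da:
            candidates.append((abs(x - b[j]), x, i, j))
            j += 1
    candidates.sort(key=lambda t: (t[0], t[1]))
    used_a, used_b, pairs = set(), set(), []
    for _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    pairs.sort()
    return pairs
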