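"""Sample x feature intensity tables for MALDI-TOF/MS peptidomic profiling.

The :class:`FeatureTable` is the common currency of every analysis stage:
rows are spectra (samples, possibly replicate collections or spots from the
same subject), columns are aligned peptidomic features identified by their
m/z value (Da), and each cell holds a signal intensity in arbitrary units.
A congruent boolean matrix flags cells whose signal fell below the
instrument's signal limit of detection (sLOD); a state tag records how far
along the normalization chain (raw -> sLOD-adjusted -> median- or
creatinine-normalized -> log2) the table has travelled, so that stages are
applied exactly once and in a declared order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "FeatureTableError", "StateError"]

#: Normalization states in their declared order of application.
STATES = ("raw", "lod-adjusted", "median-normalized", "creatinine-normalized", "log2")

#: Allowed state transitions.  Substitution may also run on an already
#: median-normalized table (the threshold is then on the normalized scale).
_TRANSITIONS = {
    "lod-adjusted": {"raw", "median-normalized"},
    "median-normalized": {"raw", "lod-adjusted"},
    "creatinine-normalized": {"raw", "lod-adjusted"},
    "log2": {"raw", "lod-adjusted", "median-normalized", "creatinine-normalized"},
}

#: Metadata columns recognised in wide-format files, in canonical order.
META_COLUMNS = ("sample_id", "subject_id", "run_id", "spot_id", "group", "creatinine")


class FeatureTableError(ValueError):
    """Structural problem with a feature table (shape, sign, ordering)."""


class StateError(FeatureTableError):
    """A normalization stage was applied out of its declared order."""


class FeatureTable:
    """Samples x features intensity matrix with censoring flags and metadata.

    Parameters
    ----------
    values : (n_samples, n_features) array of float
        Signal intensities; must be non-negative (NaN marks missing) in any
        state before ``log2``.
    mz : (n_features,) array of float
        Feature m/z values in Da, strictly increasing.
    meta : pandas.DataFrame
        One row per sample.  Must contain ``sample_id``; ``subject_id``,
        ``run_id``, ``spot_id``, ``group`` and ``creatinine`` are optional.
    below_lod : (n_samples, n_features) bool array, optional
        Flags for cells whose signal fell below the sLOD.  Defaults to all
        False.
    state : str
        One of ``raw | lod-adjusted | median-normalized |
        creatinine-normalized | log2``.
    """

    def __init__(self, values, mz, meta, below_lod=None, state="raw"):
        values = np.asarray(values, dtype=float)
        mz = np.asarray(mz, dtype=float)
        if values.ndim != 2:
            raise FeatureTableError("values must be a 2-D samples x features matrix")
        if mz.ndim != 1 or mz.size != values.shape[1]:
            raise FeatureTableError(
                f"mz length {mz.size} does not match {values.shape[1]} feature columns"
            )
        if mz.size > 1 and not np.all(np.diff(mz) > 0):
            raise FeatureTableError("m/z values must be strictly increasing")
        if state not in STATES:
            raise FeatureTableError(f"unknown normalization state {state!r}")
        if state != "log2" and np.nanmin(values, initial=0.0) < 0:
            raise FeatureTableError("negative intensities in a pre-log2 table")
        if below_lod is None:
            below_lod = np.zeros(values.shape, dtype=bool)
        below_lod = np.asarray(below_lod, dtype=bool)
        if below_lod.shape != values.shape:
            raise FeatureTableError(
                f"below_lod shape {below_lod.shape} incongruent with values {values.shape}"
            )
        meta = pd.DataFrame(meta).reset_index(drop=True)
        if "sample_id" not in meta.columns:
            raise FeatureTableError("sample metadata must contain a sample_id column")
        if len(meta) != values.shape[0]:
            raise FeatureTableError(
                f"{len(meta)} metadata rows for {values.shape[0]} sample rows"
            )
        if meta["sample_id"].duplicated().any():
            dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
            raise FeatureTableError(f"duplicate sample IDs: {dupes[:5]}")
        self.values = values
        self.mz = mz
        self.meta = meta
        self.below_lod = below_lod
        self.state = state

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> np.ndarray:
        return self.meta["sample_id"].to_numpy()

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.values.copy(), self.mz.copy(), self.meta.copy(),
            self.below_lod.copy(), self.state,
        )

    def with_state(self, new_state: str) -> None:
        """Advance the normalization state, enforcing the declared order."""
        allowed = _TRANSITIONS.get(new_state, set())
        if self.state not in allowed:
            raise StateError(
                f"cannot move from state {self.state!r} to {new_state!r}; "
                f"allowed predecessors: {sorted(allowed)}"
            )
        self.state = new_state

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Wide pandas view: metadata columns followed by one column per m/z."""
        meta_cols = [c for c in META_COLUMNS if c in self.meta.columns]
        extra = [c for c in self.meta.columns if c not in META_COLUMNS]
        out = self.meta[meta_cols + extra].copy()
        for j, mz in enumerate(self.mz):
            out[format(mz, "g")] = self.values[:, j]
        return out

    def to_long(self) -> pd.DataFrame:
        """Long (tidy) view with one row per (sample, feature) cell."""
        n, p = self.values.shape
        meta_rep = self.meta.loc[np.repeat(np.arange(n), p)].reset_index(drop=True)
        out = meta_rep.assign(
            mz=np.tile(self.mz, n),
            intensity=self.values.ravel(),
            below_lod=self.below_lod.ravel(),
        )
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<FeatureTable {self.n_samples} samples x {self.n_features} features, "
            f"state={self.state!r}, {int(self.below_lod.sum())} below-LOD cells>"
        )
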