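"""Shared in-memory containers for the NMR metabolomics pipeline.

Conventions
-----------
* ppm axes are stored strictly *descending* (high field on the right, as
  NMR spectra are drawn).  Readers accept ascending axes and reverse them.
* Sample metadata is a :class:`pandas.DataFrame` indexed by sample id with
  at least ``group`` and ``tissue`` columns.
* Feature matrices are samples x features DataFrames; processing state is
  tracked with explicit boolean flags so that stages can assert their
  preconditions (e.g. Pareto scaling requires prior normalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SpectraSet", "BinTable", "FeatureMatrix"]

_META_COLUMNS = ("group", "tissue")


def _check_metadata(metadata: pd.DataFrame, sample_ids) -> pd.DataFrame:
    if metadata.index.has_duplicates:
        dupes = metadata.index[metadata.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dupes}")
    missing = [s for s in sample_ids if s not in metadata.index]
    if missing:
        raise ValueError(f"metadata missing sample ids: {missing}")
    for col in _META_COLUMNS:
        if col not in metadata.columns:
            raise ValueError(f"metadata lacks required column {col!r}")
    return metadata.loc[list(sample_ids)]


@dataclass
class SpectraSet:
    """A set of 1D spectra on a common chemical-shift axis.

    Parameters
    ----------
    ppm : ndarray
        Strictly descending chemical-shift axis in ppm.
    intensities : ndarray, shape (n_samples, n_points)
        Non-negative intensities, one row per sample.
    metadata : DataFrame
        Indexed by sample id, with ``group`` and ``tissue`` columns, ordered
        like the intensity rows.
    """

    ppm: np.ndarray
    intensities: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.ppm.ndim != 1 or self.ppm.size == 0:
            raise ValueError("ppm axis must be a non-empty 1D array")
        if self.ppm.size > 1 and not np.all(np.diff(self.ppm) < 0):
            raise ValueError("ppm axis must be strictly descending")
        if self.intensities.shape[1] != self.ppm.size:
            raise ValueError(
                f"intensity row length {self.intensities.shape[1]} != axis "
                f"length {self.ppm.size}"
            )
        if self.intensities.shape[0] != len(self.metadata):
            raise ValueError("metadata rows must match intensity rows")
        self.metadata = _check_metadata(self.metadata, self.metadata.index)

    @property
    def sample_ids(self) -> list:
        return list(self.metadata.index)

    @property
    def groups(self) -> pd.Series:
        return self.metadata["group"]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    def subset(self, sample_ids) -> "SpectraSet":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return SpectraSet(
            ppm=self.ppm.copy(),
            intensities=self.intensities[idx].copy(),
            metadata=self.metadata.iloc[idx].copy(),
        )

    def drop_samples(self, sample_ids) -> "SpectraSet":
        keep = [s for s in self.sample_ids if s not in set(sample_ids)]
        return self.subset(keep)


@dataclass
class BinTable:
    """Spectral bins and their per-sample trapezoidal integrals.

    ``edges`` holds one ``(left_ppm, right_ppm)`` pair per bin with
    ``left_ppm > right_ppm`` (half-open ``[left, right)`` on the descending
    axis); consecutive bins within a contiguous axis segment share an edge so
    the union of bins tiles the retained axis exactly once.
    """

    edges: np.ndarray  # (n_bins, 2): left (high ppm), right (low ppm)
    integrals: pd.DataFrame  # samples x bins
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.ndim != 2 or self.edges.shape[1] != 2:
            raise ValueError("edges must have shape (n_bins, 2)")
        if np.any(self.edges[:, 0] <= self.edges[:, 1]):
            raise ValueError("each bin needs left ppm > right ppm")
        if np.any(np.asarray(self.integrals) < -1e-12):
            raise ValueError("bin integrals must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return self.edges.mean(axis=1)

    @property
    def n_bins(self) -> int:
        return self.edges.shape[0]

    def bin_definition_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "left_ppm": self.edges[:, 0],
                "right_ppm": self.edges[:, 1],
                "center_ppm": self.centers,
            }
        )

    def to_feature_matrix(self) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.integrals.copy(),
            metadata=self.metadata.copy(),
            feature_ppm=self.centers.copy(),
        )


@dataclass
class FeatureMatrix:
    """Samples x features matrix with processing-state flags.

    Features are either bin integrals (labelled by bin center ppm rounded to
    4 decimals) or metabolite integrals (labelled by metabolite name).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    normalized: bool = False
    glog: bool = False
    pareto: bool = False
    feature_ppm: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        self.metadata = _check_metadata(self.metadata, self.values.index)
        if self.pareto and not self.normalized:
            raise ValueError("pareto flag requires normalized flag")
        if self.feature_ppm is not None:
            self.feature_ppm = np.asarray(self.feature_ppm, dtype=float)
            if self.feature_ppm.size != self.values.shape[1]:
                raise ValueError("feature_ppm length must match feature count")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_names(self) -> list:
        return list(self.values.columns)

    @property
    def groups(self) -> pd.Series:
        return self.metadata["group"]

    def array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def with_values(self, values: pd.DataFrame, **flag_updates) -> "FeatureMatrix":
        fm = replace(self, values=values)
        for k, v in flag_updates.items():
            setattr(fm, k, v)
        fm.__post_init__()
        return fm

    def group_mask(self, group: str) -> np.ndarray:
        mask = (self.groups == group).to_numpy()
        if not mask.any():
            raise ValueError(f"no samples in group {group!r}")
        return mask

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values.loc[self.group_mask(group)]

    def subset_groups(self, groups) -> "FeatureMatrix":
        mask = self.groups.isin(list(groups)).to_numpy()
        if not mask.any():
            raise ValueError(f"no samples in groups {groups!r}")
        return FeatureMatrix(
            values=self.values.loc[mask].copy(),
            metadata=self.metadata.loc[mask].copy(),
            normalized=self.normalized,
            glog=self.glog,
            pareto=self.pareto,
            feature_ppm=None if self.feature_ppm is None else self.feature_ppm.copy(),
        )
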