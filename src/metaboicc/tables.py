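"""Samples x features intensity tables.

The central data container is :class:`FeatureTable`: a samples-by-features
matrix of positive intensities on the original (non-log) scale, where a
missing cell means the feature was not detected in that sample (a nondetect,
i.e. an observation left-censored at the feature's limit of detection).
Optional per-feature metadata (monoisotopic mass in Da, retention time in
minutes) rides along for annotation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTable"]


@dataclass
class FeatureTable:
    """A samples x features intensity matrix with nondetects encoded as NaN.

    Parameters
    ----------
    intensities
        DataFrame indexed by sample id with one column per feature id.
        Entries are strictly positive where present; NaN marks a nondetect.
    features
        Optional per-feature metadata indexed by feature id. Recognised
        columns: ``mass`` (Da), ``rt`` (minutes). Extra columns are kept.
    """

    intensities: pd.DataFrame
    features: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.intensities, pd.DataFrame):
            raise TypeError("intensities must be a pandas DataFrame")
        if self.intensities.columns.duplicated().any():
            dup = self.intensities.columns[self.intensities.columns.duplicated()]
            raise ValueError(f"duplicate feature ids: {list(dup)}")
        if self.intensities.index.duplicated().any():
            dup = self.intensities.index[self.intensities.index.duplicated()]
            raise ValueError(f"duplicate sample ids: {list(dup)}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValueError("intensities must be strictly positive where present")
        if self.features is not None:
            missing = self.intensities.columns.difference(self.features.index)
            if len(missing):
                raise ValueError(
                    f"feature metadata missing for {len(missing)} features, "
                    f"e.g. {list(missing[:3])}"
                )
            # keep metadata aligned with the matrix column order
            self.features = self.features.loc[self.intensities.columns]

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.columns

    # -- derived quantities ------------------------------------------------
    def detection_rates(self) -> pd.Series:
        """Fraction of samples in which each feature was detected."""
        return self.intensities.notna().mean(axis=0)

    def subset(self, feature_ids) -> "FeatureTable":
        """Return a new table restricted to ``feature_ids`` (order preserved)."""
        feats = None
        if self.features is not None:
            feats = self.features.loc[feature_ids]
        return FeatureTable(self.intensities[list(feature_ids)], feats)

    # -- I/O ----------------------------------------------------------------
    def to_csv(self, intensities_path: str, features_path: str | None = None) -> None:
        """Write the intensity matrix (and optional feature metadata) as CSV.

        Nondetects are written as empty cells.
        """
        self.intensities.to_csv(intensities_path, index_label="sample_id")
        if features_path is not None and self.features is not None:
            self.features.to_csv(features_path, index_label="feature_id")

    @classmethod
    def from_csv(
        cls, intensities_path: str | os.PathLike, features_path: str | os.PathLike | None = None
    ) -> "FeatureTable":
        ints = pd.read_csv(intensities_path, index_col="sample_id")
        feats = None
        if features_path is not None:
            feats = pd.read_csv(features_path, index_col="feature_id")
        return cls(ints, feats)
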