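"""Marker-panel container shared by the generators and the association scan."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix"]

MISSING = -1  # sentinel for a missing call in the integer call matrix


@dataclass
class GenotypeMatrix:
    """Biallelic marker calls with a linkage map.

    ``calls`` is a markers x lines integer matrix over {0, 1, MISSING}:
    0 = homozygous for the recurrent parent, 1 = heterozygous (the only
    two states a line backcrossed to the recurrent parent can show).
    ``map`` is a per-marker frame with columns ``marker``, ``linkage_group``
    (1..17 by default) and ``pos_bp``, in genome order.
    """

    calls: np.ndarray
    map: pd.DataFrame
    line_ids: list[str]

    def __post_init__(self):
        self.calls = np.asarray(self.calls)
        if self.calls.shape != (len(self.map), len(self.line_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.map)} markers x {len(self.line_ids)} lines"
            )
        if np.any(self.map["pos_bp"].to_numpy() < 0):
            raise ValueError("pos_bp must be non-negative")
        if self.map["linkage_group"].nunique() > 17:
            raise ValueError("more than 17 linkage groups")

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    @property
    def n_lines(self) -> int:
        return self.calls.shape[1]

    @property
    def marker_ids(self) -> pd.Index:
        return pd.Index(self.map["marker"])

    def subset_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            calls=self.calls[idx],
            map=self.map.iloc[idx].reset_index(drop=True),
            line_ids=list(self.line_ids),
        )

    def frequencies(self) -> np.ndarray:
        """Per-marker heterozygote frequency, missing calls excluded."""
        calls = np.ma.masked_equal(self.calls, MISSING)
        return np.asarray(calls.mean(axis=1))

    def imputed(self) -> np.ndarray:
        """Float lines x markers matrix with missing calls mean-imputed."""
        X = self.calls.T.astype(float)
        X[X == MISSING] = np.nan
        col_mean = np.nanmean(X, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        nan_mask = np.isnan(X)
        X[nan_mask] = np.broadcast_to(col_mean, X.shape)[nan_mask]
        return X
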