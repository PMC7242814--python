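"""Shared in-memory containers: ROI specifications and trial-by-voxel betas."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Trial metadata columns every BetaMatrix carries.
META_COLUMNS = ["category", "session", "memory_status"]


@dataclass
class ROISpec:
    """A region of interest: a named, duplicate-free set of voxel indices with
    a preferred stimulus category."""

    name: str
    preferred: str
    voxel_ids: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.voxel_ids = np.asarray(self.voxel_ids, dtype=int)
        if self.voxel_ids.size == 0:
            raise ValueError(f"ROI {self.name}: voxel set is empty")
        if np.unique(self.voxel_ids).size != self.voxel_ids.size:
            raise ValueError(f"ROI {self.name}: duplicate voxel ids")
        if self.preferred not in ("face", "scene"):
            raise ValueError(f"ROI {self.name}: preferred must be 'face' or 'scene'")

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_ids.size)


@dataclass
class BetaMatrix:
    """Single-trial response estimates (trials x voxels) for one ROI.

    ``meta`` holds one row per trial with at least ``category`` (face/scene),
    ``session`` (1-based scan session) and ``memory_status``
    (``source_correct`` vs ``other``); extra columns are carried through.
    """

    values: np.ndarray
    meta: pd.DataFrame
    roi: ROISpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("beta values must be a 2-D trials x voxels matrix")
        if len(self.meta) != self.values.shape[0]:
            raise ValueError(
                f"metadata length {len(self.meta)} != trial count {self.values.shape[0]}"
            )
        missing = [c for c in ("category", "session") if c not in self.meta.columns]
        if missing:
            raise ValueError(f"beta metadata missing columns: {missing}")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def subset(self, mask: np.ndarray) -> "BetaMatrix":
        """Row subset with metadata preserved."""
        mask = np.asarray(mask)
        return BetaMatrix(self.values[mask], self.meta.loc[mask].reset_index(drop=True), self.roi)

    def roi_mean_response(self) -> np.ndarray:
        """Per-trial response averaged over the ROI's voxels."""
        return self.values.mean(axis=1)
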