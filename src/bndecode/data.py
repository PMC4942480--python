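"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VoxelMeta:
    """Metadata for one voxel: MNI coordinate (mm), Brodmann area, lobe."""

    voxel_id: int
    coord: tuple[float, float, float]
    ba: str
    lobe: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"voxel {self.voxel_id}: non-finite coordinate {self.coord}")
        if not self.ba or not self.lobe:
            raise ValueError(f"voxel {self.voxel_id}: empty BA or lobe label")


@dataclass
class TrialMatrix:
    """Trial-by-voxel response table (GLM t-statistics) with class labels.

    Rows are trials (one per stimulus presentation), columns are voxels.
    ``labels[i]`` is the stimulus class of trial ``i``; ``voxel_meta[j]``
    describes column ``j``.
    """

    values: np.ndarray
    labels: np.ndarray
    voxel_meta: list[VoxelMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D trials x voxels matrix")
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError(
                f"label count {self.labels.shape[0]} != trial count {self.values.shape[0]}"
            )
        if self.voxel_meta and len(self.voxel_meta) != self.values.shape[1]:
            raise ValueError(
                f"voxel_meta count {len(self.voxel_meta)} != voxel count {self.values.shape[1]}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def voxel_ids(self) -> np.ndarray:
        if self.voxel_meta:
            return np.array([m.voxel_id for m in self.voxel_meta])
        return np.arange(self.n_voxels)

    def subset_voxels(self, columns: np.ndarray) -> "TrialMatrix":
        """Return a new TrialMatrix restricted to the given column indices."""
        meta = [self.voxel_meta[j] for j in columns] if self.voxel_meta else []
        return TrialMatrix(self.values[:, columns], self.labels.copy(), meta)


def coord_array(meta: list[VoxelMeta]) -> np.ndarray:
    """Stack voxel coordinates into an (n, 3) array (mm)."""
    return np.array([m.coord for m in meta], dtype=float)
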