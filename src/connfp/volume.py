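"""Shared image containers: 4-D BOLD volumes and integer label atlases.

Thin dataclasses around numpy arrays with a NIfTI affine, loaded and saved
through nibabel. Voxel indices are 0-based everywhere; world (mm)
coordinates exist only through the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["Volume4D", "LabelAtlas", "voxel_sizes"]


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge length in mm (norms of the affine's columns)."""
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


@dataclass
class Volume4D:
    """A subject's 4-D resting-state time series.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        BOLD signal, one time series per voxel.
    affine : ndarray, shape (4, 4)
        Voxel-to-world (mm) transform; must be invertible.
    tr : float
        Repetition time in seconds.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected a 4-D array, got ndim={self.data.ndim}")
        if self.data.shape[3] < 2:
            raise ValueError("time dimension must have at least 2 frames")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")
        if not self.tr > 0:
            raise ValueError("tr must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*voxel_sizes(self.affine), self.tr))
        img.header.set_xyzt_units("mm", "sec")
        nib.save(img, str(path))
        return path

    @classmethod
    def load(cls, path: str | Path, tr: float | None = None) -> "Volume4D":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
        if tr is None:
            zooms = img.header.get_zooms()
            if len(zooms) < 4 or zooms[3] <= 0:
                raise ValueError(
                    f"{path}: repetition time absent from header; pass tr="
                )
            tr = float(zooms[3])
        return cls(data=data, affine=np.asarray(img.affine), tr=tr)


@dataclass
class LabelAtlas:
    """Integer-labelled parcellation with its label table.

    ``table`` has columns ``label`` (int, > 0), ``name`` and ``hemisphere``
    (``left`` / ``right`` / ``none``). Label 0 is background; every voxel
    with a positive label is considered in-brain.
    """

    data: np.ndarray
    affine: np.ndarray
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("atlas must be a 3-D label image")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("atlas voxels must be integers")
        missing = {"label", "name", "hemisphere"} - set(self.table.columns)
        if missing:
            raise ValueError(f"label table missing columns: {sorted(missing)}")

    @property
    def brain_mask(self) -> np.ndarray:
        """Boolean in-brain mask (any positive label)."""
        return self.data > 0

    def labels_named(self, names: list[str]) -> list[int]:
        sel = self.table[self.table["name"].isin(names)]
        return [int(v) for v in sel["label"]]

    def mask_for_labels(self, labels: list[int] | tuple[int, ...]) -> np.ndarray:
        return np.isin(self.data, np.asarray(list(labels)))

    def save(self, image_path: str | Path, table_path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.int16), self.affine),
                 str(image_path))
        self.table.to_csv(table_path, sep="\t", index=False)

    @classmethod
    def load(cls, image_path: str | Path, table_path: str | Path) -> "LabelAtlas":
        img = nib.load(str(image_path))
        data = np.asanyarray(img.dataobj)
        data = np.rint(data).astype(np.int32)
        table = pd.read_csv(table_path, sep="\t")
        return cls(data=data, affine=np.asarray(img.affine), table=table)
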