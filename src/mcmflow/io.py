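"""NIfTI and table I/O plus the lightweight in-memory image carrier.

All images travel through :class:`Image4D`, a thin wrapper around a numpy
array with the frame timing needed by the kinetic and connectivity code.
Affines are carried through untouched — no resampling or registration is
performed anywhere in the package, so every image in one analysis must
already live on a common grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Image4D",
    "read_image",
    "write_image",
    "read_table",
    "write_table",
    "check_same_grid",
]


@dataclass
class Image4D:
    """A 3D or 4D voxel grid with optional frame timing.

    Parameters
    ----------
    data :
        Array of shape (nx, ny, nz) or (nx, ny, nz, n_frames), x-fastest,
        0-based indexing throughout.
    affine :
        4x4 voxel-to-world matrix (carried, never used for resampling).
    frame_times :
        Mid-frame times in seconds, length n_frames, for 4D series.
    units :
        Free-text unit label of the voxel values (e.g. ``"kBq/ml"``).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    frame_times: np.ndarray | None = None
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"Image4D expects 3D or 4D data, got {self.data.ndim}D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.data.ndim != 4:
                raise ValueError("frame_times given for a 3D image")
            if len(self.frame_times) != self.data.shape[3]:
                raise ValueError(
                    f"frame_times length {len(self.frame_times)} != "
                    f"n_frames {self.data.shape[3]}"
                )

    @property
    def is_series(self) -> bool:
        return self.data.ndim == 4

    @property
    def n_frames(self) -> int:
        return self.data.shape[3] if self.is_series else 1

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def frames_as_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Return the series as an (n_frames, n_voxels) matrix.

        ``mask`` selects voxels; default is every voxel in the grid.
        """
        if not self.is_series:
            raise ValueError("frames_as_matrix needs a 4D series")
        if mask is None:
            flat = self.data.reshape(-1, self.data.shape[3])
        else:
            flat = self.data[np.asarray(mask, dtype=bool)]
        return np.ascontiguousarray(flat.T)


def read_image(path) -> Image4D:
    """Load a NIfTI-1 file into an :class:`Image4D`."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected 3D or 4D NIfTI, got {data.ndim}D")
    return Image4D(data=data, affine=img.affine)


def write_image(image: Image4D | np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Write an image (or bare array) to NIfTI-1."""
    if isinstance(image, Image4D):
        data, aff = image.data, image.affine
    else:
        data, aff = np.asarray(image), affine if affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), aff), str(path))


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def check_same_grid(*images: Image4D | np.ndarray) -> tuple[int, int, int]:
    """Raise if the images do not share one 3D grid; return that grid."""
    shapes = []
    for im in images:
        arr = im.data if isinstance(im, Image4D) else np.asarray(im)
        shapes.append(arr.shape[:3])
    first = shapes[0]
    for s in shapes[1:]:
        if s != first:
            raise ValueError(f"grid mismatch: {first} vs {s}")
    return first
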