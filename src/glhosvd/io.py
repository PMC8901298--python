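"""NIfTI and gradient-table I/O in the FSL dialect.

Image data travel as NIfTI-1 (.nii or .nii.gz) via nibabel; gradient
tables as the FSL text dialect: a ``.bval`` file with one whitespace-
separated row of b-values and a ``.bvec`` file with three rows (x, y, z
components), one column per volume.  Directions are interpreted in the
image frame; phantom data written by this package are self-consistent, and
no scanner-frame reorientation is performed.

A 3-D NIfTI volume maps directly onto a :class:`~glhosvd.tensor.DWIStack`
(H x W x Q).  A 4-D volume is read as H x W x Z x Q and exposed slice by
slice, since the denoiser operates on 2-D slice stacks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import nibabel as nib
import numpy as np
from numpy.typing import NDArray

from .tensor import DWIStack

__all__ = ["DWIVolume", "read_dwi", "write_dwi", "read_gradients", "write_gradients"]


@dataclass
class DWIVolume:
    """A 4-D H x W x Z x Q acquisition, processed slice-by-slice along Z."""

    data: NDArray[np.float64]
    bvals: NDArray[np.float64]
    bvecs: NDArray[np.float64]
    affine: NDArray[np.float64]

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def slices(self) -> Iterator[DWIStack]:
        for z in range(self.n_slices):
            yield DWIStack(self.data[:, :, z, :], self.bvals, self.bvecs)

    def with_slices(self, stacks: list[DWIStack]) -> "DWIVolume":
        if len(stacks) != self.n_slices:
            raise ValueError("slice count mismatch")
        data = np.stack([s.intensities for s in stacks], axis=2)
        return DWIVolume(data, self.bvals, self.bvecs, self.affine)


def read_gradients(bval_path: str | os.PathLike, bvec_path: str | os.PathLike):
    """Read FSL-style b-value (1 x Q) and b-vector (3 x Q) text files."""
    bvals = np.loadtxt(bval_path, ndmin=1, dtype=np.float64)
    bvecs = np.loadtxt(bvec_path, ndmin=2, dtype=np.float64)
    if bvals.ndim != 1:
        raise ValueError(f"{bval_path}: expected a single row of b-values")
    if bvecs.shape[0] != 3:
        raise ValueError(f"{bvec_path}: expected 3 rows (x, y, z), got {bvecs.shape[0]}")
    if bvecs.shape[1] != bvals.shape[0]:
        raise ValueError(
            f"gradient-table mismatch: {bvals.shape[0]} b-values vs "
            f"{bvecs.shape[1]} b-vectors"
        )
    return bvals, bvecs.T  # internal layout: (Q, 3)


def write_gradients(
    bvals: NDArray[np.float64],
    bvecs: NDArray[np.float64],
    bval_path: str | os.PathLike,
    bvec_path: str | os.PathLike,
) -> None:
    """Write FSL-style gradient text files (bvecs stored as 3 x Q rows)."""
    for path in (bval_path, bvec_path):
        Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(bval_path, np.atleast_2d(np.asarray(bvals)), fmt="%.6g")
    np.savetxt(bvec_path, np.asarray(bvecs).T, fmt="%.8g")


def read_dwi(
    image_path: str | os.PathLike,
    bval_path: str | os.PathLike,
    bvec_path: str | os.PathLike,
) -> DWIStack | DWIVolume:
    """Read a DWI acquisition; returns a stack (3-D file) or volume (4-D).

    Validates that the volume count matches the gradient table and that
    all voxels are finite.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    bvals, bvecs = read_gradients(bval_path, bvec_path)
    if data.ndim not in (3, 4):
        raise ValueError(f"{image_path}: expected a 3-D or 4-D image, got {data.ndim}-D")
    if data.shape[-1] != bvals.shape[0]:
        raise ValueError(
            f"{image_path}: {data.shape[-1]} volumes but gradient table has "
            f"{bvals.shape[0]} entries"
        )
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{image_path}: image contains non-finite voxels")
    if data.ndim == 3:
        return DWIStack(data, bvals, bvecs)
    return DWIVolume(data, bvals, bvecs, np.asarray(img.affine))


def write_dwi(
    stack: DWIStack | DWIVolume,
    image_path: str | os.PathLike,
    bval_path: str | os.PathLike,
    bvec_path: str | os.PathLike,
) -> None:
    """Write a stack/volume as NIfTI plus FSL gradient files (read_dwi inverse)."""
    if isinstance(stack, DWIVolume):
        data, affine = stack.data, stack.affine
    else:
        data, affine = stack.intensities, np.eye(4)
    if not np.all(np.isfinite(data)):
        raise ValueError("refusing to write non-finite intensities")
    Path(image_path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(data, affine), str(image_path))
    write_gradients(stack.bvals, stack.bvecs, bval_path, bvec_path)


def write_map(
    image: NDArray[np.float64], image_path: str | os.PathLike
) -> None:
    """Write a 2-D scalar map (FA, ADC, ...) as a NIfTI image."""
    Path(image_path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(image, dtype=np.float64), np.eye(4)), str(image_path))
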