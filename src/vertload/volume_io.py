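"""Reading, writing, thresholding and coarsening of 3D volumes.

Supported on-disk formats are MetaImage (``.mha``/``.mhd``), NIfTI-1
(``.nii``/``.nii.gz``) — both via SimpleITK — and directories of numbered
single-plane TIFF files read as a stack (one file per SI plane).

In memory the package stores arrays as ``[x, y, z]`` with axis 2 the SI
axis. SimpleITK's numpy view is ``[z, y, x]``; conversion happens at the
file boundary so the rest of the package never sees it.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

from .volumes import ENDPLATE, MARROW, TRABECULAR, GrayVolume, LabeledVolume

__all__ = [
    "read_volume",
    "write_volume",
    "threshold_global",
    "coarsen",
]

_LABEL_DTYPES = (np.uint8, np.int8, np.uint16, np.int16, np.int32, np.uint32, np.int64)


class VolumeFormatError(ValueError):
    """Raised when a file cannot be interpreted as a supported volume."""


def _spacing_to_voxel_um(spacing, unit_hint: str | None = None) -> float:
    """Check isotropy and convert a 3-tuple of spacings to µm.

    MetaImage/NIfTI headers rarely declare units; by long-standing µCT
    convention we interpret the spacing as millimetres unless it is
    implausibly large (> 1000), in which case it is taken as µm already.
    """
    s = np.asarray(spacing, dtype=float)
    if s.size != 3:
        raise VolumeFormatError(f"expected 3 spacing entries (ElementSpacing/pixdim), got {s.size}")
    if np.any(s <= 0):
        raise VolumeFormatError(f"non-positive spacing in header: {tuple(s)}")
    if not np.allclose(s, s[0], rtol=1e-5, atol=0.0):
        raise VolumeFormatError(
            f"anisotropic spacing {tuple(s)} is not supported; "
            "the pipeline requires isotropic voxels (ElementSpacing/pixdim)"
        )
    if unit_hint == "um":
        return float(s[0])
    # heuristically treat header spacing as mm
    return float(s[0]) * 1000.0 if s[0] <= 1000.0 else float(s[0])


def _looks_like_labels(arr: np.ndarray) -> bool:
    if not np.issubdtype(arr.dtype, np.integer):
        return False
    lo, hi = arr.min(), arr.max()
    return lo >= MARROW and hi <= ENDPLATE


def read_volume(
    path: str | os.PathLike,
    format_hint: str | None = None,
    voxel_size_um: float | None = None,
) -> GrayVolume | LabeledVolume:
    """Read a volume from MetaImage, NIfTI, or a TIFF-stack directory.

    Integer images with values restricted to the compartment label set
    come back as :class:`LabeledVolume`; everything else as
    :class:`GrayVolume`. ``voxel_size_um`` overrides the header spacing
    and is mandatory for TIFF stacks (TIFF carries no reliable 3D
    spacing).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint
    if fmt is None:
        if path.is_dir():
            fmt = "tiff_stack"
        elif path.suffix.lower() in {".mha", ".mhd"}:
            fmt = "metaimage"
        elif path.name.lower().endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        elif path.suffix.lower() in {".tif", ".tiff"}:
            fmt = "tiff"
        else:
            raise VolumeFormatError(f"cannot infer format of {path.name}; pass format_hint")

    if fmt == "tiff_stack":
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".tif", ".tiff"})
        if not files:
            raise VolumeFormatError(f"no TIFF files in stack directory {path}")
        planes = [tifffile.imread(f) for f in files]
        shapes = {p.shape for p in planes}
        if len(shapes) != 1 or planes[0].ndim != 2:
            raise VolumeFormatError(f"TIFF stack planes disagree in shape: {sorted(shapes)}")
        # plane arrays are [y, x]; stack index is the SI plane
        arr = np.stack(planes, axis=-1).transpose(1, 0, 2)
        if voxel_size_um is None:
            raise VolumeFormatError("TIFF stacks carry no 3D spacing; voxel_size_um is required")
        vox = float(voxel_size_um)
    elif fmt == "tiff":
        arr = tifffile.imread(path)
        if arr.ndim != 3:
            raise VolumeFormatError(f"expected a 3D TIFF, got ndim={arr.ndim}")
        arr = arr.transpose(2, 1, 0)
        if voxel_size_um is None:
            raise VolumeFormatError("TIFF carries no 3D spacing; voxel_size_um is required")
        vox = float(voxel_size_um)
    elif fmt in {"metaimage", "nifti"}:
        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as exc:  # pragma: no cover - ITK error text varies
            raise VolumeFormatError(f"unreadable {fmt} file {path.name}: {exc}") from exc
        if img.GetDimension() != 3:
            raise VolumeFormatError(f"expected a 3D image, got {img.GetDimension()}D")
        vox = voxel_size_um if voxel_size_um is not None else _spacing_to_voxel_um(img.GetSpacing())
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # [z,y,x] -> [x,y,z]
    else:
        raise VolumeFormatError(f"unknown format hint {fmt!r}")

    if _looks_like_labels(arr):
        return LabeledVolume(arr.astype(np.uint8), vox)
    return GrayVolume(arr.astype(np.float32) if not np.issubdtype(arr.dtype, np.floating) else arr, vox)


def write_volume(volume: GrayVolume | LabeledVolume, path: str | os.PathLike) -> Path:
    """Write a volume as MetaImage or NIfTI (by extension)."""
    path = Path(path)
    if path.suffix.lower() not in {".mha", ".mhd"} and not path.name.lower().endswith((".nii", ".nii.gz")):
        raise VolumeFormatError(f"unsupported output extension for {path.name} (use .mha/.mhd/.nii/.nii.gz)")
    arr = volume.data
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    mm = volume.voxel_size_um / 1000.0
    img.SetSpacing((mm, mm, mm))
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))
    return path


def threshold_global(gray: GrayVolume, t: float) -> LabeledVolume:
    """Global threshold: intensity >= ``t`` becomes bone, else marrow.

    This is the segmentation step applied to µCT grayscale data before
    any compartment distinction; the output uses labels {0, 1} only.
    """
    if not np.isfinite(t):
        raise ValueError(f"threshold must be finite, got {t}")
    labels = (gray.data >= t).astype(np.uint8) * TRABECULAR
    return LabeledVolume(labels, gray.voxel_size_um)


def _block_reduce_mean(arr: np.ndarray, factor: int) -> np.ndarray:
    """Mean over factor³ blocks, zero-padding the high-index ends."""
    pad = [(0, (-s) % factor) for s in arr.shape]
    if any(p[1] for p in pad):
        arr = np.pad(arr, pad, mode="constant", constant_values=0)
    n0, n1, n2 = (s // factor for s in arr.shape)
    view = arr.reshape(n0, factor, n1, factor, n2, factor)
    return view.mean(axis=(1, 3, 5))


def coarsen(volume: GrayVolume | LabeledVolume, factor: int):
    """Coarsen by an integer factor, as done when downsampling 30-µm
    scans to the 60-µm analysis resolution.

    Grayscale volumes take the block mean. Binary volumes take the block
    mean and re-threshold at 0.5 with ties resolved to bone (a block
    that is exactly half bone stays bone). Grids not divisible by the
    factor are zero-padded at the high-index ends.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError(f"coarsening factor must be a positive integer, got {factor}")
    if factor == 1:
        return type(volume)(volume.data.copy(), volume.voxel_size_um)
    new_vox = volume.voxel_size_um * factor
    if isinstance(volume, GrayVolume):
        return GrayVolume(_block_reduce_mean(volume.data.astype(np.float64), factor), new_vox)
    if volume.data.max() > TRABECULAR:
        raise ValueError("coarsening is defined for binary {marrow, bone} volumes, not peeled labels")
    frac = _block_reduce_mean((volume.data != MARROW).astype(np.float64), factor)
    out = (frac >= 0.5).astype(np.uint8) * TRABECULAR
    return LabeledVolume(out, new_vox)
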