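"""Core voxel-volume containers.

All volumes are numpy arrays indexed ``[x, y, z]`` with axis 2 the
superoinferior (SI) anatomic axis — the compression direction. Voxels are
isotropic cubes; the edge length is carried in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Compartment labels shared by every module.
MARROW = 0
TRABECULAR = 1
SHELL = 2
ENDPLATE = 3

LABELS = (MARROW, TRABECULAR, SHELL, ENDPLATE)

#: Orientation-class codes used in ground-truth volumes and trabecula maps.
ORIENT_NONE = 0
ORIENT_VERTICAL = 1
ORIENT_OBLIQUE = 2
ORIENT_HORIZONTAL = 3

ORIENT_NAMES = {
    ORIENT_VERTICAL: "vertical",
    ORIENT_OBLIQUE: "oblique",
    ORIENT_HORIZONTAL: "horizontal",
}


def _check_voxel_size(voxel_size_um: float) -> float:
    v = float(voxel_size_um)
    if not np.isfinite(v) or v <= 0:
        raise ValueError(f"voxel_size_um must be a positive finite number, got {voxel_size_um!r}")
    return v


@dataclass
class GrayVolume:
    """A 3D grayscale image with isotropic voxel size in µm."""

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("GrayVolume data must be a non-empty 3D array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("GrayVolume data must be finite")
        self.voxel_size_um = _check_voxel_size(self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabeledVolume:
    """A 3D compartment-label image.

    Labels: 0 marrow, 1 trabecular bone, 2 cortical shell, 3 endplate.
    A freshly thresholded image uses only {0, 1}; peeling refines bone
    voxels into {1, 2, 3}.
    """

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("LabeledVolume data must be a non-empty 3D array")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabeledVolume data must have an integer dtype")
        if self.data.min() < MARROW or self.data.max() > ENDPLATE:
            raise ValueError("labels must lie in {0 (marrow), 1 (trab), 2 (shell), 3 (endplate)}")
        self.data = self.data.astype(np.uint8, copy=False)
        self.voxel_size_um = _check_voxel_size(self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size_um / 1000.0) ** 3

    def bone_mask(self) -> np.ndarray:
        """Boolean mask of all bone voxels (trabecular, shell, endplate)."""
        return self.data != MARROW

    def bone_volume_fraction(self) -> float:
        """BV/TV over the whole grid (no compartment distinction)."""
        return float(self.bone_mask().mean())
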