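"""Load-path analysis: which tissue carries the compressive load.

Highly stressed tissue is defined as the bone elements whose von Mises
stress lies strictly above a percentile cutoff (75th by default) of the
bone-element stress distribution; PMMA layers are excluded throughout.
The masked elements are then decomposed by compartment and trabecular
orientation class, and the decomposition is repeated over a range of
cutoffs to check that the ranking of classes is not an artifact of the
75th-percentile choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .its import TrabeculaMap
from .microfe import FEModel, FEResult
from .volumes import (
    ENDPLATE,
    ORIENT_HORIZONTAL,
    ORIENT_OBLIQUE,
    ORIENT_VERTICAL,
    SHELL,
    TRABECULAR,
)

__all__ = [
    "LoadPathReport",
    "element_classes",
    "highly_stressed_mask",
    "load_path_composition",
    "cutoff_sensitivity",
]

CLASS_NAMES = ("vertical", "oblique", "horizontal", "shell", "endplate")
_CODE = {name: i + 1 for i, name in enumerate(CLASS_NAMES)}


@dataclass
class LoadPathReport:
    """Fractions of above-cutoff bone elements per tissue class; the
    fractions sum to 1 over the classes present."""

    percentile_cutoff: float
    fractions: dict = field(default_factory=dict)
    n_masked: int = 0

    def ranking(self) -> list[str]:
        """Class names ordered by decreasing fraction (ties by name)."""
        return sorted(self.fractions, key=lambda c: (-self.fractions[c], c))


def element_classes(model: FEModel, tmap: TrabeculaMap) -> np.ndarray:
    """Per bone element: tissue-class code (1 vertical, 2 oblique,
    3 horizontal trabeculae, 4 shell, 5 endplate), aligned with
    ``FEResult.bone_von_mises()``."""
    bone = model.elem_mat == 0
    labels = model.elem_label[bone]
    vox = model.elem_voxel[bone]
    out = np.zeros(len(labels), np.uint8)
    out[labels == SHELL] = _CODE["shell"]
    out[labels == ENDPLATE] = _CODE["endplate"]
    trab = labels == TRABECULAR
    cls_vol = tmap.class_volume()
    trab_cls = cls_vol[vox[trab, 0], vox[trab, 1], vox[trab, 2]]
    lut = np.zeros(4, np.uint8)
    lut[ORIENT_VERTICAL] = _CODE["vertical"]
    lut[ORIENT_OBLIQUE] = _CODE["oblique"]
    lut[ORIENT_HORIZONTAL] = _CODE["horizontal"]
    out[trab] = lut[trab_cls]
    if (out == 0).any():
        raise ValueError("trabecula map does not cover every trabecular element")
    return out


def highly_stressed_mask(von_mises: np.ndarray, percentile: float = 75.0) -> np.ndarray:
    """Elements with stress strictly above the linearly interpolated
    percentile of the bone-element stresses."""
    vm = np.asarray(von_mises, float)
    if vm.size == 0:
        raise ValueError("cannot take a stress percentile of an empty element set")
    if not 0.0 <= percentile < 100.0:
        raise ValueError("percentile must lie in [0, 100)")
    cutoff = np.percentile(vm, percentile, method="linear")
    return vm > cutoff


def load_path_composition(mask: np.ndarray, classes: np.ndarray) -> LoadPathReport:
    """Decompose a highly-stressed element mask by tissue class."""
    mask = np.asarray(mask, bool)
    if mask.shape != classes.shape:
        raise ValueError("mask and element classes are misaligned")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty highly-stressed mask; composition undefined")
    sel = classes[mask]
    fractions = {name: float((sel == _CODE[name]).sum()) / n for name in CLASS_NAMES}
    return LoadPathReport(percentile_cutoff=np.nan, fractions=fractions, n_masked=n)


def cutoff_sensitivity(
    von_mises: np.ndarray,
    classes: np.ndarray,
    percentiles=(75.0, 80.0, 85.0, 90.0),
) -> list[LoadPathReport]:
    """One composition report per percentile cutoff."""
    reports = []
    for p in percentiles:
        mask = highly_stressed_mask(von_mises, p)
        rep = load_path_composition(mask, classes)
        rep.percentile_cutoff = float(p)
        reports.append(rep)
    return reports


def analyze_load_paths(result: FEResult, tmap: TrabeculaMap, percentile: float = 75.0) -> LoadPathReport:
    """Convenience: composition of above-percentile bone elements for a
    solved model."""
    classes = element_classes(result.model, tmap)
    vm = result.bone_von_mises()
    rep = load_path_composition(highly_stressed_mask(vm, percentile), classes)
    rep.percentile_cutoff = float(percentile)
    return rep
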