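"""Orientation-resolved bone-fraction morphometry.

For one specimen the report carries the nine orientation-resolved
fractions plus the cortical mass fraction:

======================  ================================================
BV/TV                   trabecular bone / trabecular compartment volume
vBV/TV, oBV/TV, hBV/TV  the same, split by orientation class
vBV/BV (vertical        vertical trabecular bone / all trabecular bone —
tissue fraction)        the bone-quality metric at the center of this
                        package
oBV/BV, hBV/BV          oblique and horizontal tissue fractions
vBV/BV_vertebra         vertical trabeculae / all vertebral bone tissue
                        (trabeculae + shell + endplates)
vBVvert/BV_vertebra     (vertical trabeculae + shell) / all vertebral
                        bone tissue
cortical mass fraction  shell bone / all vertebral bone
======================  ================================================

All ratios are formed from integer voxel counts, so the partition
identities (vBV/TV + oBV/TV + hBV/TV = BV/TV and the tissue fractions
summing to 1) hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .its import TrabeculaMap
from .volumes import (
    ENDPLATE,
    MARROW,
    ORIENT_HORIZONTAL,
    ORIENT_OBLIQUE,
    ORIENT_VERTICAL,
    SHELL,
    TRABECULAR,
    LabeledVolume,
)

__all__ = ["MorphologyReport", "compute_morphology", "trabecular_compartment_mask"]


@dataclass
class MorphologyReport:
    BV_TV: float
    vBV_TV: float
    oBV_TV: float
    hBV_TV: float
    vBV_BV: float
    oBV_BV: float
    hBV_BV: float
    vBV_BV_vertebra: float
    vBVvert_BV_vertebra: float
    cortical_mass_fraction: float

    def as_dict(self) -> dict:
        return asdict(self)


def trabecular_compartment_mask(labels: LabeledVolume, close_vox: int = 3) -> np.ndarray:
    """Estimate the trabecular compartment (the interior of the peeled
    shell/endplate boundary) from a labeled volume.

    Per SI slice the shell ring is morphologically closed (sealing
    pores up to ``close_vox``) and hole-filled; the compartment is the
    filled interior minus shell and endplate voxels. Without any shell
    label the whole grid is used.
    """
    shell = labels.data == SHELL
    if not shell.any():
        return np.ones(labels.shape, bool)
    struct = np.ones((close_vox, close_vox, 1), bool)
    sealed = ndimage.binary_closing(shell, structure=struct)
    filled = np.stack(
        [ndimage.binary_fill_holes(sealed[:, :, z]) for z in range(labels.shape[2])], axis=2
    )
    return filled & ~shell & (labels.data != ENDPLATE)


def compute_morphology(
    labels: LabeledVolume,
    tmap: TrabeculaMap,
    total_volume="auto",
) -> MorphologyReport:
    """Compute the orientation-resolved morphology report.

    ``total_volume`` defines TV: ``"auto"`` estimates the compartment
    interior from the labels; an integer is taken as a voxel count; a
    boolean array as an explicit compartment mask. The orientation
    split of trabecular bone comes from the trabecula map's per-voxel
    classes.
    """
    data = labels.data
    n_trab = int((data == TRABECULAR).sum())
    n_shell = int((data == SHELL).sum())
    n_end = int((data == ENDPLATE).sum())
    if isinstance(total_volume, str) and total_volume == "auto":
        tv = int(trabecular_compartment_mask(labels).sum())
    elif isinstance(total_volume, (int, np.integer)):
        tv = int(total_volume)
    else:
        tv = int(np.asarray(total_volume, bool).sum())
    if tv <= 0:
        raise ValueError("trabecular compartment volume (TV) must be positive")

    cls = tmap.class_volume()
    in_trab = data == TRABECULAR
    nv = int((in_trab & (cls == ORIENT_VERTICAL)).sum())
    no = int((in_trab & (cls == ORIENT_OBLIQUE)).sum())
    nh = int((in_trab & (cls == ORIENT_HORIZONTAL)).sum())
    if nv + no + nh != n_trab:
        raise ValueError(
            "trabecula map does not cover the trabecular compartment: "
            f"{nv + no + nh} classified vs {n_trab} trabecular voxels"
        )

    bv_vertebra = n_trab + n_shell + n_end
    if bv_vertebra == 0:
        raise ValueError("no bone voxels; morphology is undefined")
    if n_trab == 0:
        raise ValueError("empty trabecular compartment: tissue fractions (/BV) are undefined")

    return MorphologyReport(
        BV_TV=n_trab / tv,
        vBV_TV=nv / tv,
        oBV_TV=no / tv,
        hBV_TV=nh / tv,
        vBV_BV=nv / n_trab,
        oBV_BV=no / n_trab,
        hBV_BV=nh / n_trab,
        vBV_BV_vertebra=nv / bv_vertebra,
        vBVvert_BV_vertebra=(nv + n_shell) / bv_vertebra,
        cortical_mass_fraction=n_shell / bv_vertebra,
    )
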