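"""Digital isolation of the trabecular compartment.

The cortical shell of a vertebral body is thin and porous, so a naive
surface crust would absorb trabeculae and a naive connectivity rule
would leak through pores. Peeling instead estimates the shell thickness
ray by ray and regularizes it with a moving average over the boundary:

1. flood-fill the exterior marrow from the volume border;
2. per SI slice and per in-plane axis direction, record the first
   contiguous bone run entered from the exterior — its entry depth and
   run length are the local shell position and thickness;
3. discard rays that are tangential to the wall or that pass through a
   pore (entry depth or run length far from the direction's median);
4. smooth the surviving thickness field with a moving-average window
   over the boundary and mark bone within the smoothed band as shell;
5. repeat along the SI axis within a limited search depth to find the
   endplates;
6. remaining bone is trabecular.

Peeling only relabels bone voxels; the bone voxel count is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import ENDPLATE, MARROW, SHELL, TRABECULAR, LabeledVolume

__all__ = ["PeelParams", "peel_shell_endplates", "cortical_mass_fraction"]


@dataclass
class PeelParams:
    window_vox: int = 5  # moving-average window along the boundary (odd)
    max_bridge_vox: int = 2  # longest invalid-ray gap bridged by neighbors
    endplate_search_depth_vox: int = 10  # SI depth searched for endplates
    min_shell_component_vox: int = 12  # smallest per-slice shell fragment kept
    min_shell_si_span: float = 0.5  # shell components must span this fraction of the SI height

    def validate(self) -> None:
        if self.window_vox < 3 or self.window_vox % 2 == 0:
            raise ValueError("window_vox must be an odd integer >= 3")
        if self.max_bridge_vox < 1 or self.endplate_search_depth_vox < 1:
            raise ValueError("max_bridge_vox and endplate_search_depth_vox must be positive")
        if self.min_shell_component_vox < 1:
            raise ValueError("min_shell_component_vox must be positive")
        if not 0.0 <= self.min_shell_si_span <= 1.0:
            raise ValueError("min_shell_si_span must lie in [0, 1]")


def _first_run(bone_rays: np.ndarray, ext_rays: np.ndarray):
    """First contiguous bone run along axis 0 of ``bone_rays``.

    Returns (entry, thickness, valid): entry index of the first bone
    voxel reached from exterior background, run length, and whether the
    ray found such a run.
    """
    n = bone_rays.shape[0]
    idx = np.arange(n).reshape((n,) + (1,) * (bone_rays.ndim - 1))
    first = np.where(bone_rays, idx, n).min(axis=0)
    any_bone = first < n
    first_c = np.minimum(first, n - 1)
    # entered from exterior: the voxel just before the run is exterior
    # marrow, or the run starts at the border
    prev = np.clip(first_c - 1, 0, n - 1)
    entered = (first_c == 0) | np.take_along_axis(ext_rays, prev[None], axis=0)[0]
    valid = any_bone & entered
    gap = np.where((~bone_rays) & (idx >= first_c[None]), idx, n).min(axis=0)
    thickness = gap - first_c
    return first_c, thickness, valid


def _clean_field(entry, thick, valid, window: int, bridge: int):
    """Robust regularization of a (positions...) thickness field:
    median-based outlier rejection, bridging of short invalid gaps from
    the nearest valid ray, then a moving average."""
    entry = entry.astype(float)
    thick = thick.astype(float)
    if not valid.any():
        return None, None, valid
    med_t = float(np.median(thick[valid]))
    med_e = float(np.median(entry[valid]))
    # tangential rays run along the wall (huge thickness); pore rays
    # enter far too deep — both carry no usable thickness sample
    tangential = valid & (thick > med_t + window)
    thick = np.where(tangential, med_t, thick)
    pore = valid & (entry > med_e + window)
    valid = valid & ~pore
    # bridge invalid positions from the nearest valid ray
    if (~valid).any():
        dist, indices = ndimage.distance_transform_edt(~valid, return_indices=True)
        near = dist <= bridge
        fill = near & ~valid
        if fill.any():
            src = tuple(ind[fill] for ind in indices)
            entry[fill] = entry[src]
            thick[fill] = thick[src]
            valid = valid | fill
    entry = np.where(valid, entry, np.nan)
    thick = np.where(valid, thick, np.nan)
    # moving average over the boundary, ignoring invalid rays
    w = np.isfinite(thick).astype(float)
    t0 = np.where(np.isfinite(thick), thick, 0.0)
    size = (window,) * thick.ndim
    num = ndimage.uniform_filter(t0, size=size, mode="nearest")
    den = ndimage.uniform_filter(w, size=size, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        t_s = np.where(den > 0, num / den, np.nan)
    t_s = np.where(valid, t_s, np.nan)
    return entry, t_s, valid


def _mark_band(mask_out, bone_rays, entry, t_s, valid):
    """Mark bone voxels within [entry, entry + round(t_s)) along axis 0."""
    n = bone_rays.shape[0]
    idx = np.arange(n).reshape((n,) + (1,) * (bone_rays.ndim - 1))
    e = np.where(valid, entry, n + 1)
    t = np.where(valid, np.round(t_s), 0)
    band = (idx >= e[None]) & (idx < (e + t)[None])
    mask_out |= band & bone_rays


def peel_shell_endplates(binary: LabeledVolume, params: PeelParams | None = None) -> LabeledVolume:
    """Relabel the bone of a binary {marrow, bone} volume into
    trabecular / shell / endplate compartments."""
    params = params or PeelParams()
    params.validate()
    if binary.data.max() > TRABECULAR:
        raise ValueError("peeling expects a binary {marrow, bone} volume (labels 0/1)")
    bone = binary.data == TRABECULAR
    marrow = ~bone

    # exterior marrow: background 6-connected to the volume border
    comp, _ = ndimage.label(marrow, structure=ndimage.generate_binary_structure(3, 1))
    border_ids = np.unique(
        np.concatenate([
            comp[0].ravel(), comp[-1].ravel(),
            comp[:, 0].ravel(), comp[:, -1].ravel(),
            comp[:, :, 0].ravel(), comp[:, :, -1].ravel(),
        ])
    )
    border_ids = border_ids[border_ids > 0]
    if border_ids.size == 0:
        raise ValueError("volume has no exterior-connected background; cannot peel")
    ext = np.isin(comp, border_ids)

    shell = np.zeros_like(bone)
    # lateral passes: both directions of both in-plane axes
    for axis in (0, 1):
        for flip in (False, True):
            b = np.moveaxis(bone, axis, 0)
            x = np.moveaxis(ext, axis, 0)
            s = np.moveaxis(shell, axis, 0)
            if flip:
                b, x, s = b[::-1], x[::-1], s[::-1]
            entry, thick, valid = _first_run(b, x)
            # fields are (positions, z): smooth over the boundary surface
            entry, t_s, valid = _clean_field(entry, thick, valid, params.window_vox, params.max_bridge_vox)
            if entry is not None:
                _mark_band(s, b, entry, t_s, valid)

    # a genuine wall forms extended in-plane components per SI slice;
    # isolated strut tips that happen to face the exterior do not
    struct2d = np.ones((3, 3), bool)
    for z in range(shell.shape[2]):
        sl = shell[:, :, z]
        comp2d, n2d = ndimage.label(sl, structure=struct2d)
        if n2d:
            sizes = np.bincount(comp2d.ravel())
            small = np.nonzero(sizes < params.min_shell_component_vox)[0]
            small = small[small > 0]
            if small.size:
                sl[np.isin(comp2d, small)] = False

    # a cortical wall runs the (near) full SI height; wall-like faces of
    # bone that exist only near the ends (e.g. endplate rims when there
    # is no shell at all) are not shell
    comp3d, n3d = ndimage.label(shell, structure=np.ones((3, 3, 3), bool))
    if n3d:
        min_span = params.min_shell_si_span * shell.shape[2]
        for cid in range(1, n3d + 1):
            zs = np.nonzero((comp3d == cid).any(axis=(0, 1)))[0]
            if zs.size and (zs[-1] - zs[0] + 1) < min_span:
                shell[comp3d == cid] = False

    endplate = np.zeros_like(bone)
    bone_not_shell = bone & ~shell
    for flip in (False, True):
        b = np.moveaxis(bone_not_shell, 2, 0)
        x = np.moveaxis(ext | shell, 2, 0)  # rays may enter through the shell rim
        s = np.moveaxis(endplate, 2, 0)
        if flip:
            b, x, s = b[::-1], x[::-1], s[::-1]
        entry, thick, valid = _first_run(b, x)
        valid = valid & (entry < params.endplate_search_depth_vox)
        entry, t_s, valid = _clean_field(entry, thick, valid, params.window_vox, params.max_bridge_vox)
        if entry is not None:
            _mark_band(s, b, entry, t_s, valid)

    labels = np.zeros_like(binary.data)
    labels[bone] = TRABECULAR
    labels[shell & bone] = SHELL
    labels[endplate & bone & ~shell] = ENDPLATE
    return LabeledVolume(labels, binary.voxel_size_um)


def cortical_mass_fraction(labels: LabeledVolume) -> float:
    """Shell bone volume over total bone volume of the vertebra."""
    n_bone = int((labels.data != MARROW).sum())
    if n_bone == 0:
        raise ValueError("cortical mass fraction is undefined for a volume with no bone")
    return float((labels.data == SHELL).sum()) / n_bone
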