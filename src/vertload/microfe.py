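"""Voxel-based linear-elastic micro-finite-element analysis.

Every bone voxel becomes one 8-node hexahedral (brick) element with
homogeneous isotropic tissue properties; compression to a prescribed
apparent strain is applied through simulated PMMA layers extending
from the endplates, exactly as a vertebral body is tested between
platens. Because all elements are identical cubes, a single unit-
modulus element stiffness matrix per material serves the whole mesh
and the global operator is applied matrix-free, element by element
(numba-compiled); the system is solved with a Jacobi-preconditioned
conjugate-gradient iteration.

Apparent stiffness is the ratio of the SI reaction force on the
displaced face to the applied displacement. Solving the same specimen
with and without the cortical shell gives ``K_intact`` and ``K_trab``.

Boundary conditions
-------------------
``frictionless`` (default): only the SI displacement is prescribed on
the loaded faces; three lateral pins on the bottom face remove the
remaining rigid-body modes. A homogeneous block then reproduces the
uniform-strain solution exactly (K = E·A/L at any resolution).
``bonded``: all displacement components are fixed on the loaded faces,
closer to platens glued to the specimen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage

from .volumes import ENDPLATE, MARROW, SHELL, TRABECULAR, LabeledVolume

__all__ = [
    "MaterialSpec",
    "LoadCase",
    "FEModel",
    "FEResult",
    "build_fe_model",
    "solve",
    "stiffness",
    "element_von_mises",
]


@dataclass
class MaterialSpec:
    tissue_modulus_mpa: float = 10_000.0  # 10 GPa hard tissue
    tissue_poisson: float = 0.3
    pmma_modulus_mpa: float = 2_500.0  # 2.5 GPa PMMA layers
    pmma_poisson: float = 0.3

    def validate(self) -> None:
        for e in (self.tissue_modulus_mpa, self.pmma_modulus_mpa):
            if e <= 0:
                raise ValueError("elastic moduli must be positive")
        for nu in (self.tissue_poisson, self.pmma_poisson):
            if not 0.0 <= nu < 0.5:
                raise ValueError("Poisson's ratio must lie in [0, 0.5)")


@dataclass
class LoadCase:
    apparent_strain: float = 0.01  # compressive, over the full model height
    bc_mode: str = "frictionless"  # or "bonded"
    pmma_layer_thickness_vox: int = 3

    def validate(self) -> None:
        if self.apparent_strain <= 0:
            raise ValueError("apparent_strain must be positive")
        if self.bc_mode not in ("frictionless", "bonded"):
            raise ValueError(f"bc_mode must be 'frictionless' or 'bonded', got {self.bc_mode!r}")
        if self.pmma_layer_thickness_vox < 0:
            raise ValueError("pmma_layer_thickness_vox must be non-negative")


def hex8_stiffness(modulus_mpa: float, poisson: float, h_mm: float) -> np.ndarray:
    """Element stiffness of a cubic 8-node hexahedron (edge ``h_mm``),
    full 2x2x2 Gauss integration of the trilinear shape functions.

    Local node ``l`` sits at offsets ``(l & 1, (l >> 1) & 1, (l >> 2) & 1)``
    in (x, y, z); DOFs are interleaved [ux, uy, uz] per node.
    """
    E, nu, h = float(modulus_mpa), float(poisson), float(h_mm)
    D = E / ((1 + nu) * (1 - 2 * nu)) * np.array([
        [1 - nu, nu, nu, 0, 0, 0],
        [nu, 1 - nu, nu, 0, 0, 0],
        [nu, nu, 1 - nu, 0, 0, 0],
        [0, 0, 0, (1 - 2 * nu) / 2, 0, 0],
        [0, 0, 0, 0, (1 - 2 * nu) / 2, 0],
        [0, 0, 0, 0, 0, (1 - 2 * nu) / 2],
    ])
    gp = 0.5 + np.array([-1.0, 1.0]) / (2 * np.sqrt(3.0))
    Ke = np.zeros((24, 24))
    for gx in gp:
        for gy in gp:
            for gz in gp:
                B = _hex8_b_matrix(gx, gy, gz, h)
                Ke += (h**3 / 8.0) * B.T @ D @ B
    return Ke


def _hex8_b_matrix(gx: float, gy: float, gz: float, h_mm: float) -> np.ndarray:
    """Strain-displacement matrix at natural coordinates (gx, gy, gz) in
    the unit cube, for a cubic element of edge ``h_mm``."""
    B = np.zeros((6, 24))
    for l in range(8):
        bx, by, bz = l & 1, (l >> 1) & 1, (l >> 2) & 1
        fx = gx if bx else 1 - gx
        fy = gy if by else 1 - gy
        fz = gz if bz else 1 - gz
        dfx = (1.0 if bx else -1.0) / h_mm
        dfy = (1.0 if by else -1.0) / h_mm
        dfz = (1.0 if bz else -1.0) / h_mm
        dNdx, dNdy, dNdz = dfx * fy * fz, fx * dfy * fz, fx * fy * dfz
        B[0, 3 * l] = dNdx
        B[1, 3 * l + 1] = dNdy
        B[2, 3 * l + 2] = dNdz
        B[3, 3 * l] = dNdy
        B[3, 3 * l + 1] = dNdx
        B[4, 3 * l + 1] = dNdz
        B[4, 3 * l + 2] = dNdy
        B[5, 3 * l] = dNdz
        B[5, 3 * l + 2] = dNdx
    return B


@dataclass
class FEModel:
    """A voxel mesh ready to solve. Node ids are compact, in raster
    order over the padded grid (x fastest), hence deterministic."""

    elem_nodes: np.ndarray  # (ne, 8) int64 compact node ids
    elem_modulus: np.ndarray  # (ne,) float64, MPa
    elem_mat: np.ndarray  # (ne,) uint8: 0 tissue, 1 pmma
    elem_label: np.ndarray  # (ne,) uint8 compartment label; 255 for pmma
    elem_voxel: np.ndarray  # (ne, 3) int32 voxel coords in the *original* grid (z unpadded); -1 rows for pmma
    kes: np.ndarray  # (2, 24, 24) unit-modulus stiffness per material
    node_coords: np.ndarray  # (nn, 3) int32 node lattice coords in the padded grid
    fixed: np.ndarray  # (3*nn,) bool
    fixed_values: np.ndarray  # (3*nn,) float64 prescribed displacements (mm)
    h_mm: float
    applied_displacement_mm: float  # signed SI displacement of the top face
    include_shell: bool
    n_removed_floating: int
    top_plane: int  # node z-index of the displaced face
    material: MaterialSpec = field(default_factory=MaterialSpec)
    load: LoadCase = field(default_factory=LoadCase)

    @property
    def n_elements(self) -> int:
        return len(self.elem_nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)


@dataclass
class FEResult:
    """Solution of one model: nodal displacements, reactions, apparent
    stiffness, convergence diagnostics, per-element von Mises stress."""

    model: FEModel
    displacement_mm: np.ndarray  # (nn, 3)
    reaction_top_n: float
    reaction_bottom_n: float
    stiffness_n_per_mm: float
    iterations: int
    relative_residual: float
    von_mises_mpa: np.ndarray  # (ne,) all elements incl. PMMA

    @property
    def include_shell(self) -> bool:
        return self.model.include_shell

    def bone_von_mises(self) -> np.ndarray:
        return self.von_mises_mpa[self.model.elem_mat == 0]


class NoLoadPathError(RuntimeError):
    """No bone/PMMA path connects the loaded faces; the model is singular."""


def build_fe_model(
    labels: LabeledVolume,
    material: MaterialSpec | None = None,
    load: LoadCase | None = None,
    include_shell: bool = True,
) -> FEModel:
    """Convert a labeled volume into a voxel hexahedral mesh.

    Shell elements are dropped when ``include_shell`` is false (endplate
    and trabecular elements are always kept); PMMA layers of the stated
    thickness are appended over the full cross-section above and below
    the volume. Element components (face connectivity) that do not
    connect the two loaded faces are removed — they carry no load and
    would make the system singular under frictionless conditions.
    """
    material = material or MaterialSpec()
    load = load or LoadCase()
    material.validate()
    load.validate()

    data = labels.data
    keep = (data == TRABECULAR) | (data == ENDPLATE)
    if include_shell:
        keep |= data == SHELL
    n0, n1, n2 = data.shape
    tp = load.pmma_layer_thickness_vox
    nz_tot = n2 + 2 * tp

    mask = np.zeros((n0, n1, nz_tot), bool)
    mask[:, :, tp:tp + n2] = keep
    if tp > 0:
        mask[:, :, :tp] = True
        mask[:, :, nz_tot - tp:] = True

    # keep only element components connecting bottom to top (6-conn)
    comp, _ = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
    bottom_ids = np.unique(comp[:, :, 0])
    top_ids = np.unique(comp[:, :, -1])
    span_ids = np.setdiff1d(np.intersect1d(bottom_ids, top_ids), [0])
    if span_ids.size == 0:
        raise NoLoadPathError("no connected load path between the loaded faces")
    spanning = np.isin(comp, span_ids)
    n_removed = int(mask.sum() - spanning.sum())
    mask = spanning

    ex, ey, ez = np.nonzero(mask)
    order = np.lexsort((ex, ey, ez))  # raster order: x fastest, z slowest
    ex, ey, ez = ex[order], ey[order], ez[order]

    # node lattice of the padded grid; compact active-node numbering
    node_flag = np.zeros((n0 + 1, n1 + 1, nz_tot + 1), bool)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                node_flag[ex + dx, ey + dy, ez + dz] = True
    nxc, nyc, nzc = np.nonzero(node_flag)
    norder = np.lexsort((nxc, nyc, nzc))
    nxc, nyc, nzc = nxc[norder], nyc[norder], nzc[norder]
    node_id = np.full(node_flag.shape, -1, np.int64)
    node_id[nxc, nyc, nzc] = np.arange(len(nxc))
    node_coords = np.stack([nxc, nyc, nzc], axis=1).astype(np.int32)

    elem_nodes = np.empty((len(ex), 8), np.int64)
    for l in range(8):
        dx, dy, dz = l & 1, (l >> 1) & 1, (l >> 2) & 1
        elem_nodes[:, l] = node_id[ex + dx, ey + dy, ez + dz]

    is_pmma = (ez < tp) | (ez >= tp + n2)
    elem_mat = is_pmma.astype(np.uint8)
    elem_modulus = np.where(is_pmma, material.pmma_modulus_mpa, material.tissue_modulus_mpa)
    elem_label = np.full(len(ex), 255, np.uint8)
    bone_sel = ~is_pmma
    elem_label[bone_sel] = data[ex[bone_sel], ey[bone_sel], ez[bone_sel] - tp]
    elem_voxel = np.full((len(ex), 3), -1, np.int32)
    elem_voxel[bone_sel, 0] = ex[bone_sel]
    elem_voxel[bone_sel, 1] = ey[bone_sel]
    elem_voxel[bone_sel, 2] = ez[bone_sel] - tp

    h_mm = labels.voxel_size_um / 1000.0
    kes = np.stack([
        hex8_stiffness(1.0, material.tissue_poisson, h_mm),
        hex8_stiffness(1.0, material.pmma_poisson, h_mm),
    ])

    # boundary conditions
    nn = len(node_coords)
    fixed = np.zeros(3 * nn, bool)
    fixed_values = np.zeros(3 * nn)
    height_mm = nz_tot * h_mm
    u_top = -load.apparent_strain * height_mm
    bottom = node_coords[:, 2] == 0
    top = node_coords[:, 2] == nz_tot
    bot_idx = np.nonzero(bottom)[0]
    top_idx = np.nonzero(top)[0]
    fixed[3 * bot_idx + 2] = True
    fixed[3 * top_idx + 2] = True
    fixed_values[3 * top_idx + 2] = u_top
    if load.bc_mode == "bonded":
        for idx in (bot_idx, top_idx):
            fixed[3 * idx] = True
            fixed[3 * idx + 1] = True
    else:
        # pin lateral rigid modes at bottom-face nodes: the node with
        # minimal (y, x) holds x and y; the same-y node with maximal x
        # holds y (kills rotation about the SI axis)
        bc = node_coords[bot_idx]
        k0 = bot_idx[np.lexsort((bc[:, 0], bc[:, 1]))[0]]
        y0 = node_coords[k0, 1]
        same_y = bot_idx[node_coords[bot_idx, 1] == y0]
        k1 = same_y[np.argmax(node_coords[same_y, 0])]
        fixed[3 * k0] = True
        fixed[3 * k0 + 1] = True
        if k1 != k0:
            fixed[3 * k1 + 1] = True

    return FEModel(
        elem_nodes=elem_nodes,
        elem_modulus=elem_modulus.astype(np.float64),
        elem_mat=elem_mat,
        elem_label=elem_label,
        elem_voxel=elem_voxel,
        kes=kes,
        node_coords=node_coords,
        fixed=fixed,
        fixed_values=fixed_values,
        h_mm=h_mm,
        applied_displacement_mm=u_top,
        include_shell=include_shell,
        n_removed_floating=n_removed,
        top_plane=nz_tot,
        material=material,
        load=load,
    )


@njit(cache=True)
def _ebe_matvec(elem_nodes, elem_modulus, elem_mat, kes, u, out):
    out[:] = 0.0
    ue = np.empty(24)
    fe = np.empty(24)
    for e in range(elem_nodes.shape[0]):
        ke = kes[elem_mat[e]]
        s = elem_modulus[e]
        for l in range(8):
            n = elem_nodes[e, l]
            ue[3 * l] = u[3 * n]
            ue[3 * l + 1] = u[3 * n + 1]
            ue[3 * l + 2] = u[3 * n + 2]
        for i in range(24):
            acc = 0.0
            for j in range(24):
                acc += ke[i, j] * ue[j]
            fe[i] = acc * s
        for l in range(8):
            n = elem_nodes[e, l]
            out[3 * n] += fe[3 * l]
            out[3 * n + 1] += fe[3 * l + 1]
            out[3 * n + 2] += fe[3 * l + 2]


@njit(cache=True)
def _assemble_diagonal(elem_nodes, elem_modulus, elem_mat, kes, diag):
    diag[:] = 0.0
    for e in range(elem_nodes.shape[0]):
        ke = kes[elem_mat[e]]
        s = elem_modulus[e]
        for l in range(8):
            n = elem_nodes[e, l]
            diag[3 * n] += s * ke[3 * l, 3 * l]
            diag[3 * n + 1] += s * ke[3 * l + 1, 3 * l + 1]
            diag[3 * n + 2] += s * ke[3 * l + 2, 3 * l + 2]


class ConvergenceError(RuntimeError):
    pass


def solve(model: FEModel, rel_tol: float = 1e-6, max_iterations: int = 20_000) -> FEResult:
    """Solve the constrained system with Jacobi-preconditioned CG.

    Convergence is declared when the residual 2-norm on the free DOFs
    drops below ``rel_tol`` times the initial right-hand-side norm.
    """
    ndof = 3 * model.n_nodes
    fixed = model.fixed
    free = ~fixed
    buf = np.empty(ndof)

    def matvec(u: np.ndarray) -> np.ndarray:
        _ebe_matvec(model.elem_nodes, model.elem_modulus, model.elem_mat, model.kes, u, buf)
        return buf

    diag = np.empty(ndof)
    _assemble_diagonal(model.elem_nodes, model.elem_modulus, model.elem_mat, model.kes, diag)

    b = -matvec(model.fixed_values).copy()
    b[fixed] = 0.0
    b_norm = float(np.linalg.norm(b[free]))
    x = np.zeros(ndof)
    iterations = 0
    rel_res = 0.0
    if b_norm > 0:
        minv = np.zeros(ndof)
        minv[free] = 1.0 / diag[free]
        r = b.copy()
        z = minv * r
        p = z.copy()
        rz = float(r @ z)
        converged = False
        for iterations in range(1, max_iterations + 1):
            ap = matvec(p).copy()
            ap[fixed] = 0.0
            alpha = rz / float(p @ ap)
            x += alpha * p
            r -= alpha * ap
            res = float(np.linalg.norm(r[free]))
            rel_res = res / b_norm
            if rel_res <= rel_tol:
                converged = True
                break
            z = minv * r
            rz_new = float(r @ z)
            p = z + (rz_new / rz) * p
            rz = rz_new
        if not converged:
            raise ConvergenceError(
                f"PCG did not reach rel_tol={rel_tol:g} in {max_iterations} iterations "
                f"(final relative residual {rel_res:.3e})"
            )
    u = x
    u[fixed] = model.fixed_values[fixed]
    f = matvec(u).copy()
    nz = model.top_plane
    top_nodes = np.nonzero(model.node_coords[:, 2] == nz)[0]
    bottom_nodes = np.nonzero(model.node_coords[:, 2] == 0)[0]
    r_top = float(f[3 * top_nodes + 2].sum())
    r_bottom = float(f[3 * bottom_nodes + 2].sum())
    k = abs(r_top) / abs(model.applied_displacement_mm)
    vm = _von_mises_all(model, u)
    return FEResult(
        model=model,
        displacement_mm=u.reshape(-1, 3),
        reaction_top_n=r_top,
        reaction_bottom_n=r_bottom,
        stiffness_n_per_mm=k,
        iterations=iterations,
        relative_residual=rel_res,
        von_mises_mpa=vm,
    )


def _von_mises_all(model: FEModel, u: np.ndarray) -> np.ndarray:
    """Per-element von Mises stress from the centroid strain (trilinear
    shape-function gradients) and isotropic Hooke's law."""
    b0 = _hex8_b_matrix(0.5, 0.5, 0.5, model.h_mm)
    ue = u.reshape(-1, 3)[model.elem_nodes].reshape(-1, 24)
    eps = ue @ b0.T  # (ne, 6) engineering strain at the centroid
    vm = np.empty(model.n_elements)
    for mat_id, (e_mod_attr, nu) in enumerate([
        (None, model.material.tissue_poisson),
        (None, model.material.pmma_poisson),
    ]):
        sel = model.elem_mat == mat_id
        if not sel.any():
            continue
        lam_unit = nu / ((1 + nu) * (1 - 2 * nu))
        mu_unit = 1.0 / (2 * (1 + nu))
        E = model.elem_modulus[sel][:, None]
        strain = eps[sel]
        tr = strain[:, :3].sum(axis=1, keepdims=True)
        sig_n = E * (lam_unit * tr + 2 * mu_unit * strain[:, :3])
        sig_s = E * (mu_unit * strain[:, 3:])
        sm = sig_n.mean(axis=1, keepdims=True)
        dev = sig_n - sm
        j2 = 0.5 * (dev**2).sum(axis=1) + (sig_s**2).sum(axis=1)
        vm[sel] = np.sqrt(3.0 * j2)
    return vm


def stiffness(result: FEResult) -> float:
    """Apparent SI stiffness in kN/mm: reaction force on the displaced
    face over the applied displacement."""
    if result.model.applied_displacement_mm == 0:
        raise ValueError("stiffness undefined for zero applied displacement")
    return result.stiffness_n_per_mm / 1000.0


def element_von_mises(result: FEResult) -> np.ndarray:
    """Per-element von Mises stress (MPa) for all elements, PMMA
    included; use :meth:`FEResult.bone_von_mises` for bone only."""
    return result.von_mises_mpa
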