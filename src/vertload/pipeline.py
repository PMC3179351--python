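"""End-to-end specimen and cohort analysis.

Chains the stages for one binary volume: peel the cortical shell and
endplates, segment and classify individual trabeculae, compute the
morphology report, solve the intact and shell-removed micro-FE models,
and decompose the highly stressed tissue. Cohort analysis repeats this
per specimen and joins the results with the simulated strengths into
the table the statistics stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort_stats import fit_simple_regression
from .its import TrabeculaMap, classify_trabeculae
from .loadpaths import LoadPathReport, cutoff_sensitivity, element_classes
from .microfe import FEResult, LoadCase, MaterialSpec, build_fe_model, solve, stiffness
from .morphometry import MorphologyReport, compute_morphology
from .peel import PeelParams, peel_shell_endplates
from .phantom import CohortTable
from .volumes import LabeledVolume

__all__ = ["SpecimenAnalysis", "analyze_specimen", "analyze_cohort"]


@dataclass
class SpecimenAnalysis:
    labels: LabeledVolume
    tmap: TrabeculaMap
    morphology: MorphologyReport
    fe_intact: FEResult | None
    fe_trab: FEResult | None
    load_paths: list[LoadPathReport]

    @property
    def k_intact_kn_mm(self) -> float | None:
        return stiffness(self.fe_intact) if self.fe_intact else None

    @property
    def k_trab_kn_mm(self) -> float | None:
        return stiffness(self.fe_trab) if self.fe_trab else None


def analyze_specimen(
    binary: LabeledVolume,
    peel_params: PeelParams | None = None,
    material: MaterialSpec | None = None,
    load: LoadCase | None = None,
    total_volume="auto",
    run_fe: bool = True,
    fe_rel_tol: float = 1e-6,
    load_path_percentiles=(75.0, 80.0, 85.0, 90.0),
) -> SpecimenAnalysis:
    """Run the full pipeline on one binary {marrow, bone} volume."""
    labels = peel_shell_endplates(binary, peel_params)
    trab_only = LabeledVolume(
        (labels.data == 1).astype("uint8"), labels.voxel_size_um
    )
    tmap = classify_trabeculae(trab_only)
    morphology = compute_morphology(labels, tmap, total_volume=total_volume)
    fe_intact = fe_trab = None
    reports: list[LoadPathReport] = []
    if run_fe:
        model_i = build_fe_model(labels, material, load, include_shell=True)
        fe_intact = solve(model_i, rel_tol=fe_rel_tol)
        model_t = build_fe_model(labels, material, load, include_shell=False)
        fe_trab = solve(model_t, rel_tol=fe_rel_tol)
        classes = element_classes(model_i, tmap)
        reports = cutoff_sensitivity(fe_intact.bone_von_mises(), classes, load_path_percentiles)
    return SpecimenAnalysis(labels, tmap, morphology, fe_intact, fe_trab, reports)


def analyze_cohort(
    cohort: CohortTable,
    peel_params: PeelParams | None = None,
    material: MaterialSpec | None = None,
    load: LoadCase | None = None,
    run_fe: bool = True,
    fe_rel_tol: float = 1e-6,
) -> pd.DataFrame:
    """Per-specimen morphology (and optionally FE stiffness) merged with
    the simulated strengths: the cohort table for the statistics stage."""
    if cohort.specimens is None:
        raise ValueError("cohort was generated without volumes (keep_volumes=False)")
    rows = []
    for (_, meta), (vol, truth) in zip(cohort.table.iterrows(), cohort.specimens):
        ana = analyze_specimen(
            vol,
            peel_params=peel_params,
            material=material,
            load=load,
            total_volume=truth.tv_voxels,
            run_fe=run_fe,
            fe_rel_tol=fe_rel_tol,
        )
        row = {"specimen_id": meta["specimen_id"], "strength_kN": meta["strength_kN"]}
        row.update(ana.morphology.as_dict())
        if run_fe:
            row["K_intact"] = ana.k_intact_kn_mm
            row["K_trab"] = ana.k_trab_kn_mm
        rows.append(row)
    return pd.DataFrame(rows)
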