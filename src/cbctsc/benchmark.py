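"""Seeded end-to-end benchmark: simulate, correct, evaluate, dose-compare.

The benchmark emulates the pelvis-phantom study workflow on fully synthetic
data: a seeded digital pelvis phantom with an inserted tandem applicator is
forward-projected, contaminated with smooth additive scatter and photon
noise, reconstructed raw / after uniform subtraction / after the full
six-step correction, and scored with ROI statistics (per-tissue means, RMSE,
SNU, CNR), a toy attenuation-aware dose engine, 3D local gamma analysis and
DVH metrics (D90, D2cc).  All randomness flows from the single seed in the
run configuration.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .correction import CorrectionConfig, CorrectionResult, FiltrationParams, correct_cbct
from .dosimetry import (
    DwellPlan,
    GammaCriteria,
    dvh_metrics,
    dwell_plan_along_channel,
    gamma_3d_local,
    toy_dose,
)
from .fdk import ReconGrid, fdk_reconstruct, hu_to_lac, lac_to_hu
from .metrics import metrics_report
from .phantom import (
    ApplicatorSpec,
    PhantomSpec,
    applicator_scan,
    insert_applicator,
    make_pelvis_phantom,
    make_planning_ct,
    roi_catalog,
    structure_labels,
)
from .projector import ConeBeamGeometry, add_noise, forward_project, simulate_scatter, to_intensity, to_line_integral
from .volume import VoxelVolume, resample_to

log = logging.getLogger(__name__)


@dataclass
class BenchmarkArtifacts:
    """Heavyweight intermediates of a benchmark run (volumes, projections)."""

    ground_truth_hu: VoxelVolume
    prior_hu: VoxelVolume
    labels: VoxelVolume
    raw_hu: VoxelVolume
    correction: CorrectionResult
    dose_ref: VoxelVolume
    dose_eval: VoxelVolume
    rois: list


def _geometry(cfg: RunConfig) -> ConeBeamGeometry:
    g = cfg.geometry
    return ConeBeamGeometry(
        g.source_axis_distance, g.source_detector_distance,
        tuple(g.detector_pixels), g.pixel_pitch,
        np.arange(g.n_views) * (360.0 / g.n_views), g.I0,
    )


def _dose_grid(cfg: RunConfig) -> ReconGrid:
    vox = cfg.dose.grid_voxel_mm
    ext = cfg.dose.grid_extent_mm
    shape = tuple(int(round((hi - lo) / v)) for (lo, hi), v in zip(ext, vox))
    origin = tuple(lo + v / 2.0 for (lo, _), v in zip(ext, vox))
    return ReconGrid(shape, tuple(vox), origin)


def run_benchmark(cfg: RunConfig | None = None, keep_artifacts: bool = False):
    """Run the full study analog; returns a JSON-serialisable report
    (and the artifacts, if requested)."""
    cfg = RunConfig() if cfg is None else cfg
    t_start = time.time()
    timings: dict[str, float] = {}

    def _tick(stage: str, t0: float) -> float:
        timings[stage] = round(time.time() - t0, 2)
        log.info("%s done in %.1f s", stage, timings[stage])
        return time.time()

    # --- simulate ---------------------------------------------------------
    t0 = time.time()
    pspec = PhantomSpec(
        grid_shape=tuple(cfg.phantom.grid_shape),
        voxel_size=tuple(cfg.phantom.voxel_size),
        texture_scale=cfg.phantom.texture_scale,
        seed=cfg.seed,
    )
    aspec = ApplicatorSpec(
        tuple(tuple(p) for p in cfg.applicator.channel_polyline),
        cfg.applicator.radius_mm, cfg.applicator.hu_value,
    )
    labels0, hu0 = make_pelvis_phantom(pspec)
    prior = make_planning_ct(hu0, cfg.phantom.prior_noise_std_hu, cfg.seed + 1)
    labels, hu_truth = insert_applicator(labels0, hu0, aspec)
    rois = roi_catalog(labels, pspec)
    mu_w = cfg.correction.mu_w
    lac_truth = hu_to_lac(hu_truth, mu_w)
    geom = _geometry(cfg)
    p_truth = forward_project(lac_truth, geom)
    intensity = to_intensity(p_truth)
    contaminated = simulate_scatter(
        intensity, cfg.scatter.spr, cfg.scatter.blur_sigma_mm, cfg.scatter.plateau_frac
    )
    raw_stack = add_noise(contaminated, cfg.scatter.photons_per_I0, cfg.seed + 2)
    t0 = _tick("simulate", t0)

    # --- reconstruct + correct -------------------------------------------
    recon_grid = ReconGrid(tuple(pspec.grid_shape), tuple(pspec.voxel_size))
    raw_lac = fdk_reconstruct(
        to_line_integral(raw_stack), recon_grid, cfg.correction.filter_name
    )
    raw_hu = lac_to_hu(raw_lac, mu_w)
    t0 = _tick("raw_reconstruction", t0)

    ccfg = CorrectionConfig(
        mu_w=mu_w,
        percentile_rule=cfg.correction.percentile_rule,
        object_mask_rule=cfg.correction.object_mask_rule,
        softcut_eps=cfg.correction.softcut_eps,
        recon_grid=recon_grid,
        filter_name=cfg.correction.filter_name,
        segmentation_source=cfg.correction.segmentation_source,
        eps_floor=cfg.correction.eps_floor,
        mask_percentile=cfg.correction.mask_percentile,
        filtration=FiltrationParams(sigma_mm=cfg.correction.filtration_sigma_mm),
        applicator_threshold_hu=cfg.correction.applicator_threshold_hu,
        applicator_hu=cfg.applicator.hu_value,
    )
    model = applicator_scan(aspec, hu_truth)
    result = correct_cbct(raw_stack, prior, ccfg, applicator_model_hu=model)
    t0 = _tick("correction", t0)

    # --- image metrics ----------------------------------------------------
    reports = {
        "raw": metrics_report(raw_hu, hu0, rois, cnr_target="rectum"),
        "first_pass": metrics_report(lac_to_hu(result.cbct_c, mu_w), hu0, rois, cnr_target="rectum"),
        "corrected": metrics_report(result.final_hu, hu0, rois, cnr_target="rectum"),
        "reference_ct": metrics_report(prior, hu0, rois, cnr_target="rectum"),
    }
    gt_means = {s.name: s.mean for s in metrics_report(hu0, hu0, rois).roi_stats}

    roi_table = []
    for roi in rois:
        row = {"roi": roi.name, "tissue": roi.tissue_class, "truth_mean": round(gt_means[roi.name], 1)}
        for key in ("raw", "first_pass", "corrected"):
            s = next(x for x in reports[key].roi_stats if x.name == roi.name)
            row[key] = {
                "mean": round(s.mean, 1), "std": round(s.std, 1),
                "range": [round(v, 1) for v in s.range],
                "hu_error": round(s.mean - gt_means[roi.name], 1),
            }
        roi_table.append(row)

    def _errors(key):
        return {
            r["roi"]: r[key]["hu_error"] for r in roi_table
        }

    quality = {}
    for key in ("raw", "first_pass", "corrected", "reference_ct"):
        rep = reports[key]
        quality[key] = {
            "rmse_hu": round(rep.rmse_hu, 2),
            "snu_hu": {t: round(v, 2) for t, v in rep.snu_hu.items()},
            "cnr": round(rep.cnr, 3) if rep.cnr is not None else None,
        }
    t0 = _tick("image_metrics", t0)

    # --- dose + gamma + DVH ----------------------------------------------
    plan = dwell_plan_along_channel(
        aspec.channel_polyline, cfg.dose.n_dwells, cfg.dose.step_mm,
        cfg.dose.dwell_time_s, cfg.dose.source_strength,
    )
    dgrid = _dose_grid(cfg)
    dose_ref = toy_dose(lac_truth, plan, dgrid)
    final_lac = hu_to_lac(result.final_hu, mu_w)
    dose_eval = toy_dose(final_lac, plan, dgrid)
    t0 = _tick("dose", t0)

    gamma_table = []
    for dd, dta in cfg.dose.gamma_criteria:
        row = {"criteria": f"{dd:g}%, {dta:g} mm", "pass_rates": {}}
        for thr in cfg.dose.gamma_thresholds_gy:
            res = gamma_3d_local(
                dose_ref, dose_eval, GammaCriteria(dd, dta, thr)
            )
            row["pass_rates"][f"{thr:g} Gy"] = round(res.pass_rate, 2)
        gamma_table.append(row)
    t0 = _tick("gamma", t0)

    dose_labels = resample_to(labels, dose_ref, order=0, cval=0)
    name_to_label = structure_labels(pspec)
    dvh = {}
    for structure, metric in (
        ("uterus", "d90"), ("bladder", "d2cc"),
        ("rectum", "d2cc"), ("intestine", "d2cc"),
    ):
        m = dose_labels.data == name_to_label[structure]
        ref_res = dvh_metrics(dose_ref, m)
        ev_res = dvh_metrics(dose_eval, m)
        ref_v = getattr(ref_res, metric)
        ev_v = getattr(ev_res, metric)
        dvh[structure] = {
            "metric": metric,
            "reference_gy": round(ref_v, 3),
            "corrected_gy": round(ev_v, 3),
            "pct_deviation": round(100.0 * (ev_v - ref_v) / ref_v, 2) if ref_v else None,
            "volume_cm3": round(ref_res.volume_cm3, 1),
        }
    timings["total"] = round(time.time() - t_start, 2)

    report = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "s_bar": result.scatter_estimate.s_bar,
        "lac_table": {
            "mu_air": result.lac_table.mu_air, "mu_fat": result.lac_table.mu_fat,
            "mu_muscle": result.lac_table.mu_muscle, "mu_bone": result.lac_table.mu_bone,
        },
        "mask": {"r_max": round(result.mask.r_max, 4), "G_max": round(result.mask.G_max, 6)},
        "roi_table": roi_table,
        "image_quality": quality,
        "max_abs_soft_tissue_error_hu": {
            key: round(max(abs(e) for e in _errors(key).values()), 1)
            for key in ("raw", "first_pass", "corrected")
        },
        "gamma_pass_rates": gamma_table,
        "dvh": dvh,
        "timings_s": timings,
    }
    if keep_artifacts:
        return report, BenchmarkArtifacts(
            hu0, prior, labels, raw_hu, result, dose_ref, dose_eval, rois
        )
    return report


def report_markdown(report: dict) -> str:
    """Markdown rendering of the three benchmark tables."""
    lines = ["# Benchmark report", ""]
    lines += ["## ROI CT numbers (HU)", ""]
    lines.append("| ROI | truth | raw | first pass | corrected | err raw | err corr |")
    lines.append("|---|---|---|---|---|---|---|")
    for row in report["roi_table"]:
        lines.append(
            f"| {row['roi']} | {row['truth_mean']} | {row['raw']['mean']} | "
            f"{row['first_pass']['mean']} | {row['corrected']['mean']} | "
            f"{row['raw']['hu_error']} | {row['corrected']['hu_error']} |"
        )
    lines += ["", "## Image quality", ""]
    lines.append("| image | RMSE (HU) | SNU muscle (HU) | CNR |")
    lines.append("|---|---|---|---|")
    for key, q in report["image_quality"].items():
        lines.append(
            f"| {key} | {q['rmse_hu']} | {q['snu_hu'].get('muscle', '-')} | {q['cnr']} |"
        )
    lines += ["", "## Gamma pass rates (%)", ""]
    thresholds = list(report["gamma_pass_rates"][0]["pass_rates"])
    lines.append("| criteria | " + " | ".join(thresholds) + " |")
    lines.append("|" + "---|" * (len(thresholds) + 1))
    for row in report["gamma_pass_rates"]:
        lines.append(
            f"| {row['criteria']} | "
            + " | ".join(str(row["pass_rates"][t]) for t in thresholds) + " |"
        )
    lines += ["", "## DVH", ""]
    lines.append("| structure | metric | reference (Gy) | corrected (Gy) | deviation (%) |")
    lines.append("|---|---|---|---|---|")
    for s, d in report["dvh"].items():
        lines.append(
            f"| {s} | {d['metric'].upper()} | {d['reference_gy']} | "
            f"{d['corrected_gy']} | {d['pct_deviation']} |"
        )
    return "\n".join(lines) + "\n"
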