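"""End-to-end analysis pipelines and report assembly.

Ties the stages together the way the interventional workflow runs them:
load masks -> (optionally) fit or load the rigid co-registration ->
resample the ice ball onto the tumor grid -> margin map -> margin summary
plus morphometry -> JSON-ready report.  A second pipeline runs the full
cohort statistics battery on a per-case table.
"""

from __future__ import annotations

from dataclasses import asdict
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np

from . import margin_analysis, morphometry, outcome_stats
from .errors import CryomarginError
from .imaging_io import BinaryMask, assert_same_grid, read_mask, resample_mask
from .outcome_stats import CaseRecord
from .registration import LandmarkSet, RigidTransform, fit_rigid


def _package_version() -> str:
    try:
        return version("cryomargin")
    except PackageNotFoundError:
        return "unknown"


def analyze_margin(
    tumor: BinaryMask,
    ice: BinaryMask,
    transform: RigidTransform | None = None,
    threshold_mm: float = 5.0,
) -> dict:
    """Margin analysis on loaded masks; resamples ice onto the tumor grid if needed."""
    if transform is not None:
        ice = resample_mask(ice, tumor.geometry, transform)
    elif not ice.geometry.close_to(tumor.geometry):
        ice = resample_mask(ice, tumor.geometry, RigidTransform.identity())
    assert_same_grid(tumor, ice)

    margin_map = margin_analysis.compute_margin_map(tumor, ice)
    summary = margin_analysis.summarize_margin(margin_map, tumor, ice, threshold_mm)
    tumor_morpho = morphometry.measure(tumor)
    ice_vol = morphometry.volume_ml(ice)

    return {
        "version": _package_version(),
        "mtm_mm": summary.mtm_mm,
        "mtm_raw_mm": summary.mtm_raw_mm,
        "incomplete_coverage": summary.incomplete_coverage,
        "margin_achieved": summary.margin_achieved,
        "argmin_xyz_mm": list(summary.argmin_point_mm),
        "argmin_octant": summary.argmin_octant,
        "octant_min_mm": summary.octant_min_mm,
        "coverage_fractions": summary.coverage_fractions,
        "threshold_mm": summary.threshold_mm,
        "tumor_volume_ml": tumor_morpho.volume_ml,
        "iceball_volume_ml": ice_vol,
        "max_diameter_mm": tumor_morpho.max_diameter_mm,
        "voxel_diagonal_mm": summary.voxel_diagonal_mm,
        "n_surface_points": len(margin_map),
    }


def analyze_margin_files(
    tumor_path: str | Path,
    ice_path: str | Path,
    transform_path: str | Path | None = None,
    landmarks_pre: str | Path | None = None,
    landmarks_post: str | Path | None = None,
    threshold_mm: float = 5.0,
) -> dict:
    """File-level margin pipeline; exactly one registration mode may be given."""
    if transform_path is not None and landmarks_pre is not None:
        raise CryomarginError("give either a transform file or landmark files, not both")
    tumor = read_mask(tumor_path)
    ice = read_mask(ice_path)
    transform = None
    registration_info: dict = {"mode": "none"}
    if transform_path is not None:
        transform = RigidTransform.from_json(transform_path)
        registration_info = {"mode": "transform", "path": str(transform_path)}
    elif landmarks_pre is not None or landmarks_post is not None:
        if landmarks_pre is None or landmarks_post is None:
            raise CryomarginError("landmark registration needs both pre and post files")
        src = LandmarkSet.from_csv(landmarks_post)
        tgt = LandmarkSet.from_csv(landmarks_pre)
        transform, rmsd = fit_rigid(src, tgt)
        registration_info = {"mode": "landmarks", "rmsd_mm": rmsd, "n_landmarks": len(src)}
    report = analyze_margin(tumor, ice, transform, threshold_mm)
    report["inputs"] = {"tumor": str(tumor_path), "ice": str(ice_path)}
    report["registration"] = registration_info
    return report


def cohort_statistics(records: list[CaseRecord]) -> dict:
    """The full cohort battery: group contrasts, exact tests, correlation, Cox, KM.

    Continuous variables are contrasted between local-control and
    local-progression cases by Mann-Whitney U; sex and ASA class by
    Fisher's exact test; the three-level renal-complexity category by the
    Freeman-Halton test; size vs margin by Spearman correlation; margin and
    diameter as progression predictors by univariable Cox; and
    progression-free survival at 12 and 24 months by Kaplan-Meier.
    Inestimable components (e.g. Cox with zero events) are reported as
    errors without aborting the rest of the battery.
    """
    control = [r for r in records if not r.ltp]
    ltp = [r for r in records if r.ltp]
    report: dict = {
        "version": _package_version(),
        "n_cases": len(records),
        "n_local_control": len(control),
        "n_ltp": len(ltp),
    }

    def _group_summary(values: list[float]) -> dict:
        if not values:
            return {"n": 0}
        arr = np.asarray(values, dtype=float)
        # inclusive-quartile (Tukey hinge) convention for the IQR
        q1, med, q3 = _tukey_hinges(arr)
        return {"n": len(arr), "median": float(med), "iqr": [float(q1), float(q3)],
                "mean": float(arr.mean()), "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0}

    for name in ("tumor_diameter_mm", "tumor_volume_ml", "iceball_volume_ml",
                 "mtm_raw_mm", "n_probes"):
        entry: dict = {
            "local_control": _group_summary([getattr(r, name) for r in control]),
            "ltp": _group_summary([getattr(r, name) for r in ltp]),
        }
        if control and ltp:
            res = outcome_stats.mann_whitney_u(
                [getattr(r, name) for r in control],
                [getattr(r, name) for r in ltp],
            )
            entry["test"] = asdict(res)
        report.setdefault("continuous", {})[name] = entry

    categorical: dict = {}
    if control and ltp:
        sex_table = _two_by_two(records, "sex", "male")
        asa_table = _two_by_two(records, "asa", "II")
        renal_table = [
            [sum(1 for r in grp if r.renal_category == cat) for grp in (control, ltp)]
            for cat in ("low", "moderate", "high")
        ]
        categorical["sex"] = {
            "table": sex_table, "test": asdict(outcome_stats.fisher_exact_2x2(sex_table))}
        categorical["asa"] = {
            "table": asa_table, "test": asdict(outcome_stats.fisher_exact_2x2(asa_table))}
        categorical["renal_category"] = {
            "table": renal_table, "test": asdict(outcome_stats.freeman_halton(renal_table))}
    report["categorical"] = categorical

    report["size_margin_correlation"] = asdict(outcome_stats.spearman_rho(
        [r.tumor_diameter_mm for r in records],
        [r.mtm_raw_mm for r in records],
    ))

    cox: dict = {}
    for cov in ("mtm_raw_mm", "tumor_diameter_mm"):
        try:
            cox[cov] = asdict(outcome_stats.cox_univariable(records, cov))
        except CryomarginError as exc:
            cox[cov] = {"error": str(exc)}
    report["cox"] = cox

    surv = outcome_stats.km_event_free(records, [12.0, 24.0])
    report["ltp_free_survival"] = {
        "12_months": surv[0],
        "24_months": surv[1],
        "percent_12_months": 100.0 * surv[0],
        "percent_24_months": 100.0 * surv[1],
    }
    return report


def _tukey_hinges(arr: np.ndarray) -> tuple[float, float, float]:
    """Median and inclusive quartiles (hinges include the median in both halves)."""
    s = np.sort(arr)
    n = len(s)
    med = float(np.median(s))
    if n == 1:
        return med, med, med
    half = (n + 1) // 2 if n % 2 else n // 2
    return float(np.median(s[:half])), med, float(np.median(s[n - half:]))


def _two_by_two(records: list[CaseRecord], fieldname: str, first_level: str) -> list[list[int]]:
    """Rows = level first/other, columns = local control / LTP (printed-table layout)."""
    table = [[0, 0], [0, 0]]
    for r in records:
        i = 0 if getattr(r, fieldname) == first_level else 1
        j = 1 if r.ltp else 0
        table[i][j] += 1
    return table


def format_margin_report(report: dict) -> str:
    """Human-readable side-bar style margin metrics."""
    lines = [
        "3D ablation margin metrics",
        "==========================",
        f"Minimal treatment margin : {report['mtm_mm']:d} mm "
        f"(raw {report['mtm_raw_mm']:.2f} mm)",
        f"Coverage                 : "
        + ("incomplete" if report["incomplete_coverage"] else "complete"),
        f"Intended margin >= {report['threshold_mm']:.0f} mm : "
        + ("achieved" if report["margin_achieved"] else "not achieved"),
        f"Smallest-margin octant   : {report['argmin_octant']}",
        f"Tumor volume             : {report['tumor_volume_ml']:.1f} ml",
        f"Ice-ball volume          : {report['iceball_volume_ml']:.1f} ml",
        f"Max tumor diameter       : {report['max_diameter_mm']:.1f} mm",
        "Coverage fractions       : "
        + ", ".join(f"{k} {v:.1%}" for k, v in report["coverage_fractions"].items()),
        f"Distance resolution      : +/- {report['voxel_diagonal_mm'] / 2:.2f} mm "
        "(half voxel diagonal)",
    ]
    return "\n".join(lines)
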