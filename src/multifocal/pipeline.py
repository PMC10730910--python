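"""Batch orchestration: lens x eye through-focus evaluation and reporting.

For every eye the monofocal reference lens is evaluated first; its
through-focus peak determines the eye's equivalent-sphere shift, which is
then applied — as extra defocus in the optics — to every multifocal
evaluation of that eye.  Metrics of each (lens, eye) pair are normalized
by the same eye's monofocal metrics, mirroring how lens families are
compared against a monofocal control.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .profiles import EyeRecord, SagittalProfile, remove_base_power
from .segmentation import combine_with_eye, default_zone_count
from .throughfocus import (
    ThroughFocusCurve,
    equivalent_sphere_shift,
    metrics_report,
    normalize_to_monofocal,
    through_focus_curve,
)

__all__ = ["evaluate_study", "summarize_curves", "is_monofocal"]

log = logging.getLogger(__name__)


def is_monofocal(profile: SagittalProfile) -> bool:
    name = str(profile.meta.get("design", profile.meta.get("lens", ""))).lower()
    return "monofocal" in name


def _prepared(profile: SagittalProfile) -> SagittalProfile:
    """Remove the base (distance) prescription recorded in the metadata."""
    base = float(profile.meta.get("base_power_D", 0.0))
    return remove_base_power(profile, base) if base else profile


def _zone_count(cfg: RunConfig, profile: SagittalProfile, R: float) -> int | None:
    if cfg.zone_cap is None:
        return None
    return min(default_zone_count(profile, R), cfg.zone_cap)


def _sweep(profile, eye, cfg, shift_d, meta):
    meta = dict(meta, pupil_diameter_mm=eye.pupil_diameter_mm)
    assembly = combine_with_eye(
        profile,
        eye,
        grid=cfg.grid(),
        n_zones=_zone_count(cfg, profile, min(eye.pupil_radius_mm, profile.max_radius_mm)),
    )
    log.debug(
        "aperture R=%.3f mm for lens=%s eye=%s",
        assembly.aperture_radius_mm,
        meta.get("lens"),
        eye.eye_id,
    )
    return through_focus_curve(
        assembly,
        vergences=cfg.vergence_grid(),
        csf=cfg.neural_csf(),
        shift_d=shift_d,
        freq_cutoff_cpd=cfg.freq_cutoff_cpd,
        meta=meta,
    )


def evaluate_study(
    profiles: list[SagittalProfile],
    eyes: list[EyeRecord],
    cfg: RunConfig | None = None,
    outdir=None,
) -> pd.DataFrame:
    """Evaluate every (multifocal lens, eye) pair against the monofocal reference.

    Returns a tidy DataFrame (one row per pair, plus the monofocal rows)
    and, if ``outdir`` is given, writes per-pair curve CSVs under
    ``curves/``, monofocal reference curves under ``monofocal/``, the
    per-pair metrics table and per-lens mean +/- SD curves.
    """
    cfg = cfg or RunConfig()
    monofocals = [p for p in profiles if is_monofocal(p)]
    if not monofocals:
        raise ValueError("no monofocal reference profile in the batch")
    mono_profile = _prepared(monofocals[0])
    multifocals = [_prepared(p) for p in profiles if not is_monofocal(p)]

    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "curves").mkdir(parents=True, exist_ok=True)
        (outdir / "monofocal").mkdir(parents=True, exist_ok=True)

    rows = []
    lens_curves: dict[str, list[np.ndarray]] = {}
    for eye in eyes:
        raw_mono = _sweep(
            mono_profile, eye, cfg, 0.0, {"lens": "monofocal", "eye_id": eye.eye_id}
        )
        shift = equivalent_sphere_shift(raw_mono)
        mono_curve = _sweep(
            mono_profile, eye, cfg, shift, {"lens": "monofocal", "eye_id": eye.eye_id}
        )
        mono_metrics = metrics_report(mono_curve, cfg.threshold)
        if outdir is not None:
            mono_curve.to_csv(outdir / "monofocal" / f"{eye.eye_id}.csv")
        rows.append(
            _row("monofocal", eye, shift, mono_metrics, mono_profile)
            | {"area_pct": 100.0, "range_pct": 100.0, "peak_pct": 100.0}
        )
        for profile in multifocals:
            lens = str(profile.meta.get("lens", "lens"))
            curve = _sweep(profile, eye, cfg, shift, {"lens": lens, "eye_id": eye.eye_id})
            metrics = metrics_report(curve, cfg.threshold)
            try:
                metrics = normalize_to_monofocal(metrics, mono_metrics)
                normalized = metrics.normalized
            except ZeroDivisionError:
                log.warning(
                    "eye %s: monofocal reference metric is zero; "
                    "normalized percentages undefined", eye.eye_id,
                )
                normalized = {"area_pct": np.nan, "range_pct": np.nan, "peak_pct": np.nan}
            if outdir is not None:
                curve.to_csv(outdir / "curves" / f"{_safe(lens)}__{eye.eye_id}.csv")
            lens_curves.setdefault(lens, []).append(curve.values)
            rows.append(_row(lens, eye, shift, metrics, profile) | normalized)

    df = pd.DataFrame(rows)
    if outdir is not None:
        df.to_csv(outdir / "metrics.csv", index=False)
        verg = cfg.vergence_grid()
        mean_dir = outdir / "mean_curves"
        mean_dir.mkdir(exist_ok=True)
        for lens, stack in lens_curves.items():
            arr = np.vstack(stack)
            pd.DataFrame(
                {
                    "vergence_D": verg,
                    "vsotf_mean": arr.mean(axis=0),
                    "vsotf_sd": arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else 0.0,
                }
            ).to_csv(mean_dir / f"{_safe(lens)}.csv", index=False)
    return df


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-._" else "_" for c in name)


def _row(lens, eye, shift, metrics, profile):
    return {
        "lens": lens,
        "eye_id": eye.eye_id,
        "pupil_diameter_mm": eye.pupil_diameter_mm,
        "aperture_radius_mm": min(eye.pupil_radius_mm, profile.max_radius_mm),
        "shift_D": shift,
        "area": metrics.area,
        "area_weighted_D": metrics.area_weighted_D,
        "range_D": metrics.range_D,
        "peak": metrics.peak,
        "peak_location_D": metrics.peak_location_D,
    }


def summarize_curves(curves_dir, threshold: float = 0.12) -> dict[str, pd.DataFrame]:
    """Recompute metrics from curve files and aggregate per lens and per eye.

    Reads every curve CSV under ``curves_dir`` (layout written by
    :func:`evaluate_study`), recomputes the three metrics, normalizes each
    (lens, eye) pair by that eye's monofocal reference, and returns
    ``{"per_lens": ..., "per_eye": ...}`` summary tables.
    """
    curves_dir = Path(curves_dir)
    mono_files = sorted((curves_dir / "monofocal").glob("*.csv"))
    multi_files = sorted((curves_dir / "curves").glob("*.csv"))
    if not mono_files and not multi_files:
        raise FileNotFoundError(f"no curve files found under {curves_dir}")
    mono_metrics = {}
    for path in mono_files:
        curve = ThroughFocusCurve.from_csv(path)
        mono_metrics[curve.meta.get("eye_id", path.stem)] = metrics_report(
            curve, threshold
        )
    rows = []
    for path in mono_files:
        curve = ThroughFocusCurve.from_csv(path)
        m = mono_metrics[curve.meta.get("eye_id", path.stem)]
        rows.append(
            {
                "lens": "monofocal",
                "eye_id": curve.meta.get("eye_id", path.stem),
                "area": m.area,
                "range_D": m.range_D,
                "peak": m.peak,
                "area_pct": 100.0,
                "range_pct": 100.0,
                "peak_pct": 100.0,
            }
        )
    for path in multi_files:
        curve = ThroughFocusCurve.from_csv(path)
        eye_id = curve.meta.get("eye_id", "")
        m = metrics_report(curve, threshold)
        row = {
            "lens": curve.meta.get("lens", path.stem),
            "eye_id": eye_id,
            "pupil_diameter_mm": curve.meta.get("pupil_diameter_mm", np.nan),
            "area": m.area,
            "range_D": m.range_D,
            "peak": m.peak,
        }
        if eye_id in mono_metrics:
            norm = normalize_to_monofocal(m, mono_metrics[eye_id]).normalized
            row |= norm
        rows.append(row)
    df = pd.DataFrame(rows)
    agg_cols = [c for c in ("area", "range_D", "peak", "area_pct", "range_pct", "peak_pct") if c in df]
    per_lens = df.groupby("lens")[agg_cols].agg(["mean", "std"])
    per_lens.columns = ["_".join(c) for c in per_lens.columns]
    per_lens = per_lens.reset_index()
    multi = df[df["lens"] != "monofocal"]
    eye_cols = ["area", "range_D", "peak"]
    if "pupil_diameter_mm" in multi:
        eye_cols = ["pupil_diameter_mm", *eye_cols]
    per_eye = multi.groupby("eye_id")[eye_cols].mean().reset_index()
    return {"per_lens": per_lens, "per_eye": per_eye, "per_pair": df}
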