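"""Study/report readers and writers, and run configuration.

On-disk layout of a study directory::

    manifest.json          all metadata: specs, times, calibration, truth
    labels.nii.gz          integer organ label volume (label map in manifest)
    body.nii.gz            body mask
    mu.nii.gz              attenuation volume (cm^-1)
    density.nii.gz         density volume (g/mL)
    syringe_roi.nii.gz     calibration-standard ROI on the planar grid
    planar_000_ant.nii.gz  anterior planar image of time point 0, ...
    spect_000.nii.gz       SPECT volume of time point 0 (if acquired), ...

All volumetric data are NIfTI; tabular outputs are CSV; manifests and
comparisons are JSON. Reading a directory without SPECT volumes yields a
dataset flagged planar-only rather than an error.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .constants import LU177_HALF_LIFE_H, LU177_MEAN_ELECTRON_ENERGY_MEV
from .errors import ConfigError, GeometryError
from .phantom import (
    AcquisitionSpec,
    AdministrationRecord,
    CalibrationStandard,
    OrganSpec,
    OrganTruth,
    Phantom,
    PhantomSpec,
    Shape,
    StudyDataset,
    TruthRecord,
)
from .scenarios import ScenarioComparison, ScenarioResult


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Normalized pipeline configuration (units: h, MBq/GBq, mm, g, Gy)."""

    preset: str = "paper_like"
    seed: int = 0
    scenario: str = "all"
    t_ref_h: float = 24.0
    physical_half_life_h: float = LU177_HALF_LIFE_H
    delta_e_mev: float = LU177_MEAN_ELECTRON_ENERGY_MEV
    noise: bool = False
    administered_activity_gbq: float = 7.2
    planar_sensitivity_cps_per_mbq: float | None = None


_CONFIG_KEYS = {
    "preset",
    "seed",
    "scenario",
    "t_ref_h",
    "physical_half_life_h",
    "half_life_days",
    "delta_e_mev",
    "noise",
    "administered_activity_gbq",
    "planar_sensitivity_cps_per_mbq",
}


def validate_config(cfg: Mapping | None) -> RunConfig:
    """Fill defaults, normalize units and reject unknown keys."""
    cfg = dict(cfg or {})
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if "half_life_days" in cfg:
        if "physical_half_life_h" in cfg:
            raise ConfigError("give the half-life in days or hours, not both")
        cfg["physical_half_life_h"] = float(cfg.pop("half_life_days")) * 24.0
    out = RunConfig(**cfg)
    if out.physical_half_life_h <= 0:
        raise ConfigError("physical half-life must be positive")
    if out.delta_e_mev <= 0:
        raise ConfigError("energy per decay must be positive")
    if out.administered_activity_gbq <= 0:
        raise ConfigError("administered activity must be positive")
    if (
        out.planar_sensitivity_cps_per_mbq is not None
        and out.planar_sensitivity_cps_per_mbq <= 0
    ):
        raise ConfigError("planar sensitivity must be positive")
    if out.scenario not in ("all", "multi_spect", "planar", "hybrid"):
        raise ConfigError(f"unknown scenario {out.scenario!r}")
    return out


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# (de)serialisation helpers
# ---------------------------------------------------------------------------


def _nifti_write(path: Path, data: np.ndarray, voxel_mm: float) -> None:
    img = nib.Nifti1Image(np.asarray(data), np.diag([voxel_mm] * 3 + [1.0]))
    nib.save(img, str(path))


def _nifti_read(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def _finite(x: float) -> float | None:
    return None if math.isinf(x) else x


def _or_inf(x) -> float:
    return math.inf if x is None else float(x)


def _organ_to_dict(o: OrganSpec) -> dict:
    return {
        "name": o.name,
        "shape": {
            "kind": o.shape.kind,
            "center_mm": list(o.shape.center_mm),
            "semi_axes_mm": list(o.shape.semi_axes_mm),
        },
        "density_g_ml": o.density_g_ml,
        "uptake_fraction": o.uptake_fraction,
        "biological_half_life_h": _finite(o.biological_half_life_h),
        "is_tumour": o.is_tumour,
        "host_organ": o.host_organ,
        "attenuation_cm1": o.attenuation_cm1,
    }


def _organ_from_dict(d: dict) -> OrganSpec:
    return OrganSpec(
        name=d["name"],
        shape=Shape(
            d["shape"]["kind"],
            tuple(d["shape"]["center_mm"]),
            tuple(d["shape"]["semi_axes_mm"]),
        ),
        density_g_ml=d["density_g_ml"],
        uptake_fraction=d["uptake_fraction"],
        biological_half_life_h=_or_inf(d["biological_half_life_h"]),
        is_tumour=d["is_tumour"],
        host_organ=d["host_organ"],
        attenuation_cm1=d["attenuation_cm1"],
    )


def write_study(study: StudyDataset, out_dir) -> Path:
    """Serialise a study dataset (NIfTI volumes + central JSON manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    phantom = study.phantom
    vx = phantom.voxel_size_mm

    labels = np.zeros(phantom.spec.grid_shape, dtype=np.int16)
    label_map = {}
    for i, name in enumerate(study.organ_names, start=1):
        labels[phantom.masks[name]] = i
        label_map[name] = i
    _nifti_write(out / "labels.nii.gz", labels, vx)
    _nifti_write(out / "body.nii.gz", phantom.body_mask.astype(np.uint8), vx)
    _nifti_write(out / "mu.nii.gz", phantom.mu_cm1, vx)
    _nifti_write(out / "density.nii.gz", phantom.density_g_ml, vx)
    _nifti_write(out / "syringe_roi.nii.gz", study.syringe_roi.astype(np.uint8), vx)

    times = list(study.time_points_h)
    for i, t in enumerate(times):
        ant, post = study.planar[t]
        _nifti_write(out / f"planar_{i:03d}_ant.nii.gz", ant, vx)
        _nifti_write(out / f"planar_{i:03d}_post.nii.gz", post, vx)
        if t in study.spect:
            _nifti_write(out / f"spect_{i:03d}.nii.gz", study.spect[t], vx)

    spec = phantom.spec
    manifest = {
        "format_version": 1,
        "package_version": __version__,
        "time_points_h": times,
        "spect_time_points_h": list(study.spect_time_points_h),
        "label_map": label_map,
        "phantom_spec": {
            "grid_shape": list(spec.grid_shape),
            "voxel_size_mm": spec.voxel_size_mm,
            "organs": [_organ_to_dict(o) for o in spec.organs],
            "body": {
                "kind": spec.body.kind,
                "center_mm": list(spec.body.center_mm),
                "semi_axes_mm": list(spec.body.semi_axes_mm),
            },
            "background_uptake_fraction": spec.background_uptake_fraction,
            "background_half_life_h": _finite(spec.background_half_life_h),
            "mu_body_cm1": spec.mu_body_cm1,
            "body_density_g_ml": spec.body_density_g_ml,
        },
        "acquisition": {
            "time_points_h": list(study.acq.time_points_h),
            "spect_time_points_h": (
                None
                if study.acq.spect_time_points_h is None
                else list(study.acq.spect_time_points_h)
            ),
            "physical_half_life_h": study.acq.physical_half_life_h,
            "planar_sensitivity_cps_per_mbq": study.acq.planar_sensitivity_cps_per_mbq,
            "planar_duration_s": study.acq.planar_duration_s,
            "spect_psf_fwhm_mm": study.acq.spect_psf_fwhm_mm,
            "planar_psf_fwhm_mm": study.acq.planar_psf_fwhm_mm,
            "noise": study.acq.noise,
            "spect_noise_sd": study.acq.spect_noise_sd,
            "seed": study.acq.seed,
        },
        "administration": {"activity_gbq": study.admin.activity_gbq},
        "calibration": {
            "nominal_activity_mbq": study.calibration.nominal_activity_mbq,
            "reference_time_h": study.calibration.reference_time_h,
            "volume_ml": study.calibration.volume_ml,
            "center_mm": (
                None
                if study.calibration.center_mm is None
                else list(study.calibration.center_mm)
            ),
            "duration_s": study.calibration.duration_s,
            "measurements": {str(i): study.calibration.measurements[t] for i, t in enumerate(times)},
        },
        "spect_calibration_factor": study.spect_calibration_factor,
        "truth": None
        if study.truth is None
        else {
            "organs": {
                name: dataclasses.asdict(tr) for name, tr in study.truth.organs.items()
            },
            "background_uptake_fraction": study.truth.background_uptake_fraction,
            "background_lambda_eff_per_h": study.truth.background_lambda_eff_per_h,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_study(study_dir) -> StudyDataset:
    """Load a study directory written by :func:`write_study`.

    Geometry consistency (shapes, voxel size) is enforced; missing SPECT
    frames are tolerated (the dataset is then only usable for the planar and,
    if one SPECT exists, hybrid workflows).
    """
    d = Path(study_dir)
    manifest_path = d / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {d}")
    manifest = json.loads(manifest_path.read_text())

    ps = manifest["phantom_spec"]
    spec = PhantomSpec(
        grid_shape=tuple(ps["grid_shape"]),
        voxel_size_mm=ps["voxel_size_mm"],
        organs=tuple(_organ_from_dict(o) for o in ps["organs"]),
        body=Shape(
            ps["body"]["kind"],
            tuple(ps["body"]["center_mm"]),
            tuple(ps["body"]["semi_axes_mm"]),
        ),
        background_uptake_fraction=ps["background_uptake_fraction"],
        background_half_life_h=_or_inf(ps["background_half_life_h"]),
        mu_body_cm1=ps["mu_body_cm1"],
        body_density_g_ml=ps["body_density_g_ml"],
    )

    labels = _nifti_read(d / "labels.nii.gz")
    body = _nifti_read(d / "body.nii.gz").astype(bool)
    mu = _nifti_read(d / "mu.nii.gz")
    density = _nifti_read(d / "density.nii.gz")
    grid = tuple(labels.shape)
    if grid != tuple(spec.grid_shape):
        raise GeometryError(
            f"label volume {grid} does not match manifest grid {spec.grid_shape}"
        )
    masks = {
        name: labels == idx for name, idx in manifest["label_map"].items()
    }
    background = body.copy()
    for m in masks.values():
        background &= ~m
    phantom = Phantom(
        spec=spec,
        masks=masks,
        body_mask=body,
        background_mask=background,
        density_g_ml=density,
        mu_cm1=mu,
    )

    aq = manifest["acquisition"]
    acq = AcquisitionSpec(
        time_points_h=tuple(aq["time_points_h"]),
        spect_time_points_h=(
            None if aq["spect_time_points_h"] is None else tuple(aq["spect_time_points_h"])
        ),
        physical_half_life_h=aq["physical_half_life_h"],
        planar_sensitivity_cps_per_mbq=aq["planar_sensitivity_cps_per_mbq"],
        planar_duration_s=aq["planar_duration_s"],
        spect_psf_fwhm_mm=aq["spect_psf_fwhm_mm"],
        planar_psf_fwhm_mm=aq["planar_psf_fwhm_mm"],
        noise=aq["noise"],
        spect_noise_sd=aq["spect_noise_sd"],
        seed=aq["seed"],
    )
    times = [float(t) for t in manifest["time_points_h"]]
    if list(acq.time_points_h) != times:
        raise GeometryError("acquisition and study time points disagree")

    planar = {}
    spect = {}
    for i, t in enumerate(times):
        ant_p = d / f"planar_{i:03d}_ant.nii.gz"
        post_p = d / f"planar_{i:03d}_post.nii.gz"
        if not ant_p.exists() or not post_p.exists():
            raise FileNotFoundError(f"missing planar pair for time point {t} h")
        ant = _nifti_read(ant_p)
        post = _nifti_read(post_p)
        if ant.shape != (grid[0], grid[2]) or post.shape != (grid[0], grid[2]):
            raise GeometryError(f"planar image shape mismatch at t={t} h")
        planar[t] = (ant, post)
        sp = d / f"spect_{i:03d}.nii.gz"
        if sp.exists():
            vol = _nifti_read(sp)
            if vol.shape != grid:
                raise GeometryError(f"SPECT volume shape mismatch at t={t} h")
            spect[t] = vol

    cal = manifest["calibration"]
    calibration = CalibrationStandard(
        nominal_activity_mbq=cal["nominal_activity_mbq"],
        reference_time_h=cal["reference_time_h"],
        volume_ml=cal["volume_ml"],
        center_mm=None if cal["center_mm"] is None else tuple(cal["center_mm"]),
        duration_s=cal["duration_s"],
        measurements={times[int(i)]: v for i, v in cal["measurements"].items()},
    )

    truth = None
    if manifest["truth"] is not None:
        tr = manifest["truth"]
        truth = TruthRecord(
            organs={
                name: OrganTruth(**vals) for name, vals in tr["organs"].items()
            },
            background_uptake_fraction=tr["background_uptake_fraction"],
            background_lambda_eff_per_h=tr["background_lambda_eff_per_h"],
        )

    return StudyDataset(
        phantom=phantom,
        acq=acq,
        admin=AdministrationRecord(activity_gbq=manifest["administration"]["activity_gbq"]),
        calibration=calibration,
        planar=planar,
        spect=spect,
        syringe_roi=_nifti_read(d / "syringe_roi.nii.gz").astype(bool),
        truth=truth,
        spect_calibration_factor=manifest["spect_calibration_factor"],
    )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def write_reports(
    results: Mapping[str, ScenarioResult],
    out_dir,
    comparison: ScenarioComparison | None = None,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> Path:
    """Write doses.csv, residence_times.csv, tacs.csv (+ comparison.json).

    The run manifest records the seed, the package version and a hash of the
    configuration so a run can be reproduced byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    dose_rows = []
    rt_rows = []
    tac_rows = []
    for scenario, result in sorted(results.items()):
        dose_rows.append(result.dose_frame())
        for name in sorted(result.fits):
            f = result.fits[name]
            rt_rows.append(
                {
                    "organ": name,
                    "method": scenario,
                    "A0_MBq": f.a0_mbq,
                    "lambda_per_h": f.lambda_eff_per_h,
                    "tau_h": result.residence_times[name].tau_h,
                    "r2": f.r_squared,
                    "flags": "" if f.converged else "not_converged",
                }
            )
            tac = result.tacs[name]
            for t, a in zip(tac.times_h, tac.activities_mbq):
                tac_rows.append(
                    {
                        "organ": name,
                        "time_h": t,
                        "activity_MBq": a,
                        "method": scenario,
                    }
                )
    pd.concat(dose_rows, ignore_index=True).to_csv(out / "doses.csv", index=False)
    pd.DataFrame(rt_rows).to_csv(out / "residence_times.csv", index=False)
    pd.DataFrame(tac_rows).to_csv(out / "tacs.csv", index=False)

    if comparison is not None:
        (out / "comparison.json").write_text(
            json.dumps(comparison.to_dict(), indent=1, sort_keys=True)
        )

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": None if config is None else dataclasses.asdict(config),
        "config_hash": None if config is None else config_hash(config),
        "scenarios": sorted(results),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
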