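"""Bundled phantom configurations.

``paper_like`` is the default demonstration phantom. Its geometry was
constructed so the known failure modes of planar dosimetry are all present:

* an attenuating, finite-thickness body (soft tissue at 208 keV),
* a large, slowly washing-out liver whose projection overlaps the right
  kidney in the anterior-posterior view,
* a uniform soft-tissue background compartment filling the rest of the body,
* a low-density lung compartment whose thickness varies strongly across its
  footprint (a single thickness weighting factor cannot be right everywhere),
* a small spherical tumour inside the liver (partial-volume territory),
* a calibration syringe in air below the feet.

``no_physics`` switches all of that off (no attenuation, no blur, no noise,
no background, organs disjoint in projection); on it the three workflows must
agree, which makes it the null configuration for equivalence tests.
"""
from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .constants import MU_LUNG_208KEV_CM1, MU_WATER_208KEV_CM1
from .errors import PhantomError
from .phantom import (
    AcquisitionSpec,
    AdministrationRecord,
    CalibrationStandard,
    OrganSpec,
    PhantomSpec,
    Shape,
    StudyDataset,
    simulate_study,
)

PRESETS = ("paper_like", "no_physics")


def paper_like_phantom() -> PhantomSpec:
    """Thorax/abdomen phantom with liver-over-right-kidney projection overlap."""
    organs = (
        OrganSpec(
            name="liver",
            shape=Shape("ellipsoid", (150.0, 45.0, 185.0), (60.0, 30.0, 42.0)),
            density_g_ml=1.06,
            uptake_fraction=0.25,
            biological_half_life_h=120.0,
        ),
        OrganSpec(
            name="kidney_right",
            shape=Shape("ellipsoid", (150.0, 88.0, 145.0), (22.0, 14.0, 35.0)),
            density_g_ml=1.05,
            uptake_fraction=0.02,
            biological_half_life_h=60.0,
        ),
        OrganSpec(
            name="kidney_left",
            shape=Shape("ellipsoid", (66.0, 88.0, 145.0), (22.0, 14.0, 35.0)),
            density_g_ml=1.05,
            uptake_fraction=0.02,
            biological_half_life_h=60.0,
        ),
        OrganSpec(
            name="spleen",
            shape=Shape("ellipsoid", (60.0, 60.0, 215.0), (20.0, 14.0, 28.0)),
            density_g_ml=1.06,
            uptake_fraction=0.02,
            biological_half_life_h=90.0,
        ),
        OrganSpec(
            name="lungs",
            shape=Shape("ellipsoid", (128.0, 56.0, 258.0), (42.0, 22.0, 26.0)),
            density_g_ml=0.26,
            uptake_fraction=0.01,
            biological_half_life_h=40.0,
            attenuation_cm1=MU_LUNG_208KEV_CM1,
        ),
        OrganSpec(
            name="tumour",
            shape=Shape("sphere", (172.0, 45.0, 196.0), (15.0, 15.0, 15.0)),
            density_g_ml=1.06,
            uptake_fraction=0.012,
            biological_half_life_h=160.0,
            is_tumour=True,
            host_organ="liver",
        ),
    )
    return PhantomSpec(
        grid_shape=(64, 28, 96),
        voxel_size_mm=4.0,
        organs=organs,
        body=Shape("ellipsoid", (128.0, 56.0, 150.0), (110.0, 50.0, 145.0)),
        background_uptake_fraction=0.40,
        background_half_life_h=70.0,
        mu_body_cm1=MU_WATER_208KEV_CM1,
    )


def no_physics_phantom() -> PhantomSpec:
    """Disjoint organs, no attenuation, no background: the null configuration."""
    organs = (
        OrganSpec(
            name="kidney",
            shape=Shape("sphere", (60.0, 48.0, 80.0), (16.0, 16.0, 16.0)),
            density_g_ml=1.05,
            uptake_fraction=0.03,
            biological_half_life_h=60.0,
        ),
        OrganSpec(
            name="liver",
            shape=Shape("ellipsoid", (130.0, 48.0, 90.0), (30.0, 20.0, 25.0)),
            density_g_ml=1.06,
            uptake_fraction=0.20,
            biological_half_life_h=120.0,
        ),
        OrganSpec(
            name="spleen",
            shape=Shape("sphere", (60.0, 48.0, 180.0), (18.0, 18.0, 18.0)),
            density_g_ml=1.06,
            uptake_fraction=0.02,
            biological_half_life_h=90.0,
        ),
    )
    return PhantomSpec(
        grid_shape=(48, 24, 72),
        voxel_size_mm=4.0,
        organs=organs,
        body=Shape("box", (96.0, 48.0, 124.0), (80.0, 40.0, 110.0)),
        background_uptake_fraction=0.0,
        mu_body_cm1=0.0,
    )


def default_acquisition(preset: str = "paper_like", noise: bool = False, seed: int = 0) -> AcquisitionSpec:
    if preset == "paper_like":
        return AcquisitionSpec(
            planar_psf_fwhm_mm=8.0,
            spect_psf_fwhm_mm=10.0,
            noise=noise,
            seed=seed,
        )
    if preset == "no_physics":
        return AcquisitionSpec(
            planar_psf_fwhm_mm=0.0,
            spect_psf_fwhm_mm=0.0,
            noise=noise,
            seed=seed,
        )
    raise PhantomError(f"unknown preset {preset!r}; choose one of {PRESETS}")


def default_calibration(preset: str = "paper_like") -> CalibrationStandard:
    if preset == "no_physics":
        # smaller syringe so it fits below the feet of the compact grid
        return CalibrationStandard(volume_ml=12.0)
    return CalibrationStandard()


def simulate_preset_study(
    preset: str = "paper_like",
    seed: int = 0,
    noise: bool = False,
    administered_gbq: float = 7.2,
) -> StudyDataset:
    """Simulate a complete study from one of the bundled presets."""
    if preset == "paper_like":
        spec = paper_like_phantom()
    elif preset == "no_physics":
        spec = no_physics_phantom()
    else:
        raise PhantomError(f"unknown preset {preset!r}; choose one of {PRESETS}")
    return simulate_study(
        spec,
        default_acquisition(preset, noise=noise, seed=seed),
        AdministrationRecord(activity_gbq=administered_gbq),
        default_calibration(preset),
    )


def jitter_phantom(
    base: PhantomSpec, rng: np.random.Generator, max_attempts: int = 25
) -> PhantomSpec:
    """Perturb organ sizes, positions and kinetics to emulate a new patient.

    Semi-axes scale by up to +/-8% per axis, centres shift by up to 4 mm in
    the x/z plane (the anterior-posterior layout is kept so overlap topology
    is preserved), uptake fractions and biological half-lives jitter
    log-normally. Draws that produce 3D-overlapping organs are rejected and
    redrawn.
    """
    for _ in range(max_attempts):
        organs = []
        for o in base.organs:
            cx, cy, cz = o.shape.center_mm
            ax, ay, az = o.shape.semi_axes_mm
            scale = rng.uniform(0.92, 1.08, size=3)
            shift = rng.uniform(-4.0, 4.0, size=2)
            shape = Shape(
                o.shape.kind,
                (cx + shift[0], cy, cz + shift[1]),
                (ax * scale[0], ay * scale[1], az * scale[2]),
            )
            organs.append(
                replace(
                    o,
                    shape=shape,
                    uptake_fraction=float(
                        o.uptake_fraction * rng.lognormal(0.0, 0.25)
                    ),
                    biological_half_life_h=float(
                        o.biological_half_life_h * rng.lognormal(0.0, 0.20)
                    )
                    if math.isfinite(o.biological_half_life_h)
                    else o.biological_half_life_h,
                )
            )
        try:
            spec = replace(base, organs=tuple(organs))
            from .phantom import build_phantom

            build_phantom(spec)  # validates geometry
            return spec
        except PhantomError:
            continue
    raise PhantomError("could not draw a geometrically valid jittered phantom")


def simulate_cohort(
    n_studies: int,
    seed: int = 0,
    preset: str = "paper_like",
    noise: bool = False,
    time_points_h: tuple[float, ...] | None = None,
) -> list[StudyDataset]:
    """Simulate a cohort of patient-equivalent studies by seeded jitter."""
    if preset == "paper_like":
        base = paper_like_phantom()
    elif preset == "no_physics":
        base = no_physics_phantom()
    else:
        raise PhantomError(f"unknown preset {preset!r}; choose one of {PRESETS}")
    rng = np.random.default_rng(seed)
    studies = []
    for i in range(n_studies):
        spec = jitter_phantom(base, rng)
        acq = default_acquisition(preset, noise=noise, seed=int(rng.integers(2**31)))
        if time_points_h is not None:
            acq = replace(acq, time_points_h=time_points_h)
        admin = AdministrationRecord(
            activity_gbq=float(np.clip(rng.normal(7.2, 0.4), 5.0, 9.0))
        )
        studies.append(simulate_study(spec, acq, admin, default_calibration(preset)))
    return studies
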