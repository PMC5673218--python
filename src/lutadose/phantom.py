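"""Digital phantoms for 177Lu planar/SPECT dosimetry studies.

This module generates synthetic, ground-truth-annotated imaging studies with
the statistical structure the downstream analysis assumes:

* mono-exponential organ washout on top of physical decay,
* photon attenuation along the anterior-posterior axis in planar views,
* finite-resolution Gaussian blur (the source of partial-volume losses),
* Poisson counting noise on planar images (optional),
* organs that are disjoint in 3D but may overlap in 2D projection,
* a co-scanned calibration syringe placed in air below the feet.

Geometry conventions
--------------------
Volumes are indexed ``(x, y, z)``; planar projection is along the ``y`` axis
with the *anterior* detector on the ``-y`` side. The posterior view is returned
as the camera sees it, i.e. mirrored left-right (``x``) relative to the
anterior frame; :func:`lutadose.quantify.geometric_mean` undoes the mirror.
Voxel ``i`` is centred at ``(i + 0.5) * voxel_size_mm``. All masks are boolean
arrays on the same grid.

SPECT volumes are produced directly as quantitative activity maps (MBq per
voxel), i.e. post-reconstruction and post-attenuation-correction; tomographic
reconstruction is deliberately not modelled. The SPECT calibration factor is
therefore 1 by default but still flows through the quantification code path.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .constants import (
    LU177_HALF_LIFE_H,
    LU177_MEAN_ELECTRON_ENERGY_MEV,
    MU_WATER_208KEV_CM1,
)
from .errors import GeometryError, PhantomError

Vec3 = tuple[float, float, float]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


# ---------------------------------------------------------------------------
# geometric primitives and specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Shape:
    """Geometric primitive: ``ellipsoid``, ``sphere`` or ``box``.

    ``center_mm`` and ``semi_axes_mm`` are in millimetres; a sphere may be
    given a single radius which is broadcast to three semi-axes. For a box the
    semi-axes are half edge lengths.
    """

    kind: str
    center_mm: Vec3
    semi_axes_mm: Vec3

    def __post_init__(self):
        if self.kind not in ("ellipsoid", "sphere", "box"):
            raise PhantomError(f"unknown shape kind {self.kind!r}")
        semi = np.atleast_1d(np.asarray(self.semi_axes_mm, dtype=float))
        if semi.size == 1:
            semi = np.repeat(semi, 3)
        if semi.size != 3:
            raise PhantomError("semi_axes_mm must be a scalar or length-3")
        if np.any(semi <= 0):
            raise PhantomError("semi-axes must be positive")
        center = np.asarray(self.center_mm, dtype=float)
        if center.size != 3:
            raise PhantomError("center_mm must be length-3")
        object.__setattr__(self, "semi_axes_mm", tuple(semi))
        object.__setattr__(self, "center_mm", tuple(center))

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        cx, cy, cz = self.center_mm
        ax, ay, az = self.semi_axes_mm
        if self.kind == "box":
            return (
                (np.abs(x - cx) <= ax)
                & (np.abs(y - cy) <= ay)
                & (np.abs(z - cz) <= az)
            )
        return (
            ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
        ) <= 1.0

    def bounding_box_mm(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center_mm)
        s = np.asarray(self.semi_axes_mm)
        return c - s, c + s


@dataclass(frozen=True)
class OrganSpec:
    """One organ (or tumour) of the phantom.

    ``uptake_fraction`` is the fraction of the administered activity residing
    in the organ at t=0; ``biological_half_life_h`` may be ``math.inf`` for a
    purely physically decaying compartment. ``attenuation_cm1`` overrides the
    body attenuation coefficient inside the organ (e.g. lung).
    """

    name: str
    shape: Shape
    density_g_ml: float
    uptake_fraction: float
    biological_half_life_h: float = math.inf
    is_tumour: bool = False
    host_organ: str | None = None
    attenuation_cm1: float | None = None

    def __post_init__(self):
        if self.density_g_ml <= 0:
            raise PhantomError(f"organ {self.name!r}: density must be positive")
        if self.uptake_fraction < 0:
            raise PhantomError(f"organ {self.name!r}: uptake fraction must be >= 0")
        if self.biological_half_life_h <= 0:
            raise PhantomError(f"organ {self.name!r}: biological half-life must be > 0")
        if self.attenuation_cm1 is not None and self.attenuation_cm1 < 0:
            raise PhantomError(f"organ {self.name!r}: attenuation must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description: grid, body, organs and background kinetics."""

    grid_shape: tuple[int, int, int]
    voxel_size_mm: float
    organs: tuple[OrganSpec, ...]
    body: Shape
    background_uptake_fraction: float = 0.0
    background_half_life_h: float = math.inf
    mu_body_cm1: float = MU_WATER_208KEV_CM1
    body_density_g_ml: float = 1.0

    def __post_init__(self):
        if self.voxel_size_mm <= 0:
            raise PhantomError("voxel size must be positive")
        if self.mu_body_cm1 < 0:
            raise PhantomError("attenuation must be >= 0")
        if self.background_uptake_fraction < 0:
            raise PhantomError("background uptake fraction must be >= 0")
        names = [o.name for o in self.organs]
        if len(set(names)) != len(names):
            raise PhantomError("organ names must be unique")
        total = sum(o.uptake_fraction for o in self.organs)
        total += self.background_uptake_fraction
        if total > 1.0 + 1e-9:
            raise PhantomError(
                f"uptake fractions sum to {total:.4f} > 1 (organs + background)"
            )
        object.__setattr__(self, "organs", tuple(self.organs))

    def organ(self, name: str) -> OrganSpec:
        for o in self.organs:
            if o.name == name:
                return o
        raise KeyError(name)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Imaging protocol: time points, camera characteristics and noise.

    Default time points follow a five-day protocol between 4 h and 168 h p.i.
    ``spect_time_points_h=None`` means a SPECT volume at every planar time
    point (multi-SPECT-style study); a hybrid-style study lists a subset.
    """

    time_points_h: tuple[float, ...] = (4.0, 24.0, 48.0, 72.0, 168.0)
    spect_time_points_h: tuple[float, ...] | None = None
    physical_half_life_h: float = LU177_HALF_LIFE_H
    planar_sensitivity_cps_per_mbq: float = 10.0
    planar_duration_s: float = 120.0
    spect_psf_fwhm_mm: float = 0.0
    planar_psf_fwhm_mm: float = 0.0
    noise: bool = False
    spect_noise_sd: float = 0.0  # multiplicative Gaussian sd on SPECT voxels
    seed: int = 0

    def __post_init__(self):
        tp = tuple(float(t) for t in self.time_points_h)
        if len(tp) < 2:
            raise PhantomError("at least two time points are required")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise PhantomError("time points must be strictly increasing")
        if any(t < 0 for t in tp):
            raise PhantomError("time points must be >= 0")
        if self.physical_half_life_h <= 0:
            raise PhantomError("physical half-life must be positive")
        if self.planar_sensitivity_cps_per_mbq <= 0:
            raise PhantomError("planar sensitivity must be positive")
        if self.planar_duration_s <= 0:
            raise PhantomError("planar duration must be positive")
        if self.spect_psf_fwhm_mm < 0 or self.planar_psf_fwhm_mm < 0:
            raise PhantomError("PSF FWHM must be >= 0")
        object.__setattr__(self, "time_points_h", tp)
        if self.spect_time_points_h is not None:
            sp = tuple(float(t) for t in self.spect_time_points_h)
            if not set(sp) <= set(tp):
                raise PhantomError(
                    "SPECT time points must be a subset of the planar time points"
                )
            object.__setattr__(self, "spect_time_points_h", sp)

    @property
    def effective_spect_time_points_h(self) -> tuple[float, ...]:
        if self.spect_time_points_h is None:
            return self.time_points_h
        return self.spect_time_points_h


@dataclass(frozen=True)
class AdministrationRecord:
    """Administered activity (GBq) at t=0."""

    activity_gbq: float = 7.2

    def __post_init__(self):
        if self.activity_gbq <= 0:
            raise PhantomError("administered activity must be positive")

    @property
    def activity_mbq(self) -> float:
        return self.activity_gbq * 1000.0


@dataclass
class CalibrationStandard:
    """A co-scanned 177Lu-filled syringe used to calibrate the planar camera.

    The syringe sits in air below the feet; ``measurements`` maps each
    acquisition time (h p.i.) to the counts extracted from its ROI on the
    geometric-mean image, filled in by :func:`simulate_study`.
    """

    nominal_activity_mbq: float = 196.0
    reference_time_h: float = 0.0
    volume_ml: float = 50.0
    center_mm: Vec3 | None = None
    duration_s: float | None = None
    measurements: dict[float, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.nominal_activity_mbq <= 0:
            raise PhantomError("calibration activity must be positive")
        if self.volume_ml <= 0:
            raise PhantomError("calibration volume must be positive")

    @property
    def radius_mm(self) -> float:
        return (3.0 * self.volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)

    def activity_at(self, t_h: float, physical_half_life_h: float = LU177_HALF_LIFE_H) -> float:
        lam = math.log(2.0) / physical_half_life_h
        return self.nominal_activity_mbq * math.exp(-lam * (t_h - self.reference_time_h))


@dataclass
class OrganTruth:
    uptake_fraction: float
    lambda_eff_per_h: float
    tau_h: float
    mass_g: float
    dose_gy: float


@dataclass
class TruthRecord:
    """Analytic ground truth for parameter-recovery tests."""

    organs: dict[str, OrganTruth]
    background_uptake_fraction: float
    background_lambda_eff_per_h: float


@dataclass
class Phantom:
    """A built voxel phantom: masks, density and attenuation volumes."""

    spec: PhantomSpec
    masks: dict[str, np.ndarray]
    body_mask: np.ndarray
    background_mask: np.ndarray
    density_g_ml: np.ndarray
    mu_cm1: np.ndarray

    @property
    def voxel_size_mm(self) -> float:
        return self.spec.voxel_size_mm

    @property
    def voxel_volume_ml(self) -> float:
        return (self.spec.voxel_size_mm / 10.0) ** 3

    def organ_volume_ml(self, name: str) -> float:
        return float(self.masks[name].sum()) * self.voxel_volume_ml

    def organ_mass_g(self, name: str) -> float:
        return self.organ_volume_ml(name) * self.spec.organ(name).density_g_ml


@dataclass
class StudyDataset:
    """One patient-equivalent study: planar pairs, SPECT volumes, truth.

    Planar images are stored in the frame each camera sees (posterior mirrored
    in x); ``planar[t] = (anterior, posterior)``.
    """

    phantom: Phantom
    acq: AcquisitionSpec
    admin: AdministrationRecord
    calibration: CalibrationStandard
    planar: dict[float, tuple[np.ndarray, np.ndarray]]
    spect: dict[float, np.ndarray]
    syringe_roi: np.ndarray
    truth: TruthRecord | None = None
    spect_calibration_factor: float = 1.0

    @property
    def time_points_h(self) -> tuple[float, ...]:
        return self.acq.time_points_h

    @property
    def spect_time_points_h(self) -> tuple[float, ...]:
        return tuple(sorted(self.spect.keys()))

    @property
    def organ_names(self) -> tuple[str, ...]:
        return tuple(o.name for o in self.phantom.spec.organs)


# ---------------------------------------------------------------------------
# kinetics of the generator
# ---------------------------------------------------------------------------


def effective_lambda(
    physical_half_life_h: float, biological_half_life_h: float = math.inf
) -> float:
    """Effective decay constant lambda_phys + lambda_bio in h^-1."""
    if physical_half_life_h <= 0:
        raise PhantomError("physical half-life must be positive")
    lam = math.log(2.0) / physical_half_life_h
    if math.isfinite(biological_half_life_h):
        if biological_half_life_h <= 0:
            raise PhantomError("biological half-life must be positive")
        lam += math.log(2.0) / biological_half_life_h
    return lam


def organ_activity(
    organ: OrganSpec,
    admin: AdministrationRecord,
    t_h: float,
    physical_half_life_h: float = LU177_HALF_LIFE_H,
) -> float:
    """Organ activity in MBq at ``t_h`` hours p.i.

    ``A(t) = A_admin * f * exp(-lambda_eff * t)`` with
    ``lambda_eff = ln2/T_phys + ln2/T_bio``.
    """
    if t_h < 0:
        raise PhantomError("time must be >= 0")
    lam = effective_lambda(physical_half_life_h, organ.biological_half_life_h)
    return admin.activity_mbq * organ.uptake_fraction * math.exp(-lam * t_h)


def background_activity(
    spec: PhantomSpec,
    admin: AdministrationRecord,
    t_h: float,
    physical_half_life_h: float = LU177_HALF_LIFE_H,
) -> float:
    """Total soft-tissue background activity in MBq at ``t_h``."""
    if t_h < 0:
        raise PhantomError("time must be >= 0")
    lam = effective_lambda(physical_half_life_h, spec.background_half_life_h)
    return admin.activity_mbq * spec.background_uptake_fraction * math.exp(-lam * t_h)


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------


def _grid_coords(spec: PhantomSpec):
    nx, ny, nz = spec.grid_shape
    dx = spec.voxel_size_mm
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dx
    z = (np.arange(nz) + 0.5) * dx
    return x[:, None, None], y[None, :, None], z[None, None, :]


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterise a :class:`PhantomSpec` onto its voxel grid.

    Organ masks are mutually disjoint in 3D (overlap is only ever allowed in
    2D projection); a tumour with a ``host_organ`` is carved out of its host.
    Raises :class:`PhantomError` naming the offending organ for shapes outside
    the grid or genuinely overlapping 3D definitions.
    """
    x, y, z = _grid_coords(spec)
    extent = np.asarray(spec.grid_shape, dtype=float) * spec.voxel_size_mm

    raw: dict[str, np.ndarray] = {}
    for organ in spec.organs:
        lo, hi = organ.shape.bounding_box_mm()
        if np.any(lo < 0) or np.any(hi > extent):
            raise PhantomError(f"organ {organ.name!r} extends outside the grid")
        mask = organ.shape.contains(x, y, z)
        if not mask.any():
            raise PhantomError(f"organ {organ.name!r} has an empty mask")
        raw[organ.name] = mask

    masks = {name: m.copy() for name, m in raw.items()}
    for organ in spec.organs:
        if organ.host_organ is not None:
            if organ.host_organ not in raw:
                raise PhantomError(
                    f"organ {organ.name!r}: unknown host {organ.host_organ!r}"
                )
            host = masks[organ.host_organ]
            if np.any(raw[organ.name] & ~raw[organ.host_organ]):
                raise PhantomError(
                    f"organ {organ.name!r} is not contained in host "
                    f"{organ.host_organ!r}"
                )
            host &= ~raw[organ.name]

    claim = np.zeros(spec.grid_shape, dtype=np.int16)
    for m in masks.values():
        claim += m
    if np.any(claim > 1):
        offenders = [
            o.name for o in spec.organs if np.any(masks[o.name] & (claim > 1))
        ]
        raise PhantomError(
            "organs overlap in 3D (only 2D projection overlap is allowed): "
            + ", ".join(offenders)
        )

    body = spec.body.contains(x, y, z)
    background = body.copy()
    for m in masks.values():
        background &= ~m

    density = np.zeros(spec.grid_shape, dtype=float)
    density[body] = spec.body_density_g_ml
    mu = np.zeros(spec.grid_shape, dtype=float)
    mu[body] = spec.mu_body_cm1
    for organ in spec.organs:
        m = masks[organ.name]
        density[m] = organ.density_g_ml
        if organ.attenuation_cm1 is not None:
            mu[m] = organ.attenuation_cm1
        else:
            mu[m] = spec.mu_body_cm1

    return Phantom(
        spec=spec,
        masks=masks,
        body_mask=body,
        background_mask=background,
        density_g_ml=density,
        mu_cm1=mu,
    )


def render_activity_volume(
    phantom: Phantom,
    activities_mbq: Mapping[str, float],
    psf_fwhm_mm: float = 0.0,
) -> np.ndarray:
    """Distribute per-organ activities uniformly over their masks.

    ``activities_mbq`` maps organ names (and optionally ``"background"``) to
    total MBq. With ``psf_fwhm_mm > 0`` the volume is convolved with an
    isotropic Gaussian; the kernel is normalised so the global sum is
    preserved (activity near the grid edge can truncate — keep sources a few
    sigma away from the boundary).
    """
    if psf_fwhm_mm < 0:
        raise PhantomError("PSF FWHM must be >= 0")
    vol = np.zeros(phantom.spec.grid_shape, dtype=float)
    for name, activity in activities_mbq.items():
        if activity < 0:
            raise PhantomError(f"negative activity for {name!r}")
        mask = (
            phantom.background_mask if name == "background" else phantom.masks[name]
        )
        n = mask.sum()
        if n == 0:
            raise PhantomError(f"empty mask for {name!r}")
        vol[mask] += activity / n
    if psf_fwhm_mm > 0:
        sigma = psf_fwhm_mm * _FWHM_TO_SIGMA / phantom.voxel_size_mm
        vol = ndimage.gaussian_filter(vol, sigma=sigma, mode="constant")
    return vol


def project_planar(
    activity_mbq: np.ndarray,
    mu_cm1: np.ndarray,
    direction: str,
    sensitivity_cps_per_mbq: float,
    duration_s: float,
    voxel_size_mm: float,
    noise: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Attenuated parallel projection of an activity volume along ``y``.

    ``counts(x, z) = duration * sensitivity * sum_y a(x,y,z) * exp(-int mu dl)``
    where the attenuation line integral runs from the voxel centre to the
    detector (half self-attenuation in the emitting voxel). The posterior view
    is mirrored in ``x`` as the camera sees it. With ``noise=True`` the image
    is Poisson-sampled (reproducible for a fixed ``rng``).
    """
    if activity_mbq.shape != mu_cm1.shape:
        raise GeometryError(
            f"activity {activity_mbq.shape} and attenuation {mu_cm1.shape} "
            "volumes do not share a grid"
        )
    if direction not in ("anterior", "posterior"):
        raise PhantomError(f"unknown projection direction {direction!r}")
    dy_cm = voxel_size_mm / 10.0
    if direction == "anterior":
        path = (np.cumsum(mu_cm1, axis=1) - 0.5 * mu_cm1) * dy_cm
    else:
        rev = mu_cm1[:, ::-1, :]
        path = ((np.cumsum(rev, axis=1) - 0.5 * rev) * dy_cm)[:, ::-1, :]
    img = duration_s * sensitivity_cps_per_mbq * np.sum(
        activity_mbq * np.exp(-path), axis=1
    )
    if direction == "posterior":
        img = img[::-1, :]  # camera mirror
    if noise:
        if rng is None:
            raise PhantomError("noise=True requires an rng")
        img = rng.poisson(img).astype(float)
    return img


# ---------------------------------------------------------------------------
# full study simulation
# ---------------------------------------------------------------------------


def _syringe_geometry(
    phantom: Phantom, calibration: CalibrationStandard
) -> tuple[Shape, np.ndarray]:
    """Place the syringe in air beyond the body along z ("below the feet")."""
    spec = phantom.spec
    dx = spec.voxel_size_mm
    r = calibration.radius_mm
    if calibration.center_mm is not None:
        center = calibration.center_mm
    else:
        z_idx = np.nonzero(phantom.body_mask.any(axis=(0, 1)))[0]
        z_body_end = (z_idx.max() + 1) * dx if z_idx.size else 0.0
        center = (
            spec.grid_shape[0] * dx / 2.0,
            spec.grid_shape[1] * dx / 2.0,
            z_body_end + 12.0 + r,
        )
    shape = Shape("sphere", center, (r, r, r))
    lo, hi = shape.bounding_box_mm()
    extent = np.asarray(spec.grid_shape, dtype=float) * dx
    if np.any(lo < 0) or np.any(hi > extent):
        raise PhantomError(
            "calibration syringe does not fit in the grid below the feet; "
            "enlarge the grid along z"
        )
    x, y, z = _grid_coords(spec)
    mask = shape.contains(x, y, z)
    if (mask.any(axis=1) & phantom.body_mask.any(axis=1)).any():
        raise PhantomError("calibration syringe overlaps the body in projection")
    return shape, mask


def simulate_study(
    phantom_spec: PhantomSpec,
    acq: AcquisitionSpec,
    admin: AdministrationRecord,
    calibration: CalibrationStandard | None = None,
) -> StudyDataset:
    """Simulate a complete imaging study with analytic ground truth.

    Produces one anterior/posterior planar pair per time point (with the
    calibration syringe rendered into the field of view), SPECT-like activity
    volumes at the configured SPECT time points, and a :class:`TruthRecord`
    with the analytic residence time ``tau = f / lambda_eff`` and the
    local-deposition dose for every organ.
    """
    from .dosimetry import self_dose  # deferred: dosimetry does not import phantom

    phantom = build_phantom(phantom_spec)
    if calibration is None:
        calibration = CalibrationStandard()
    calibration.duration_s = acq.planar_duration_s
    calibration.measurements = {}

    rng = np.random.default_rng(acq.seed)
    _, syringe_mask = _syringe_geometry(phantom, calibration)
    syr_unit = syringe_mask.astype(float) / syringe_mask.sum()

    # syringe ROI on the anterior-frame planar grid, padded for blur
    pad = 1
    if acq.planar_psf_fwhm_mm > 0:
        sigma_px = acq.planar_psf_fwhm_mm * _FWHM_TO_SIGMA / phantom.voxel_size_mm
        pad = max(1, int(math.ceil(3.0 * sigma_px)))
    syringe_roi = ndimage.binary_dilation(syringe_mask.any(axis=1), iterations=pad)

    spect_tps = acq.effective_spect_time_points_h
    planar: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    spect: dict[float, np.ndarray] = {}
    for t in acq.time_points_h:
        acts = {
            o.name: organ_activity(o, admin, t, acq.physical_half_life_h)
            for o in phantom_spec.organs
        }
        if phantom_spec.background_uptake_fraction > 0:
            acts["background"] = background_activity(
                phantom_spec, admin, t, acq.physical_half_life_h
            )
        body_vol = render_activity_volume(phantom, acts, psf_fwhm_mm=0.0)
        syr_act = calibration.activity_at(t, acq.physical_half_life_h)
        planar_vol = body_vol + syr_unit * syr_act

        pair = []
        for direction in ("anterior", "posterior"):
            img = project_planar(
                planar_vol,
                phantom.mu_cm1,
                direction,
                acq.planar_sensitivity_cps_per_mbq,
                acq.planar_duration_s,
                phantom.voxel_size_mm,
                noise=False,
            )
            if acq.planar_psf_fwhm_mm > 0:
                sigma_px = (
                    acq.planar_psf_fwhm_mm * _FWHM_TO_SIGMA / phantom.voxel_size_mm
                )
                img = ndimage.gaussian_filter(img, sigma=sigma_px, mode="constant")
            if acq.noise:
                img = rng.poisson(img).astype(float)
            pair.append(img)
        ant, post = pair
        planar[t] = (ant, post)

        gm = np.sqrt(ant * post[::-1, :])
        calibration.measurements[t] = float(gm[syringe_roi].sum())

        if t in spect_tps:
            svol = render_activity_volume(phantom, acts, acq.spect_psf_fwhm_mm)
            if acq.noise and acq.spect_noise_sd > 0:
                svol = svol * (1.0 + acq.spect_noise_sd * rng.standard_normal(svol.shape))
                np.clip(svol, 0.0, None, out=svol)
            spect[t] = svol

    truth_organs: dict[str, OrganTruth] = {}
    for o in phantom_spec.organs:
        lam = effective_lambda(acq.physical_half_life_h, o.biological_half_life_h)
        tau = o.uptake_fraction / lam
        mass = phantom.organ_mass_g(o.name)
        dose = (
            self_dose(tau, admin.activity_gbq, mass, LU177_MEAN_ELECTRON_ENERGY_MEV)
            if tau > 0
            else 0.0
        )
        truth_organs[o.name] = OrganTruth(
            uptake_fraction=o.uptake_fraction,
            lambda_eff_per_h=lam,
            tau_h=tau,
            mass_g=mass,
            dose_gy=dose,
        )
    truth = TruthRecord(
        organs=truth_organs,
        background_uptake_fraction=phantom_spec.background_uptake_fraction,
        background_lambda_eff_per_h=effective_lambda(
            acq.physical_half_life_h, phantom_spec.background_half_life_h
        ),
    )

    return StudyDataset(
        phantom=phantom,
        acq=acq,
        admin=admin,
        calibration=calibration,
        planar=planar,
        spect=spect,
        syringe_roi=syringe_roi,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# simulated observers
# ---------------------------------------------------------------------------


def perturb_roi(
    mask: np.ndarray,
    mode: str,
    magnitude: int = 1,
    seed: int | None = None,
    shift: tuple[int, ...] | None = None,
) -> np.ndarray:
    """Simulate an independent observer's ROI/VOI delineation.

    ``mode`` is ``dilate``, ``erode`` or ``shift``. For ``shift`` an explicit
    integer ``shift`` vector may be given; otherwise one is drawn uniformly in
    ``[-magnitude, magnitude]`` per axis from ``seed``. Shifting zero-fills at
    the boundary, so the voxel count is preserved whenever the mask does not
    touch the grid edge. The input mask is never modified.
    """
    if magnitude < 0:
        raise PhantomError("magnitude must be >= 0")
    if mode not in ("dilate", "erode", "shift"):
        raise PhantomError(f"unknown perturbation mode {mode!r}")
    if magnitude == 0 and shift is None:
        return mask.copy()
    if mode == "dilate":
        return ndimage.binary_dilation(mask, iterations=magnitude)
    if mode == "erode":
        out = ndimage.binary_erosion(mask, iterations=magnitude)
        if not out.any():
            raise PhantomError("erosion produced an empty mask")
        return out
    if shift is None:
        rng = np.random.default_rng(seed)
        shift = tuple(int(s) for s in rng.integers(-magnitude, magnitude + 1, mask.ndim))
    if len(shift) != mask.ndim:
        raise PhantomError("shift vector dimensionality mismatch")
    out = np.zeros_like(mask)
    src = []
    dst = []
    for s, n in zip(shift, mask.shape):
        if abs(s) >= n:
            return out
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = mask[tuple(src)]
    return out
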