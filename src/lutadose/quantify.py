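"""Image + ROI/VOI quantification: from counts to organ activities.

Implements the three quantification paths of the pipeline:

* conjugate-view (geometric-mean) planar quantification with thickness-
  weighted background subtraction and syringe-based camera calibration,
* SPECT VOI quantification with a manual calibration factor,
* the hybrid building blocks: projecting 3D VOIs onto the planar grid,
  removing pixels claimed by more than one organ and substituting the removed
  activity under a uniform-concentration assumption, and rescaling a planar
  time-activity curve by a single SPECT measurement.

Planar quantification deliberately applies *no* attenuation correction: the
resulting depth-dependent bias of the planar path relative to SPECT is the
mechanism this package exists to expose.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import integrate, ndimage

from .constants import LU177_HALF_LIFE_H
from .errors import GeometryError, QuantificationError
from .phantom import CalibrationStandard

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ROI2D:
    """A planar organ ROI with its paired background band."""

    organ: str
    mask: np.ndarray
    background_mask: np.ndarray | None = None

    def __post_init__(self):
        if not self.mask.any():
            raise QuantificationError(f"ROI for {self.organ!r} is empty")
        if self.background_mask is not None and np.any(
            self.mask & self.background_mask
        ):
            raise QuantificationError(
                f"background band overlaps the ROI for {self.organ!r}"
            )


@dataclass
class VOI3D:
    """A 3D volume of interest."""

    organ: str
    mask: np.ndarray

    def __post_init__(self):
        if not self.mask.any():
            raise QuantificationError(f"VOI for {self.organ!r} is empty")


@dataclass(frozen=True)
class BackgroundCorrectionSpec:
    """Organ/body anterior-posterior extents (cm) and the weighting factor."""

    d_organ_cm: float
    d_body_cm: float

    @property
    def wf(self) -> float:
        return background_weighting(self.d_organ_cm, self.d_body_cm)


@dataclass(frozen=True)
class RecoveryModel:
    """Sphere recovery coefficients for a Gaussian PSF of given FWHM."""

    psf_fwhm_mm: float

    def coefficient(self, volume_ml: float) -> float:
        return recovery_coefficient(self.psf_fwhm_mm, volume_ml)


# ---------------------------------------------------------------------------
# planar building blocks
# ---------------------------------------------------------------------------


def geometric_mean(
    anterior: np.ndarray, posterior: np.ndarray, mirror_posterior: bool = True
) -> np.ndarray:
    """Pixelwise conjugate-view image ``sqrt(anterior * posterior)``.

    The posterior image is mirrored left-right back into the anterior frame
    first (camera geometry); pass ``mirror_posterior=False`` for images
    already aligned.
    """
    if anterior.shape != posterior.shape:
        raise GeometryError(
            f"anterior {anterior.shape} and posterior {posterior.shape} "
            "images differ in shape"
        )
    if np.any(anterior < 0) or np.any(posterior < 0):
        raise QuantificationError("count images must be non-negative")
    if mirror_posterior:
        posterior = posterior[::-1, :]
    return np.sqrt(anterior * posterior)


def background_weighting(d_organ_cm: float, d_body_cm: float) -> float:
    """Thickness weighting factor ``wf = 1 - d_organ / d_body``.

    ``d_organ`` and ``d_body`` are the anterior-posterior extents of organ and
    body in cm; the factor rescales an adjacent full-thickness background band
    to the background share of the organ column.
    """
    if d_body_cm <= 0:
        raise QuantificationError("body extent must be positive")
    if d_organ_cm < 0 or d_organ_cm > d_body_cm:
        raise QuantificationError(
            f"organ extent {d_organ_cm} must lie in [0, body extent {d_body_cm}]"
        )
    return 1.0 - d_organ_cm / d_body_cm


def correct_background(
    organ_counts: float,
    organ_pixels: int,
    bg_counts: float,
    bg_pixels: int,
    wf: float,
) -> tuple[float, bool]:
    """Subtract the weighted per-pixel background from the organ counts.

    Returns ``(corrected_counts, floored)``; counts are floored at zero with
    the flag set rather than silently dropped.
    """
    if organ_pixels <= 0 or bg_pixels <= 0:
        raise QuantificationError("pixel counts must be positive")
    if organ_counts < 0 or bg_counts < 0:
        raise QuantificationError("counts must be non-negative")
    corrected = organ_counts - wf * (bg_counts / bg_pixels) * organ_pixels
    if corrected < 0:
        return 0.0, True
    return corrected, False


def planar_sensitivity(
    counts: float, duration_s: float, activity_mbq: float
) -> float:
    """Camera sensitivity ``(counts/duration)/activity`` in cps per MBq."""
    if counts <= 0:
        raise QuantificationError(
            "calibration standard yielded zero counts (missing from the field of view?)"
        )
    if duration_s <= 0 or activity_mbq <= 0:
        raise QuantificationError("duration and activity must be positive")
    return counts / duration_s / activity_mbq


def sensitivity_from_standard(
    standard: CalibrationStandard,
    acquisition_time_h: float,
    physical_half_life_h: float = LU177_HALF_LIFE_H,
) -> float:
    """Sensitivity from the syringe measurement at one acquisition.

    The nominal syringe activity is decay-corrected from its reference time to
    the acquisition time before dividing.
    """
    if acquisition_time_h not in standard.measurements:
        raise QuantificationError(
            f"no calibration measurement at t={acquisition_time_h} h"
        )
    if standard.duration_s is None:
        raise QuantificationError("calibration standard has no acquisition duration")
    activity = standard.activity_at(acquisition_time_h, physical_half_life_h)
    return planar_sensitivity(
        standard.measurements[acquisition_time_h], standard.duration_s, activity
    )


def auto_background_band(
    roi_mask: np.ndarray,
    exclude: np.ndarray | None = None,
    band_width: int = 2,
    gap: int = 1,
    side: str = "+x",
) -> np.ndarray:
    """Place a background band next to an organ ROI.

    The band is ``band_width`` pixels wide, offset laterally (along the image
    x axis) from the ROI bounding box, and spans the ROI's z range. It is
    shifted outward pixel by pixel until it overlaps neither the ROI nor any
    pixel of ``exclude`` (typically the union of all organ ROIs and the
    syringe ROI). Raises if no placement fits in the grid.
    """
    if side not in ("+x", "-x"):
        raise QuantificationError(f"unknown band side {side!r}")
    nx, nz = roi_mask.shape
    xs, zs = np.nonzero(roi_mask)
    if xs.size == 0:
        raise QuantificationError("cannot place a band next to an empty ROI")
    z0, z1 = zs.min(), zs.max()
    blocked = roi_mask if exclude is None else (roi_mask | exclude)

    if side == "+x":
        start = xs.max() + 1 + gap
        step = 1
    else:
        start = xs.min() - gap - band_width
        step = -1
    while 0 <= start and start + band_width <= nx:
        band = np.zeros_like(roi_mask)
        band[start : start + band_width, z0 : z1 + 1] = True
        if not np.any(band & blocked):
            return band
        start += step
    raise QuantificationError(
        "no background band placement available next to the ROI"
    )


def planar_organ_activity(
    gm_image: np.ndarray,
    roi: ROI2D,
    wf: float,
    sensitivity_cps_per_mbq: float,
    duration_s: float,
) -> tuple[float, bool]:
    """Background-corrected, calibrated organ activity from a GM image (MBq).

    No attenuation correction is applied; the returned ``floored`` flag marks
    corrections that hit the zero floor.
    """
    if gm_image.shape != roi.mask.shape:
        raise GeometryError("image and ROI shapes differ")
    if sensitivity_cps_per_mbq <= 0 or duration_s <= 0:
        raise QuantificationError("sensitivity and duration must be positive")
    organ_counts = float(gm_image[roi.mask].sum())
    if roi.background_mask is not None and roi.background_mask.any():
        bg_counts = float(gm_image[roi.background_mask].sum())
        corrected, floored = correct_background(
            organ_counts,
            int(roi.mask.sum()),
            bg_counts,
            int(roi.background_mask.sum()),
            wf,
        )
    else:
        corrected, floored = organ_counts, False
    return corrected / duration_s / sensitivity_cps_per_mbq, floored


# ---------------------------------------------------------------------------
# SPECT / hybrid building blocks
# ---------------------------------------------------------------------------


def voi_activity(
    spect_volume: np.ndarray, voi: VOI3D, spect_calibration_factor: float = 1.0
) -> float:
    """Total activity (MBq) inside a VOI of a quantitative SPECT volume."""
    if spect_volume.shape != voi.mask.shape:
        raise GeometryError("volume and VOI shapes differ")
    if spect_calibration_factor <= 0:
        raise QuantificationError("SPECT calibration factor must be positive")
    return float(spect_volume[voi.mask].sum()) * spect_calibration_factor


def project_voi(voi: VOI3D, axis: int = 1) -> ROI2D:
    """Project a 3D VOI onto the planar grid (union along the given axis)."""
    return ROI2D(organ=voi.organ, mask=voi.mask.any(axis=axis))


@dataclass
class OverlapCorrection:
    """Residual 2D mask and substitution factor for one organ."""

    organ: str
    residual_mask: np.ndarray
    substitution_factor: float
    removed_voxel_fraction: float


def remove_overlap_and_substitute(
    vois: Sequence[VOI3D],
    axis: int = 1,
    host_pairs: frozenset[tuple[str, str]] | set[tuple[str, str]] = frozenset(),
) -> dict[str, OverlapCorrection]:
    """Drop projection pixels claimed by more than one organ and compensate.

    For each organ, pixels where two or more projected VOIs coincide are
    removed from its 2D mask. A measurement taken on the residual region is
    scaled by ``V_total / V_residual`` (3D voxel counts, where a voxel is
    *residual* if its projected pixel survives) — exact under uniform
    concentration, biased when the removed part is hotter or colder than the
    rest. Raises naming the organ if an organ is fully occluded.

    A lesion enclosed by its host organ would always be fully occluded, so
    ``host_pairs`` may list ``(lesion, host)`` pairs: the lesion then keeps
    the pixels it shares with its host (the host still loses them), which is
    how a tumour-in-liver ROI stays measurable.
    """
    if not vois:
        raise QuantificationError("at least one VOI is required")
    projections = {v.organ: v.mask.any(axis=axis) for v in vois}

    out: dict[str, OverlapCorrection] = {}
    for v in vois:
        blocked = np.zeros_like(projections[v.organ])
        for other, proj in projections.items():
            if other == v.organ or (v.organ, other) in host_pairs:
                continue
            blocked |= proj
        residual2d = projections[v.organ] & ~blocked
        if not residual2d.any():
            raise QuantificationError(
                f"organ {v.organ!r} is fully occluded in projection"
            )
        keep = np.expand_dims(residual2d, axis=axis)
        v_total = int(v.mask.sum())
        v_res = int((v.mask & keep).sum())
        if v_res == 0:
            raise QuantificationError(
                f"organ {v.organ!r} has no voxels over its residual region"
            )
        out[v.organ] = OverlapCorrection(
            organ=v.organ,
            residual_mask=residual2d,
            substitution_factor=v_total / v_res,
            removed_voxel_fraction=1.0 - v_res / v_total,
        )
    return out


def hybrid_rescale(
    times_h: np.ndarray,
    activities_mbq: np.ndarray,
    spect_activity_mbq: float,
    t_ref_h: float,
) -> np.ndarray:
    """Scale a planar TAC so it matches a SPECT measurement at ``t_ref``.

    Every value is multiplied by ``A_SPECT(t_ref) / A_planar(t_ref)``; the
    curve shape (and hence the fitted effective half-life) is preserved.
    """
    times_h = np.asarray(times_h, dtype=float)
    activities_mbq = np.asarray(activities_mbq, dtype=float)
    idx = np.nonzero(np.isclose(times_h, t_ref_h))[0]
    if idx.size == 0:
        raise QuantificationError(
            f"t_ref={t_ref_h} h is not one of the TAC time points {list(times_h)}"
        )
    ref = activities_mbq[idx[0]]
    if ref <= 0:
        raise QuantificationError(
            f"planar activity at t_ref={t_ref_h} h is not positive ({ref:.4g} MBq)"
        )
    return activities_mbq * (spect_activity_mbq / ref)


# ---------------------------------------------------------------------------
# partial-volume correction
# ---------------------------------------------------------------------------


def _blurred_sphere_profile(r: np.ndarray, radius: float, sigma: float) -> np.ndarray:
    """Radial profile of a unit sphere convolved with an isotropic Gaussian."""
    from scipy.special import erf

    s2 = sigma * math.sqrt(2.0)
    r = np.asarray(r, dtype=float)
    safe_r = np.where(r < 1e-9, 1e-9, r)
    term1 = 0.5 * (erf((safe_r + radius) / s2) - erf((safe_r - radius) / s2))
    term2 = (
        sigma
        / (safe_r * math.sqrt(2.0 * math.pi))
        * (
            np.exp(-((safe_r - radius) ** 2) / (2.0 * sigma**2))
            - np.exp(-((safe_r + radius) ** 2) / (2.0 * sigma**2))
        )
    )
    return term1 - term2


def recovery_coefficient(psf_fwhm_mm: float, volume_ml: float) -> float:
    """Recovery coefficient of a uniform sphere under a Gaussian PSF.

    ``RC`` is the fraction of a sphere's activity recovered by integrating the
    blurred sphere over its own (true) boundary; measured activity is divided
    by ``RC`` to correct the partial-volume loss. ``RC = 1`` for a zero-width
    PSF and tends monotonically to 1 as the volume grows.
    """
    if volume_ml <= 0:
        raise QuantificationError("volume must be positive")
    if psf_fwhm_mm < 0:
        raise QuantificationError("PSF FWHM must be >= 0")
    if psf_fwhm_mm == 0:
        return 1.0
    radius_mm = (3.0 * volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    sigma = psf_fwhm_mm * _FWHM_TO_SIGMA

    def integrand(r):
        return _blurred_sphere_profile(r, radius_mm, sigma) * r**2

    val, _ = integrate.quad(integrand, 0.0, radius_mm, limit=200)
    return float(3.0 * val / radius_mm**3)
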