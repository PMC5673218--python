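"""The three end-to-end dosimetry workflows and their statistical comparison.

``run_multi_spect``, ``run_planar`` and ``run_hybrid`` each take a
:class:`~lutadose.phantom.StudyDataset` through quantification, mono-
exponential fitting, residence times and absorbed doses. ``compare_scenarios``
reproduces the cohort-level analysis: per-organ Friedman test across the
three scenarios, pairwise Wilcoxon signed-rank tests against the
multi-SPECT/CT reference, and the median dose-per-activity ratio table.
``kendalls_w`` and ``simulate_observer_study`` cover inter-observer agreement
on simulated ROI delineations.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import LU177_MEAN_ELECTRON_ENERGY_MEV
from .errors import ScenarioError
from .kinetics import (
    FitResult,
    ResidenceTime,
    TimeActivityCurve,
    fit_monoexp,
    residence_time,
)
from .dosimetry import DoseReport, dose_per_activity, organ_mass, self_dose, sphere_dose
from .phantom import StudyDataset
from .quantify import (
    ROI2D,
    VOI3D,
    auto_background_band,
    geometric_mean,
    hybrid_rescale,
    planar_organ_activity,
    project_voi,
    recovery_coefficient,
    remove_overlap_and_substitute,
    sensitivity_from_standard,
    voi_activity,
)

SCENARIOS = ("multi_spect", "planar", "hybrid")

#: Tolerance (hours) when matching the nominal hybrid SPECT time point to the
#: study's actual frames.
T_REF_TOLERANCE_H = 2.0


@dataclass
class ScenarioResult:
    """Everything one workflow produced for one study."""

    scenario: str
    tacs: dict[str, TimeActivityCurve]
    fits: dict[str, FitResult]
    residence_times: dict[str, ResidenceTime]
    doses: dict[str, DoseReport]
    details: dict = field(default_factory=dict)

    def dose_frame(self) -> pd.DataFrame:
        rows = [
            {
                "organ": d.organ,
                "scenario": d.scenario,
                "tau_h": d.tau_h,
                "mass_g": d.mass_g,
                "dose_gy": d.dose_gy,
                "dpa_gy_per_gbq": d.dpa_gy_per_gbq,
            }
            for d in self.doses.values()
        ]
        return pd.DataFrame(rows).sort_values("organ").reset_index(drop=True)


# ---------------------------------------------------------------------------
# shared pieces
# ---------------------------------------------------------------------------


def _projected_masks(study: StudyDataset) -> dict[str, np.ndarray]:
    return {name: study.phantom.masks[name].any(axis=1) for name in study.organ_names}


def _band_exclusion(study: StudyDataset) -> np.ndarray:
    excl = study.syringe_roi.copy()
    for m in _projected_masks(study).values():
        excl |= m
    return excl


def _background_band(
    roi_mask: np.ndarray, exclusion: np.ndarray, band_width: int = 2
) -> np.ndarray:
    try:
        return auto_background_band(roi_mask, exclude=exclusion, band_width=band_width)
    except Exception:
        return auto_background_band(
            roi_mask, exclude=exclusion, band_width=band_width, side="-x"
        )


def organ_thickness_spec(study: StudyDataset, organ: str) -> tuple[float, float]:
    """Anterior-posterior extents (cm) of organ and body for the Eq.-style wf.

    Both are bounding extents along the projection axis, the body one
    restricted to the columns of the organ's footprint — a single factor per
    organ, as in a planar workflow where extents come from a CT scout.
    """
    dy_cm = study.phantom.voxel_size_mm / 10.0
    mask = study.phantom.masks[organ]
    ys = np.nonzero(mask.any(axis=(0, 2)))[0]
    d_organ = (ys.max() - ys.min() + 1) * dy_cm

    footprint = mask.any(axis=1)
    body_cols = study.phantom.body_mask & footprint[:, None, :]
    ys_b = np.nonzero(body_cols.any(axis=(0, 2)))[0]
    if ys_b.size == 0:  # organ outside the body: treat its own extent as body
        return d_organ, d_organ
    d_body = (ys_b.max() - ys_b.min() + 1) * dy_cm
    return d_organ, max(d_body, d_organ)


def _gm_images(study: StudyDataset) -> dict[float, np.ndarray]:
    return {
        t: geometric_mean(ant, post) for t, (ant, post) in sorted(study.planar.items())
    }


def _sensitivities(study: StudyDataset) -> dict[float, float]:
    return {
        t: sensitivity_from_standard(
            study.calibration, t, study.acq.physical_half_life_h
        )
        for t in study.time_points_h
    }


def _organ_doses(
    study: StudyDataset,
    taus: Mapping[str, ResidenceTime],
    scenario: str,
    tumour_psf_fwhm_mm: float,
    delta_e_mev: float = LU177_MEAN_ELECTRON_ENERGY_MEV,
) -> dict[str, DoseReport]:
    """Self-dose for organs, partial-volume-corrected sphere dose for tumours."""
    phantom = study.phantom
    a_gbq = study.admin.activity_gbq
    doses: dict[str, DoseReport] = {}
    for spec in phantom.spec.organs:
        name = spec.name
        mass = organ_mass(
            phantom.masks[name], phantom.voxel_volume_ml, spec.density_g_ml, name
        )
        tau = taus[name].tau_h
        if spec.is_tumour:
            rc = (
                recovery_coefficient(
                    tumour_psf_fwhm_mm, phantom.organ_volume_ml(name)
                )
                if tumour_psf_fwhm_mm > 0
                else 1.0
            )
            dose = sphere_dose(tau, a_gbq, mass.mass_g, delta_e_mev, rc)
        else:
            rc = 1.0
            dose = self_dose(tau, a_gbq, mass.mass_g, delta_e_mev)
        doses[name] = DoseReport(
            organ=name,
            scenario=scenario,
            tau_h=tau,
            mass_g=mass.mass_g,
            dose_gy=dose,
            dpa_gy_per_gbq=dose_per_activity(dose, a_gbq),
            recovery_coefficient=rc,
            is_tumour=spec.is_tumour,
        )
    return doses


def _finish(
    study: StudyDataset,
    scenario: str,
    tacs: dict[str, TimeActivityCurve],
    tumour_psf_fwhm_mm: float,
    details: dict,
) -> ScenarioResult:
    fits = {name: fit_monoexp(tac) for name, tac in tacs.items()}
    taus = {name: residence_time(f, study.admin) for name, f in fits.items()}
    doses = _organ_doses(study, taus, scenario, tumour_psf_fwhm_mm)
    return ScenarioResult(
        scenario=scenario,
        tacs=tacs,
        fits=fits,
        residence_times=taus,
        doses=doses,
        details=details,
    )


# ---------------------------------------------------------------------------
# the three workflows
# ---------------------------------------------------------------------------


def run_multi_spect(study: StudyDataset) -> ScenarioResult:
    """SPECT/CT-only workflow: 3D VOI activities at every time point."""
    missing = sorted(set(study.time_points_h) - set(study.spect_time_points_h))
    if missing:
        raise ScenarioError(
            f"multi-SPECT workflow needs a SPECT volume at every time point; "
            f"missing at t={missing} h — use the hybrid workflow instead"
        )
    times = np.asarray(study.time_points_h)
    tacs = {}
    for name in study.organ_names:
        voi = VOI3D(name, study.phantom.masks[name])
        acts = np.array(
            [
                voi_activity(study.spect[t], voi, study.spect_calibration_factor)
                for t in times
            ]
        )
        tacs[name] = TimeActivityCurve(name, times, acts, method="spect")
    return _finish(
        study, "multi_spect", tacs, study.acq.spect_psf_fwhm_mm, details={}
    )


def run_planar(study: StudyDataset) -> ScenarioResult:
    """Planar-only workflow: geometric-mean images, projected (possibly
    overlapping) ROIs, thickness-weighted background subtraction, syringe
    calibration — and no attenuation correction."""
    if set(study.planar.keys()) != set(study.time_points_h):
        missing = sorted(set(study.time_points_h) - set(study.planar.keys()))
        raise ScenarioError(f"missing planar pair at t={missing} h")
    gms = _gm_images(study)
    sens = _sensitivities(study)
    projections = _projected_masks(study)
    exclusion = _band_exclusion(study)
    duration = study.acq.planar_duration_s

    wfs: dict[str, float] = {}
    rois: dict[str, ROI2D] = {}
    for name, proj in projections.items():
        d_organ, d_body = organ_thickness_spec(study, name)
        wfs[name] = 1.0 - d_organ / d_body
        rois[name] = ROI2D(
            organ=name,
            mask=proj,
            background_mask=_background_band(proj, exclusion),
        )

    times = np.asarray(study.time_points_h)
    floored: dict[str, list[float]] = {}
    tacs = {}
    for name in study.organ_names:
        acts = []
        for t in times:
            a, flo = planar_organ_activity(
                gms[t], rois[name], wfs[name], sens[t], duration
            )
            if flo:
                floored.setdefault(name, []).append(float(t))
            acts.append(a)
        tacs[name] = TimeActivityCurve(name, times, np.array(acts), method="planar")
    return _finish(
        study,
        "planar",
        tacs,
        study.acq.planar_psf_fwhm_mm,
        details={"wf": wfs, "floored": floored, "sensitivity_cps_per_mbq": sens},
    )


def run_hybrid(study: StudyDataset, t_ref_h: float = 24.0) -> ScenarioResult:
    """Hybrid workflow: planar curve shapes anchored by one SPECT measurement.

    3D VOIs (from the SPECT/CT nominally at ``t_ref``) are projected onto the
    geometric-mean images; projection pixels claimed by several organs are
    removed and the lost activity substituted assuming uniform concentration;
    the resulting planar TAC is rescaled so its value at ``t_ref`` equals the
    SPECT VOI activity.
    """
    spect_times = np.asarray(study.spect_time_points_h)
    if spect_times.size == 0:
        raise ScenarioError("hybrid workflow needs at least one SPECT volume")
    i = int(np.argmin(np.abs(spect_times - t_ref_h)))
    t_spect = float(spect_times[i])
    if abs(t_spect - t_ref_h) > T_REF_TOLERANCE_H:
        raise ScenarioError(
            f"no SPECT within {T_REF_TOLERANCE_H} h of t_ref={t_ref_h} h; "
            f"available SPECT times: {list(spect_times)}"
        )
    planar_times = np.asarray(study.time_points_h)
    j = int(np.argmin(np.abs(planar_times - t_spect)))
    t_planar = float(planar_times[j])
    if abs(t_planar - t_spect) > T_REF_TOLERANCE_H:
        raise ScenarioError(
            f"no planar acquisition within {T_REF_TOLERANCE_H} h of the "
            f"SPECT frame at {t_spect} h"
        )

    gms = _gm_images(study)
    sens = _sensitivities(study)
    exclusion = _band_exclusion(study)
    duration = study.acq.planar_duration_s

    vois = [VOI3D(name, study.phantom.masks[name]) for name in study.organ_names]
    host_pairs = frozenset(
        (o.name, o.host_organ)
        for o in study.phantom.spec.organs
        if o.host_organ is not None
    )
    corrections = remove_overlap_and_substitute(vois, host_pairs=host_pairs)

    wfs: dict[str, float] = {}
    rois: dict[str, ROI2D] = {}
    for name in study.organ_names:
        d_organ, d_body = organ_thickness_spec(study, name)
        wfs[name] = 1.0 - d_organ / d_body
        rois[name] = ROI2D(
            organ=name,
            mask=corrections[name].residual_mask,
            background_mask=_background_band(
                corrections[name].residual_mask, exclusion
            ),
        )

    tacs = {}
    scale_factors: dict[str, float] = {}
    for name in study.organ_names:
        factor = corrections[name].substitution_factor
        acts = []
        for t in planar_times:
            a, _ = planar_organ_activity(
                gms[t], rois[name], wfs[name], sens[t], duration
            )
            acts.append(a * factor)
        acts = np.asarray(acts)
        spect_act = voi_activity(
            study.spect[t_spect],
            VOI3D(name, study.phantom.masks[name]),
            study.spect_calibration_factor,
        )
        rescaled = hybrid_rescale(planar_times, acts, spect_act, t_planar)
        scale_factors[name] = float(spect_act / acts[j]) if acts[j] > 0 else math.nan
        tacs[name] = TimeActivityCurve(name, planar_times, rescaled, method="hybrid")
    return _finish(
        study,
        "hybrid",
        tacs,
        study.acq.spect_psf_fwhm_mm,
        details={
            "t_ref_h": t_spect,
            "substitution_factors": {
                k: c.substitution_factor for k, c in corrections.items()
            },
            "rescale_factors": scale_factors,
            "wf": wfs,
        },
    )


def run_all(study: StudyDataset, t_ref_h: float = 24.0) -> dict[str, ScenarioResult]:
    return {
        "multi_spect": run_multi_spect(study),
        "planar": run_planar(study),
        "hybrid": run_hybrid(study, t_ref_h=t_ref_h),
    }


# ---------------------------------------------------------------------------
# cohort comparison
# ---------------------------------------------------------------------------


@dataclass
class OrganComparison:
    organ: str
    medians: dict[str, float]
    friedman_chi2: float
    friedman_p: float
    wilcoxon: dict[str, tuple[float, float]]  # scenario -> (statistic, p)
    ratio_hybrid_over_multi: float
    ratio_planar_over_multi: float

    @property
    def ratio_hybrid_over_multi_rounded(self) -> float:
        return round(self.ratio_hybrid_over_multi, 1)

    @property
    def ratio_planar_over_multi_rounded(self) -> float:
        return round(self.ratio_planar_over_multi, 1)


@dataclass
class ScenarioComparison:
    """Per-organ paired comparison of the three workflows over a cohort."""

    table: pd.DataFrame  # columns: study, organ, scenario, dpa_gy_per_gbq
    organs: dict[str, OrganComparison]

    def to_dict(self) -> dict:
        return {
            organ: {
                "medians_gy_per_gbq": oc.medians,
                "friedman_chi2": oc.friedman_chi2,
                "friedman_p": oc.friedman_p,
                "wilcoxon_vs_multi_spect": {
                    k: {"statistic": v[0], "p": v[1]} for k, v in oc.wilcoxon.items()
                },
                "ratio_hybrid_over_multi": oc.ratio_hybrid_over_multi,
                "ratio_planar_over_multi": oc.ratio_planar_over_multi,
                "ratio_hybrid_over_multi_rounded": oc.ratio_hybrid_over_multi_rounded,
                "ratio_planar_over_multi_rounded": oc.ratio_planar_over_multi_rounded,
            }
            for organ, oc in self.organs.items()
        }


def median_ratios(
    medians: Mapping[str, Mapping[str, float]], reference: str = "multi_spect"
) -> pd.DataFrame:
    """Median-DpA ratio table against the multi-SPECT reference.

    ``medians[organ][scenario]`` holds the per-scenario median dose per
    injected activity. Ratios are reported at full precision and rounded to
    one decimal for report parity.
    """
    rows = []
    for organ, per_scenario in medians.items():
        ref = per_scenario[reference]
        if ref <= 0:
            raise ScenarioError(f"non-positive reference median for {organ!r}")
        row = {"organ": organ}
        for scenario, med in per_scenario.items():
            if scenario == reference:
                continue
            ratio = med / ref
            row[f"ratio_{scenario}_over_{reference}"] = ratio
            row[f"ratio_{scenario}_over_{reference}_rounded"] = round(ratio, 1)
        rows.append(row)
    return pd.DataFrame(rows).set_index("organ")


def _friedman(columns: list[np.ndarray]) -> tuple[float, float]:
    arr = np.column_stack(columns)
    if np.allclose(arr, arr[:, [0]]):
        return 0.0, 1.0
    stat, p = stats.friedmanchisquare(*columns)
    return float(stat), float(p)


def _wilcoxon(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    d = np.asarray(x) - np.asarray(y)
    if np.allclose(d, 0.0):
        return 0.0, 1.0
    # exact null distribution for small samples, normal approximation with
    # continuity correction otherwise; always two-sided
    method = "exact" if (len(d) <= 25 and not np.any(d == 0)) else "approx"
    res = stats.wilcoxon(x, y, alternative="two-sided", method=method, correction=True)
    return float(res.statistic), float(res.pvalue)


def compare_scenarios(
    cohort: Sequence[Mapping[str, ScenarioResult]] | pd.DataFrame,
) -> ScenarioComparison:
    """Paired per-organ comparison of the scenarios across a cohort.

    ``cohort`` is either a list of ``{scenario: ScenarioResult}`` mappings
    (one per study) or an already-assembled long-format DataFrame with columns
    ``study, organ, scenario, dpa_gy_per_gbq``. At least three studies are
    required for the Friedman test; all studies must share the same organ set.
    """
    if isinstance(cohort, pd.DataFrame):
        table = cohort.copy()
    else:
        rows = []
        for i, per_scenario in enumerate(cohort):
            for scenario, result in per_scenario.items():
                for d in result.doses.values():
                    rows.append(
                        {
                            "study": i,
                            "organ": d.organ,
                            "scenario": scenario,
                            "dpa_gy_per_gbq": d.dpa_gy_per_gbq,
                        }
                    )
        table = pd.DataFrame(rows)

    studies = sorted(table["study"].unique())
    if len(studies) < 3:
        raise ScenarioError("at least 3 studies are required for the Friedman test")
    organ_sets = table.groupby("study")["organ"].agg(lambda s: frozenset(s))
    if organ_sets.nunique() != 1:
        raise ScenarioError("studies have unequal organ sets")

    scenarios = [s for s in SCENARIOS if s in set(table["scenario"])]
    if "multi_spect" not in scenarios:
        raise ScenarioError("the multi_spect reference scenario is missing")

    organs: dict[str, OrganComparison] = {}
    for organ, sub in table.groupby("organ"):
        wide = sub.pivot(index="study", columns="scenario", values="dpa_gy_per_gbq")
        wide = wide.loc[studies, scenarios]
        if wide.isna().any().any():
            raise ScenarioError(f"missing scenario values for organ {organ!r}")
        cols = [wide[s].to_numpy() for s in scenarios]
        chi2, p = _friedman(cols) if len(scenarios) == 3 else (math.nan, math.nan)
        wilcoxon = {
            s: _wilcoxon(wide[s].to_numpy(), wide["multi_spect"].to_numpy())
            for s in scenarios
            if s != "multi_spect"
        }
        medians = {s: float(wide[s].median()) for s in scenarios}
        ref = medians["multi_spect"]
        organs[organ] = OrganComparison(
            organ=organ,
            medians=medians,
            friedman_chi2=chi2,
            friedman_p=p,
            wilcoxon=wilcoxon,
            ratio_hybrid_over_multi=(
                medians.get("hybrid", math.nan) / ref if ref > 0 else math.nan
            ),
            ratio_planar_over_multi=(
                medians.get("planar", math.nan) / ref if ref > 0 else math.nan
            ),
        )
    return ScenarioComparison(table=table, organs=organs)


# ---------------------------------------------------------------------------
# inter-observer agreement
# ---------------------------------------------------------------------------


@dataclass
class ObserverAgreementResult:
    """Kendall's coefficient of concordance with both p-value routes."""

    w: float
    p_chi2: float
    p_permutation: float | None
    n_observers: int
    n_items: int
    counts: np.ndarray | None = None


def _w_statistic(ranks: np.ndarray) -> float:
    m, n = ranks.shape
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * ties
    if denom <= 0:
        return 1.0  # every observer ties every item: perfect (degenerate) accord
    return 12.0 * s / denom


def kendalls_w(
    data: np.ndarray,
    n_permutations: int = 1000,
    seed: int | None = 0,
) -> ObserverAgreementResult:
    """Kendall's W over an observers x items matrix of extracted counts.

    Ranks are assigned within each observer with average ties; the statistic
    uses the tie-corrected denominator. Both the chi-square approximation
    (``chi2 = m (n-1) W`` on ``n-1`` df) and a seeded permutation p-value
    (independent within-observer permutations) are reported; pass
    ``n_permutations=0`` to skip the latter.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ScenarioError("data must be a 2-D observers x items matrix")
    m, n = data.shape
    if m < 2 or n < 2:
        raise ScenarioError("need at least 2 observers and 2 items")
    ranks = stats.rankdata(data, axis=1)
    w = _w_statistic(ranks)
    chi2 = m * (n - 1) * w
    p_chi2 = float(stats.chi2.sf(chi2, n - 1))

    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = np.stack([rng.permutation(row) for row in ranks])
            if _w_statistic(perm) >= w - 1e-12:
                hits += 1
        p_perm = (hits + 1) / (n_permutations + 1)
    return ObserverAgreementResult(
        w=w, p_chi2=p_chi2, p_permutation=p_perm, n_observers=m, n_items=n
    )


@dataclass
class ObserverStudyResult:
    """Agreement of simulated observers for 3D VOI vs 2D ROI definitions."""

    voi_3d: ObserverAgreementResult
    roi_2d: ObserverAgreementResult


def simulate_observer_study(
    studies: Sequence[StudyDataset],
    n_observers: int = 3,
    magnitude: int = 2,
    seed: int = 0,
    organ: str = "kidney_right",
    t_ref_h: float = 24.0,
) -> ObserverStudyResult:
    """Simulate independent observers re-delineating an organ over a cohort.

    Each observer/item draw shifts the reference mask by up to ``magnitude``
    voxels per axis and randomly dilates or erodes by one step; counts are
    extracted from the SPECT volume (3D VOI) and from the geometric-mean
    planar image through the projected, independently perturbed 2D ROI.
    Kendall's W is computed separately for both definition routes.
    """
    from .phantom import perturb_roi

    if n_observers < 2:
        raise ScenarioError("need at least 2 observers")
    if len(studies) < 2:
        raise ScenarioError("need at least 2 studies (items) for concordance")
    rng = np.random.default_rng(seed)

    counts3 = np.zeros((n_observers, len(studies)))
    counts2 = np.zeros((n_observers, len(studies)))
    for o in range(n_observers):
        for i, study in enumerate(studies):
            spect_times = np.asarray(study.spect_time_points_h)
            t_s = float(spect_times[np.argmin(np.abs(spect_times - t_ref_h))])
            planar_times = np.asarray(study.time_points_h)
            t_p = float(planar_times[np.argmin(np.abs(planar_times - t_ref_h))])
            base3 = study.phantom.masks[organ]
            gm = geometric_mean(*study.planar[t_p])

            shift3 = tuple(int(s) for s in rng.integers(-magnitude, magnitude + 1, 3))
            morph3 = int(rng.integers(-1, 2)) if magnitude > 0 else 0
            m3 = perturb_roi(base3, "shift", magnitude, shift=shift3)
            if morph3 == 1:
                m3 = perturb_roi(m3, "dilate", 1)
            elif morph3 == -1:
                try:
                    m3 = perturb_roi(m3, "erode", 1)
                except Exception:
                    pass
            counts3[o, i] = study.spect[t_s][m3].sum()

            base2 = base3.any(axis=1)
            shift2 = tuple(int(s) for s in rng.integers(-magnitude, magnitude + 1, 2))
            morph2 = int(rng.integers(-1, 2)) if magnitude > 0 else 0
            m2 = perturb_roi(base2, "shift", magnitude, shift=shift2)
            if morph2 == 1:
                m2 = perturb_roi(m2, "dilate", 1)
            elif morph2 == -1:
                try:
                    m2 = perturb_roi(m2, "erode", 1)
                except Exception:
                    pass
            counts2[o, i] = gm[m2].sum()

    res3 = kendalls_w(counts3, seed=seed)
    res2 = kendalls_w(counts2, seed=seed)
    res3.counts = counts3
    res2.counts = counts2
    return ObserverStudyResult(voi_3d=res3, roi_2d=res2)
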