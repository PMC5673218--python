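"""Absorbed dose from residence times (MIRD-style, self-dose default).

The default dose model is local electron deposition: every electron emitted
inside an organ deposits its energy in that organ, so the self S-value at a
reference mass ``m`` is

    S = 3.6e12 decays/(GBq h) * Delta_e [MeV] * 1.602e-13 J/MeV / (m [kg])

and the self-dose term is rescaled by ``m_ref / m`` for the individual organ
mass (the non-penetrating component of the MIRD mass adjustment). 177Lu
electrons have sub-millimetre range so the absorbed fraction is taken as 1
for the >= 3 g objects this pipeline handles; photon cross-dose is omitted by
default but a full S-value table can be supplied as CSV to upgrade fidelity.

Absorbed doses are in Gy and numerically equal to Sv (radiation weighting
factor 1 for electrons); dose per injected activity (DpA) is Gy/GBq.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import (
    DECAYS_PER_GBQ_H,
    J_PER_MEV,
    LU177_MEAN_ELECTRON_ENERGY_MEV,
)
from .errors import DosimetryError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrganMass:
    """Individual organ mass from CT-style volumetry and a standard density."""

    organ: str
    volume_ml: float
    density_g_ml: float

    @property
    def mass_g(self) -> float:
        return self.volume_ml * self.density_g_ml


@dataclass
class DoseReport:
    """Absorbed dose for one organ/tumour under one imaging scenario."""

    organ: str
    scenario: str
    tau_h: float
    mass_g: float
    dose_gy: float
    dpa_gy_per_gbq: float
    recovery_coefficient: float = 1.0
    is_tumour: bool = False

    @property
    def dose_sv(self) -> float:
        # w_R = 1 for electrons: Gy and Sv coincide numerically
        return self.dose_gy

    @property
    def dpa_sv_per_gbq(self) -> float:
        return self.dpa_gy_per_gbq


def organ_mass(
    mask: np.ndarray, voxel_volume_ml: float, density_g_ml: float, organ: str = ""
) -> OrganMass:
    """Organ mass = voxel count x voxel volume x standardized density."""
    n = int(np.asarray(mask).sum())
    if n == 0:
        raise DosimetryError(f"empty mask for organ {organ!r}")
    if voxel_volume_ml <= 0 or density_g_ml <= 0:
        raise DosimetryError("voxel volume and density must be positive")
    return OrganMass(organ=organ, volume_ml=n * voxel_volume_ml, density_g_ml=density_g_ml)


def self_dose(
    tau_h: float,
    a_admin_gbq: float,
    mass_g: float,
    delta_e_mev: float = LU177_MEAN_ELECTRON_ENERGY_MEV,
) -> float:
    """Local-deposition self-dose in Gy.

    ``D = tau * A_admin * 3.6e12 * Delta_e * 1.602e-13 / (m/1000)`` — the
    cumulated activity ``tau * A_admin`` (GBq h) converted to decays, times
    the electron energy per decay, divided by the organ mass in kg.
    """
    if mass_g <= 0:
        raise DosimetryError("mass must be positive")
    if a_admin_gbq <= 0:
        raise DosimetryError("administered activity must be positive")
    if tau_h < 0:
        raise DosimetryError("residence time must be >= 0")
    if delta_e_mev <= 0:
        raise DosimetryError("energy per decay must be positive")
    energy_j = tau_h * a_admin_gbq * DECAYS_PER_GBQ_H * delta_e_mev * J_PER_MEV
    return energy_j / (mass_g / 1000.0)


@dataclass
class DoseFactorTable:
    """S-values in Gy per (GBq h) at reference masses, per (target, source).

    The default table built by :meth:`local_deposition` is diagonal (self-dose
    only); OLINDA-style phantom tables can be loaded from CSV with columns
    ``target, source, s_gy_per_gbq_h, ref_mass_g``. A missing cross term is
    treated as zero with a logged warning; a missing diagonal is an error.
    """

    entries: dict[tuple[str, str], tuple[float, float]]

    def __post_init__(self):
        for (t, s), (sv, m) in self.entries.items():
            if sv < 0:
                raise DosimetryError(f"S-value for {t}<-{s} must be >= 0")
            if t == s and sv <= 0:
                raise DosimetryError(f"diagonal S-value for {t!r} must be > 0")
            if m <= 0:
                raise DosimetryError(f"reference mass for {t}<-{s} must be > 0")

    @classmethod
    def local_deposition(
        cls,
        ref_masses_g: Mapping[str, float],
        delta_e_mev: float = LU177_MEAN_ELECTRON_ENERGY_MEV,
    ) -> "DoseFactorTable":
        entries = {}
        for organ, mass in ref_masses_g.items():
            if mass <= 0:
                raise DosimetryError(f"reference mass for {organ!r} must be positive")
            s = DECAYS_PER_GBQ_H * delta_e_mev * J_PER_MEV / (mass / 1000.0)
            entries[(organ, organ)] = (s, mass)
        return cls(entries=entries)

    @classmethod
    def from_csv(cls, path) -> "DoseFactorTable":
        df = pd.read_csv(path)
        required = {"target", "source", "s_gy_per_gbq_h", "ref_mass_g"}
        if not required <= set(df.columns):
            raise DosimetryError(f"S-value CSV needs columns {sorted(required)}")
        entries = {
            (r.target, r.source): (float(r.s_gy_per_gbq_h), float(r.ref_mass_g))
            for r in df.itertuples()
        }
        return cls(entries=entries)

    def to_csv(self, path) -> None:
        rows = [
            {"target": t, "source": s, "s_gy_per_gbq_h": sv, "ref_mass_g": m}
            for (t, s), (sv, m) in sorted(self.entries.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    def s_value(self, target: str, source: str) -> tuple[float, float] | None:
        return self.entries.get((target, source))


def organ_dose(
    taus_h: Mapping[str, float],
    a_admin_gbq: float,
    masses_g: Mapping[str, float],
    table: DoseFactorTable,
    target: str,
) -> float:
    """MIRD target dose ``D_T = A_admin * sum_S tau_S * S(T<-S)`` in Gy.

    The self-dose (diagonal) term is rescaled by ``m_ref / m`` for the
    individual target mass; cross terms are used as tabulated.
    """
    if table.s_value(target, target) is None:
        raise DosimetryError(f"missing diagonal S-value for target {target!r}")
    dose = 0.0
    for source, tau in taus_h.items():
        entry = table.s_value(target, source)
        if entry is None:
            logger.warning(
                "no S-value for %s <- %s; cross-dose contribution treated as 0",
                target,
                source,
            )
            continue
        s, ref_mass = entry
        if source == target:
            m = masses_g.get(target)
            if m is None or m <= 0:
                raise DosimetryError(f"missing mass for target {target!r}")
            s = s * (ref_mass / m)
        dose += tau * s
    return a_admin_gbq * dose


def sphere_dose(
    tau_h: float,
    a_admin_gbq: float,
    mass_g: float,
    delta_e_mev: float = LU177_MEAN_ELECTRON_ENERGY_MEV,
    rc: float = 1.0,
) -> float:
    """Tumour dose under the unit-density-like sphere model, in Gy.

    The residence time is divided by the recovery coefficient ``rc`` before
    dosing (partial-volume corrected activity); the absorbed fraction is
    taken as 1 for the sphere masses handled here.
    """
    if rc <= 0 or rc > 1:
        raise DosimetryError("recovery coefficient must lie in (0, 1]")
    return self_dose(tau_h / rc, a_admin_gbq, mass_g, delta_e_mev)


def dose_per_activity(dose_gy: float, a_admin_gbq: float) -> float:
    """Dose per injected activity, Gy/GBq (== Sv/GBq for electrons)."""
    if a_admin_gbq <= 0:
        raise DosimetryError("administered activity must be positive")
    return dose_gy / a_admin_gbq
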