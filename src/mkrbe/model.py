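"""Modified microdosimetric kinetic (mMK) survival model for interrupted
multi-field photon irradiation.

The mMK model extends linear-quadratic (LQ) cell survival with pairwise
dose-interaction terms between fields.  Sublethal lesions produced by one
field can still combine with lesions from a later field, but the pool of
sublethal damage decays exponentially (first-order sublethal damage repair,
rate constant ``a + c`` in h^-1) during the interruption between fields.
For a schedule of N instantaneous fields with doses D_1..D_N and elapsed
time dt(n, m) between fields n and m::

    -ln S = sum_n [(alpha0 + gamma * beta0) D_n + beta0 D_n^2]
            + 2 sum_{n<m} beta0 exp(-(a+c) dt(n, m)) D_n D_m

gamma is the dose-mean specific energy of a single energy-deposition event
in a micron-scale domain, gamma = y_D / (rho * pi * r_d^2), converting the
radiation quality (dose-mean lineal energy y_D) into an additive
contribution to the effective linear coefficient alpha = alpha0 + gamma*beta0.

RBE here compares the interrupted schedule against the same total dose
delivered instantaneously with no interruption: the iso-survival reference
dose (positive root of the LQ inversion) divided by the physical dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "KEV_PER_UM_TO_GY",
    "DomainGeometry",
    "CellLineParams",
    "DeliverySchedule",
    "RbeResult",
    "gamma",
    "repair_rate_from_halftime",
    "neg_log_sf",
    "delivery_time",
    "lq_invert",
    "rbe",
]

# 1 keV/um deposited in 1 um^3 of unit-density matter, expressed in Gy:
# 1.602176634e-16 J/keV / (1e3 kg/m^3 * 1e-18 m^3) * (um/m factors folded in)
# => gamma[Gy] = 0.1602176634 * y_D[keV/um] / (rho[g/cm^3] * pi * r_d[um]^2)
KEV_PER_UM_TO_GY = 0.1602176634


@dataclass(frozen=True)
class DomainGeometry:
    """Microdosimetric domain: a sphere of radius ``r_d_um`` (um) and
    density ``rho_g_cm3`` (g/cm^3) over which single-event energy
    deposition is tallied."""

    r_d_um: float = 0.5
    rho_g_cm3: float = 1.0

    def __post_init__(self) -> None:
        if self.r_d_um <= 0:
            raise ValueError(f"domain radius must be positive, got {self.r_d_um}")
        if self.rho_g_cm3 <= 0:
            raise ValueError(f"domain density must be positive, got {self.rho_g_cm3}")


@dataclass(frozen=True)
class CellLineParams:
    """Radiobiological constants of one cell line.

    alpha0 : Gy^-1
        Linear lethal-lesion coefficient before the track-quality term.
    beta0 : Gy^-2
        Quadratic coefficient (coefficient of D^2 in -ln S).
    repair_rate : h^-1
        First-order sublethal-damage repair rate constant (a + c).
    """

    alpha0: float
    beta0: float
    repair_rate: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.alpha0 < 0:
            raise ValueError(f"alpha0 must be >= 0, got {self.alpha0}")
        if self.beta0 <= 0:
            raise ValueError(f"beta0 must be > 0, got {self.beta0}")
        if self.repair_rate < 0:
            raise ValueError(f"repair_rate must be >= 0, got {self.repair_rate}")

    @classmethod
    def from_half_time(
        cls, alpha0: float, beta0: float, half_time_h: float, label: str = ""
    ) -> "CellLineParams":
        """Build from a sublethal-damage repair half-time (h) instead of a rate."""
        return cls(alpha0, beta0, repair_rate_from_halftime(half_time_h), label)


@dataclass(frozen=True)
class DeliverySchedule:
    """Ordered irradiation fields with interruptions between them.

    field_doses : Gy, one entry per field, delivered in order.
    interruptions_min : min, gap tau_k between field k and field k+1
        (length is one less than the number of fields).
    dose_rate_gy_min : Gy/min, common to all fields.  Fields are modelled
        as instantaneous pulses, so the dose rate only enters the reported
        elapsed delivery time, never the survival calculation.
    """

    field_doses: tuple[float, ...]
    interruptions_min: tuple[float, ...] = ()
    dose_rate_gy_min: float = 3.0

    def __init__(
        self,
        field_doses: Sequence[float],
        interruptions_min: Sequence[float] = (),
        dose_rate_gy_min: float = 3.0,
    ) -> None:
        doses = tuple(float(d) for d in field_doses)
        gaps = tuple(float(t) for t in interruptions_min)
        if len(doses) < 1:
            raise ValueError("schedule needs at least one field")
        if any(d < 0 for d in doses):
            raise ValueError(f"field doses must be >= 0, got {doses}")
        if any(t < 0 for t in gaps):
            raise ValueError(f"interruption times must be >= 0, got {gaps}")
        if len(gaps) != len(doses) - 1:
            raise ValueError(
                f"{len(doses)} fields need {len(doses) - 1} interruptions, "
                f"got {len(gaps)}"
            )
        object.__setattr__(self, "field_doses", doses)
        object.__setattr__(self, "interruptions_min", gaps)
        object.__setattr__(self, "dose_rate_gy_min", float(dose_rate_gy_min))

    @classmethod
    def equal_split(
        cls,
        total_dose_gy: float,
        n_fields: int,
        gap_min: float,
        dose_rate_gy_min: float = 3.0,
    ) -> "DeliverySchedule":
        """Total dose divided equally over ``n_fields``, every gap equal."""
        if n_fields < 1:
            raise ValueError("n_fields must be >= 1")
        return cls(
            [total_dose_gy / n_fields] * n_fields,
            [gap_min] * (n_fields - 1),
            dose_rate_gy_min,
        )

    @property
    def total_dose(self) -> float:
        return sum(self.field_doses)

    @property
    def n_fields(self) -> int:
        return len(self.field_doses)

    def field_start_times_min(self) -> np.ndarray:
        """Start time of each (instantaneous) field, minutes from the first."""
        return np.concatenate([[0.0], np.cumsum(self.interruptions_min)])


@dataclass(frozen=True)
class RbeResult:
    """Survival and RBE of one delivery scenario.

    reference_dose_gy is the instantaneous (no-interruption) dose producing
    the same surviving fraction; rbe = reference_dose / physical total dose.
    """

    neg_log_sf: float
    surviving_fraction: float
    reference_dose_gy: float
    rbe: float


def gamma(y_d_kev_um: float, geom: DomainGeometry = DomainGeometry()) -> float:
    """Single-event dose-mean specific energy gamma (Gy).

    gamma = y_D / (rho * pi * r_d^2) with the keV/um -> Gy unit conversion
    written out explicitly:
    gamma[Gy] = 0.1602176634 * y_D[keV/um] / (rho[g/cm^3] * pi * r_d[um]^2).
    """
    if y_d_kev_um < 0:
        raise ValueError(f"y_D must be >= 0, got {y_d_kev_um}")
    return KEV_PER_UM_TO_GY * y_d_kev_um / (geom.rho_g_cm3 * math.pi * geom.r_d_um**2)


def repair_rate_from_halftime(half_time_h: float) -> float:
    """Sublethal-damage repair rate (a + c) = ln 2 / T_1/2, in h^-1."""
    if half_time_h <= 0:
        raise ValueError(f"repair half-time must be positive, got {half_time_h}")
    return math.log(2.0) / half_time_h


def neg_log_sf(
    sched: DeliverySchedule, cell: CellLineParams, gamma_gy: float
) -> float:
    """-ln(surviving fraction) of an interrupted schedule under the mMK model.

    Fields are instantaneous pulses.  The cross term between fields n and m
    decays with the total elapsed time between them, i.e. the sum of the
    intervening gaps; for equal gaps tau this is the familiar
    (m - n) * tau exponent.  Gaps are stored in minutes, the repair rate in
    h^-1; the min -> h conversion happens exactly once, here.
    """
    d = np.asarray(sched.field_doses, dtype=float)
    alpha = cell.alpha0 + gamma_gy * cell.beta0
    total = float(np.sum(alpha * d + cell.beta0 * d**2))
    if sched.n_fields > 1:
        t_h = sched.field_start_times_min() / 60.0
        n_idx, m_idx = np.triu_indices(sched.n_fields, k=1)
        dt = t_h[m_idx] - t_h[n_idx]  # elapsed time from field n to field m
        cross = float(np.sum(np.exp(-cell.repair_rate * dt) * d[n_idx] * d[m_idx]))
        total += 2.0 * cell.beta0 * cross
    return total


def delivery_time(sched: DeliverySchedule) -> float:
    """Total elapsed treatment time in minutes: beam-on time at the common
    dose rate (D = dose_rate * T) plus all interruptions.  Reported for
    logging and plots only; survival treats fields as instantaneous."""
    if sched.dose_rate_gy_min <= 0:
        raise ValueError(f"dose rate must be positive, got {sched.dose_rate_gy_min}")
    return sched.total_dose / sched.dose_rate_gy_min + sum(sched.interruptions_min)


def lq_invert(neg_log_s: float, alpha: float, beta: float) -> float:
    """Dose (Gy) at which the LQ curve alpha*D + beta*D^2 reaches the given
    -ln S: the positive quadratic root (-alpha + sqrt(alpha^2 + 4*beta*x)) / (2*beta)."""
    if neg_log_s < 0:
        raise ValueError(f"-lnS must be >= 0, got {neg_log_s}")
    if beta <= 0:
        raise ValueError(f"beta must be > 0 for quadratic inversion, got {beta}")
    return (-alpha + math.sqrt(alpha * alpha + 4.0 * beta * neg_log_s)) / (2.0 * beta)


def rbe(
    sched: DeliverySchedule, cell: CellLineParams, gamma_gy: float
) -> RbeResult:
    """RBE of an interrupted schedule against instantaneous delivery.

    The reference is the same cell irradiated instantaneously (all gaps
    zero), so its survival is plain LQ with alpha = alpha0 + gamma*beta0 and
    beta = beta0.  The iso-survival reference dose is found by LQ inversion
    and divided by the schedule's physical total dose.  A schedule with all
    gaps zero therefore has RBE exactly 1.
    """
    if sched.total_dose <= 0:
        raise ValueError("RBE undefined for zero total dose")
    nls = neg_log_sf(sched, cell, gamma_gy)
    alpha = cell.alpha0 + gamma_gy * cell.beta0
    d_ref = lq_invert(nls, alpha, cell.beta0)
    return RbeResult(
        neg_log_sf=nls,
        surviving_fraction=math.exp(-nls),
        reference_dose_gy=d_ref,
        rbe=d_ref / sched.total_dose,
    )
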