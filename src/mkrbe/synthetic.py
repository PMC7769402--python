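"""Synthetic inputs for end-to-end testing: lineal-energy spectra with a
prescribed dose-mean, delivery schedules, and noisy survival observations.

No public survival dataset accompanies the model, so recovery of the
radiobiological parameters is exercised on data drawn from the model
itself: observed surviving fractions are the model SF times multiplicative
lognormal noise (equivalently, additive Gaussian noise on -lnS — the
standard error structure of clonogenic assays, and it keeps observations
positive).  The fit is least squares on -lnS over (alpha, beta0, a + c)
with positivity bounds.  alpha0 and gamma*beta0 enter survival only through
their sum alpha = alpha0 + gamma*beta0, so only the combined alpha is
identifiable from survival data and only it is reported.

All randomness flows through one explicit integer seed; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .microdosimetry import LinealEnergySpectrum
from .model import CellLineParams, DeliverySchedule, neg_log_sf

__all__ = [
    "SyntheticSurvivalSet",
    "FitResult",
    "make_spectrum",
    "simulate_survival",
    "fit_parameters",
    "recovery_design",
    "write_survival_set",
    "read_survival_set",
]


@dataclass(frozen=True)
class SyntheticSurvivalSet:
    """Simulated clonogenic observations: one SF per delivery scenario."""

    scenarios: tuple[DeliverySchedule, ...]
    observed_sf: np.ndarray
    true_params: CellLineParams
    gamma_gy: float
    noise_sd: float
    seed: int


@dataclass(frozen=True)
class FitResult:
    """Estimates recovered from survival data.

    alpha is the combined linear coefficient alpha0 + gamma*beta0 (its two
    components cannot be separated from survival alone).
    """

    alpha: float
    beta0: float
    repair_rate: float
    residual_norm: float


def make_spectrum(
    target_y_d: float,
    shape: float = 0.6,
    n_bins: int = 200,
    seed: int = 0,
) -> LinealEnergySpectrum:
    """Lognormal-shaped lineal-energy spectrum with the requested dose-mean.

    A lognormal density with dispersion ``shape`` is tabulated on a
    geometric grid (with seed-dependent jitter so distinct seeds give
    distinct but reproducible spectra), then the whole y-axis is stretched
    so the trapezoid-rule dose-mean equals ``target_y_d`` — the stretch
    covariance y -> c*y makes this rescaling exact.  ``n_bins == 1`` gives
    a point mass at the target.
    """
    if target_y_d <= 0:
        raise ValueError(f"target y_D must be positive, got {target_y_d}")
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    if shape <= 0:
        raise ValueError(f"shape must be positive, got {shape}")
    if n_bins == 1:
        return LinealEnergySpectrum([target_y_d], [1.0])
    rng = np.random.default_rng(seed)
    lo, hi = np.exp(-4.0 * shape), np.exp(4.0 * shape)
    y = np.geomspace(lo, hi, n_bins)
    # jitter interior nodes without breaking monotonicity
    step = np.diff(np.log(y)).min()
    y[1:-1] *= np.exp(rng.uniform(-0.3, 0.3, n_bins - 2) * step)
    f = np.exp(-0.5 * (np.log(y) / shape) ** 2) / y
    spec = LinealEnergySpectrum(y, f)
    scale = target_y_d / spec.moments().y_d
    return LinealEnergySpectrum(spec.y_grid * scale, spec.density / scale)


def simulate_survival(
    schedules: Sequence[DeliverySchedule],
    params: CellLineParams,
    gamma_gy: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticSurvivalSet:
    """Draw observed SFs: model SF times exp(eps), eps ~ N(0, noise_sd^2),
    independent across scenarios and reproducible per seed."""
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    nls = np.array([neg_log_sf(s, params, gamma_gy) for s in schedules])
    eps = rng.normal(0.0, noise_sd, size=len(nls)) if noise_sd > 0 else 0.0
    return SyntheticSurvivalSet(
        scenarios=tuple(schedules),
        observed_sf=np.exp(-nls + eps),
        true_params=params,
        gamma_gy=gamma_gy,
        noise_sd=noise_sd,
        seed=seed,
    )


def _design_summaries(schedules: Sequence[DeliverySchedule]):
    """Per-schedule sufficient statistics for the -lnS model:
    total dose, sum of squared field doses, and the pairwise
    (elapsed hours, D_n*D_m) arrays feeding the cross term."""
    out = []
    for s in schedules:
        d = np.asarray(s.field_doses)
        t_h = s.field_start_times_min() / 60.0
        n = len(d)
        iu, ju = np.triu_indices(n, k=1)
        out.append((d.sum(), (d**2).sum(), t_h[ju] - t_h[iu], d[iu] * d[ju]))
    return out


def _model_neg_log_sf(theta: np.ndarray, summaries) -> np.ndarray:
    alpha, beta0, rate = theta
    vals = np.empty(len(summaries))
    for i, (dsum, d2sum, dt, dprod) in enumerate(summaries):
        cross = 2.0 * np.sum(np.exp(-rate * dt) * dprod) if len(dt) else 0.0
        vals[i] = alpha * dsum + beta0 * (d2sum + cross)
    return vals


def fit_parameters(data: SyntheticSurvivalSet) -> FitResult:
    """Recover (alpha, beta0, a + c) by bounded least squares on -lnS.

    Requires an identifiable design: at least two distinct total doses
    (to separate alpha from beta0) and at least two distinct positive
    inter-field gap patterns (to pin the repair rate).
    """
    totals = {round(s.total_dose, 9) for s in data.scenarios}
    gap_patterns = {
        s.interruptions_min for s in data.scenarios if any(s.interruptions_min)
    }
    problems = []
    if len(totals) < 2:
        problems.append("need >= 2 distinct total dose levels")
    if len(gap_patterns) < 2:
        problems.append("need >= 2 distinct positive interruption patterns")
    if problems:
        raise ValueError("design not identifiable: " + "; ".join(problems))

    summaries = _design_summaries(data.scenarios)
    y = -np.log(np.asarray(data.observed_sf))

    def resid(theta):
        return _model_neg_log_sf(theta, summaries) - y

    sol = least_squares(
        resid,
        x0=np.array([0.1, 0.05, 1.0]),
        bounds=(np.array([0.0, 1e-12, 0.0]), np.array([np.inf] * 3)),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    alpha, beta0, rate = sol.x
    return FitResult(
        alpha=float(alpha),
        beta0=float(beta0),
        repair_rate=float(rate),
        residual_norm=float(np.linalg.norm(sol.fun)),
    )


def recovery_design(
    doses_gy: Sequence[float] = (1.0, 2.0, 4.0, 8.0),
    field_counts: Sequence[int] = (2, 4),
    taus_min: Sequence[float] = (1.0, 3.0, 5.0, 10.0, 30.0, 60.0),
    dose_rate_gy_min: float = 3.0,
) -> list[DeliverySchedule]:
    """Equal-split schedule grid for parameter-recovery studies
    (defaults give 4 x 2 x 6 = 48 scenarios)."""
    return [
        DeliverySchedule.equal_split(d, n, tau, dose_rate_gy_min)
        for d in doses_gy
        for n in field_counts
        for tau in taus_min
    ]


_SEP = ";"


def write_survival_set(data: SyntheticSurvivalSet, path: str | Path) -> None:
    """Serialize a survival set to CSV: field doses and gaps as
    semicolon-joined columns plus the observed SF."""
    rows = [
        {
            "field_doses_gy": _SEP.join(repr(d) for d in s.field_doses),
            "interruptions_min": _SEP.join(repr(t) for t in s.interruptions_min),
            "dose_rate_gy_min": s.dose_rate_gy_min,
            "observed_sf": repr(float(sf)),
        }
        for s, sf in zip(data.scenarios, data.observed_sf)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_survival_set(
    path: str | Path,
    true_params: CellLineParams,
    gamma_gy: float,
    noise_sd: float = float("nan"),
    seed: int = -1,
) -> SyntheticSurvivalSet:
    """Inverse of :func:`write_survival_set`.  Provenance fields
    (true_params, noise_sd, seed) are supplied by the caller because CSV
    carries only the observations."""
    df = pd.read_csv(
        path,
        dtype={"field_doses_gy": str, "interruptions_min": str},
        float_precision="round_trip",
    )
    scenarios = []
    for _, row in df.iterrows():
        doses = [float(x) for x in row["field_doses_gy"].split(_SEP)]
        gaps_str = row["interruptions_min"]
        gaps = (
            [float(x) for x in gaps_str.split(_SEP)]
            if isinstance(gaps_str, str) and gaps_str
            else []
        )
        scenarios.append(
            DeliverySchedule(doses, gaps, float(row["dose_rate_gy_min"]))
        )
    return SyntheticSurvivalSet(
        scenarios=tuple(scenarios),
        observed_sf=df["observed_sf"].to_numpy(dtype=float),
        true_params=true_params,
        gamma_gy=gamma_gy,
        noise_sd=noise_sd,
        seed=seed,
    )
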