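"""Sampler uptake calibration and time-weighted-average (TWA) water concentrations.

Integrative passive sampling in the linear-uptake phase follows first-order
kinetics: the mass accumulated on a sorbent disk after ``t`` days in water
of concentration ``C`` is ``m = Rs * C * t``, where ``Rs`` (L/day) is the
sampling rate — the equivalent volume of water cleared of analyte per day.
``Rs`` is obtained in the laboratory by exposing disks to a constant known
concentration and regressing mass on time; in the field the relation is
inverted to give the TWA concentration ``C_TWA = m / (Rs * t)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RsEstimate",
    "TwaResult",
    "AgreementSummary",
    "calibrate_rs",
    "twa_concentration",
    "theoretical_disk_mass",
    "twa_agreement",
]


@dataclass(frozen=True)
class RsEstimate:
    """A calibrated sampling rate with its fit diagnostics.

    ``valid`` is False when the calibration slope was non-positive; such
    estimates must not be used downstream (``rs`` is NaN then).
    ``linear_window`` is the time span actually used after the
    linear-window truncation rule.
    """

    compound_id: str
    sorbent: str
    rs: float  # L/day
    fit_r2: float
    n_points: int
    linear_window: tuple[float, float]
    intercept: float = 0.0
    valid: bool = True


@dataclass(frozen=True)
class TwaResult:
    compound_id: str
    sorbent: str
    c_twa: float  # ng/L
    mass_ng: float
    duration_days: float


@dataclass(frozen=True)
class AgreementSummary:
    """Paired TWA-vs-grab comparison: mean and sd of (twa - grab)."""

    mean_error: float
    sd: float
    n: int
    differences: tuple[float, ...]


def _ols(times: np.ndarray, masses: np.ndarray):
    res = stats.linregress(times, masses)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue) ** 2
    return res.slope, res.intercept, r2


def calibrate_rs(
    times,
    masses,
    c_lab: float,
    compound_id: str = "",
    sorbent: str = "",
) -> RsEstimate:
    """Calibrate the sampling rate from a lab uptake time series.

    Ordinary least squares of disk mass (ng) on time (days), with a free
    intercept (a small lag phase must not bias the slope); the sampling
    rate is ``slope / c_lab``.  Linear-window rule (single pass): the line
    is also fit to the first n-1 points; if the last timepoint's deviation
    from that line exceeds 3x its residual standard deviation (onset of
    curvature towards equilibrium), the last point is dropped and the
    n-1-point fit kept.  The leave-last-out form is used because a full
    fit absorbs a curving endpoint into its own residual scale and the
    rule would never fire.

    Parameters
    ----------
    times : array-like, days
    masses : array-like, ng/disk, same length as ``times``
    c_lab : float
        Constant exposure concentration during calibration, ng/L (> 0).
    """
    times = np.asarray(times, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if times.shape != masses.shape or times.ndim != 1:
        raise ValueError("times and masses must be 1-d arrays of equal length")
    if times.size < 3:
        raise ValueError("calibration requires at least 3 timepoints")
    if c_lab <= 0:
        raise ValueError("c_lab must be > 0")

    order = np.argsort(times)
    times, masses = times[order], masses[order]

    slope, intercept, r2 = _ols(times, masses)
    n = times.size
    if n > 3:
        s_h, i_h, r2_h = _ols(times[:-1], masses[:-1])
        resid_head = masses[:-1] - (s_h * times[:-1] + i_h)
        head_sd = float(np.sqrt(np.sum(resid_head**2) / (n - 3)))
        last_dev = abs(masses[-1] - (s_h * times[-1] + i_h))
        floor = 1e-9 * max(1.0, float(np.max(np.abs(masses))))
        if last_dev > max(3 * head_sd, floor):
            times, masses = times[:-1], masses[:-1]
            slope, intercept, r2 = s_h, i_h, r2_h

    valid = slope > 0
    return RsEstimate(
        compound_id=compound_id,
        sorbent=sorbent,
        rs=slope / c_lab if valid else float("nan"),
        fit_r2=r2,
        n_points=int(times.size),
        linear_window=(float(times[0]), float(times[-1])),
        intercept=float(intercept),
        valid=bool(valid),
    )


def twa_concentration(mass_ng: float, rs: float, duration_days: float) -> float:
    """TWA water concentration (ng/L) from accumulated disk mass.

    ``C_TWA = m / (Rs * t)`` — linear in mass, exact inverse of
    :func:`theoretical_disk_mass`.
    """
    if rs <= 0:
        raise ValueError(f"rs must be > 0 (got {rs})")
    if duration_days <= 0:
        raise ValueError(f"duration_days must be > 0 (got {duration_days})")
    if mass_ng < 0:
        raise ValueError(f"mass_ng must be >= 0 (got {mass_ng})")
    return mass_ng / (rs * duration_days)


def theoretical_disk_mass(c_water: float, rs: float, duration_days: float) -> float:
    """Disk mass (ng) a sampler would accumulate at a given water concentration.

    ``m = C * Rs * t``; used to place literature water data on the sampler
    mass scale when no physical deployment exists.
    """
    if c_water < 0 or rs < 0 or duration_days < 0:
        raise ValueError("all inputs must be >= 0")
    return c_water * rs * duration_days


def twa_agreement(twa, grab) -> AgreementSummary:
    """Mean error between paired TWA and grab-sample concentrations.

    Pairs must be aligned by compound.  The error sign is (twa - grab);
    the sd uses the n-1 denominator and is 0 by convention for a single
    pair.
    """
    twa = np.asarray(twa, dtype=float)
    grab = np.asarray(grab, dtype=float)
    if twa.shape != grab.shape or twa.ndim != 1:
        raise ValueError("twa and grab must be 1-d arrays of equal length")
    if twa.size == 0:
        raise ValueError("no overlapping compounds to compare")
    diffs = twa - grab
    sd = float(np.std(diffs, ddof=1)) if diffs.size > 1 else 0.0
    return AgreementSummary(
        mean_error=float(np.mean(diffs)),
        sd=sd,
        n=int(diffs.size),
        differences=tuple(float(d) for d in diffs),
    )
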