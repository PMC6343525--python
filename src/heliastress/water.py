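"""Pot water-status math for robot-managed dry-down experiments.

The platform weighs each pot before and after irrigation.  A pot is
calibrated by its weight at full soil water capacity (``w_max``) and its
total transpirable soil water (``ttsw``); the fraction of transpirable
soil water is FTSW = (weight - w_min) / ttsw, clamped to [0, 1].  The
controller converts a target FTSW to a target weight and tops the pot up
to it at each visit (water is only ever added, never removed).  SFTSW,
the cumulative water-deficit indicator, is the time integral of
(1 - FTSW) over a window, in unitless * days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PotCalibration",
    "PotSeries",
    "WaterStatusSeries",
    "compute_ftsw",
    "target_weight",
    "irrigation_dose",
    "transpiration_between_weighings",
    "integrate_sftsw",
    "run_scenario",
]


@dataclass(frozen=True)
class PotCalibration:
    """Per-pot weight calibration: full-capacity weight and TTSW (same mass units)."""

    w_max: float
    ttsw: float

    def __post_init__(self):
        if not (np.isfinite(self.w_max) and np.isfinite(self.ttsw)):
            raise ValueError("calibration weights must be finite")
        if self.ttsw <= 0:
            raise ValueError(f"ttsw must be > 0, got {self.ttsw}")

    @property
    def w_min(self) -> float:
        return self.w_max - self.ttsw


@dataclass
class PotSeries:
    """Weighing/irrigation record of one plant: timestamps in day fractions."""

    plant_id: str
    timestamps: np.ndarray
    weight_pre: np.ndarray
    weight_post: np.ndarray
    dose: np.ndarray
    calibration: PotCalibration

    def __post_init__(self):
        t = np.asarray(self.timestamps, dtype=float)
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        self.timestamps = t
        self.weight_pre = np.asarray(self.weight_pre, dtype=float)
        self.weight_post = np.asarray(self.weight_post, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plant_id": self.plant_id,
                "timestamp": self.timestamps,
                "weight_pre": self.weight_pre,
                "weight_post": self.weight_post,
                "dose": self.dose,
            }
        )


@dataclass
class WaterStatusSeries:
    """Derived water status of one plant: clamped FTSW, raw FTSW, transpiration."""

    plant_id: str
    timestamps: np.ndarray
    ftsw: np.ndarray
    ftsw_raw: np.ndarray
    transpiration: np.ndarray
    n_floored: int = 0
    true_ftsw: np.ndarray | None = None  # noise-free trace when known (simulation)


def compute_ftsw(weight, cal: PotCalibration):
    """FTSW = (weight - w_min) / ttsw, clamped to [0, 1]."""
    weight = np.asarray(weight, dtype=float)
    if not np.all(np.isfinite(weight)):
        raise ValueError("pot weight must be finite")
    raw = (weight - cal.w_min) / cal.ttsw
    out = np.clip(raw, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def target_weight(f_target: float, cal: PotCalibration) -> float:
    """Target pot weight realizing FTSW = f_target: w_min + f_target * ttsw."""
    f_target = float(f_target)
    if not (0.0 <= f_target <= 1.0):
        raise ValueError(f"target FTSW must be in [0, 1], got {f_target}")
    return cal.w_min + f_target * cal.ttsw


def irrigation_dose(current_weight: float, f_target: float, cal: PotCalibration) -> float:
    """Water to add to reach the target weight; never negative, never past w_max."""
    current_weight = float(current_weight)
    if not np.isfinite(current_weight):
        raise ValueError("current weight must be finite")
    dose = max(0.0, target_weight(f_target, cal) - current_weight)
    return min(dose, max(0.0, cal.w_max - current_weight))


def transpiration_between_weighings(series: PotSeries) -> tuple[np.ndarray, int]:
    """Per-interval transpiration rate (mass/day) from successive weighings.

    Rate over interval k is (post-irrigation weight at visit k-1 minus
    pre-irrigation weight at visit k) / elapsed days.  Negative raw rates
    (measurement noise) are floored at 0; the number floored is returned.
    """
    if series.timestamps.size < 2:
        raise ValueError("need at least two weighings")
    dt = np.diff(series.timestamps)
    raw = (series.weight_post[:-1] - series.weight_pre[1:]) / dt
    n_floored = int(np.sum(raw < 0))
    return np.maximum(raw, 0.0), n_floored


def integrate_sftsw(timestamps, ftsw, window=None) -> float:
    """Trapezoidal integral of (1 - FTSW) over [t0, t1], in unitless * days.

    The window defaults to the full series span; its endpoints are
    interpolated so SFTSW is exactly additive over adjacent windows.
    """
    t = np.asarray(timestamps, dtype=float)
    f = np.asarray(ftsw, dtype=float)
    if t.size == 0:
        raise ValueError("empty series")
    if window is None:
        t0, t1 = t[0], t[-1]
    else:
        t0, t1 = float(window[0]), float(window[1])
    if not (t[0] <= t0 < t1 <= t[-1]):
        raise ValueError(f"window [{t0}, {t1}] empty or outside series span")
    grid = np.unique(np.concatenate([[t0, t1], t[(t > t0) & (t < t1)]]))
    vals = np.interp(grid, t, f)
    return float(np.trapezoid(1.0 - vals, grid))


def run_scenario(
    plant_model,
    f_target,
    cal: PotCalibration,
    days: int,
    visits_per_day: int = 1,
    start_ftsw: float = 1.0,
    plant_id: str = "plant",
) -> tuple[PotSeries, WaterStatusSeries]:
    """Couple the irrigation controller with a plant forward model.

    ``f_target`` is a constant in [0, 1] or a day-indexed schedule
    (sequence of length >= days).  At each visit the pot transpires for
    the elapsed interval, is weighed (with the model's measurement
    noise), then topped up to the target weight of the day.

    Aborts with a diagnostic if the observed weight falls below
    w_min - 3 * noise_sd (plant model divergence).
    """
    if not (1 <= int(visits_per_day) <= 4):
        raise ValueError("visits_per_day must be in 1..4")
    if np.isscalar(f_target):
        schedule = np.full(days, float(f_target))
    else:
        schedule = np.asarray(f_target, dtype=float)
        if schedule.size < days:
            raise ValueError("target schedule shorter than the scenario")
    if np.any((schedule < 0) | (schedule > 1)):
        raise ValueError("target FTSW values must lie in [0, 1]")

    atsw = float(np.clip(start_ftsw, 0, 1)) * cal.ttsw
    dt = 1.0 / visits_per_day
    noise = getattr(plant_model.truth, "noise_sd_weight", 0.0)

    ts, w_pre, w_post, doses, true_f = [], [], [], [], []
    for day in range(days):
        for v in range(visits_per_day):
            atsw, _ = plant_model.step(atsw, cal.ttsw, dt=dt)
            w_true = cal.w_min + atsw
            obs_pre = plant_model.observe(w_true)
            if obs_pre < cal.w_min - 3.0 * noise - 1e-12:
                raise RuntimeError(
                    f"plant model divergence for {plant_id!r} at day {day}: "
                    f"observed weight {obs_pre:.3f} < w_min - 3*noise"
                )
            dose = irrigation_dose(obs_pre, schedule[day], cal)
            atsw = min(atsw + dose, cal.ttsw)
            ts.append(day + (v + 1) * dt)
            w_pre.append(obs_pre)
            w_post.append(obs_pre + dose)
            doses.append(dose)
            true_f.append(atsw / cal.ttsw)

    pots = PotSeries(
        plant_id=plant_id,
        timestamps=np.array(ts),
        weight_pre=np.array(w_pre),
        weight_post=np.array(w_post),
        dose=np.array(doses),
        calibration=cal,
    )
    raw = (pots.weight_post - cal.w_min) / cal.ttsw
    transp, n_floored = transpiration_between_weighings(pots)
    status = WaterStatusSeries(
        plant_id=plant_id,
        timestamps=pots.timestamps,
        ftsw=np.clip(raw, 0.0, 1.0),
        ftsw_raw=raw,
        transpiration=np.concatenate([[np.nan], transp]),
        n_floored=n_floored,
        true_ftsw=np.array(true_f),
    )
    return pots, status
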