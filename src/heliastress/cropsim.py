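"""Simplified daily crop simulator for genotype x environment studies.

The model keeps the structure of a process-based oilseed crop model —
thermal-time phenology, a single soil water bucket, light interception
with radiation-use efficiency, a nitrogen dilution balance, and
genotype-dependent FTSW response curves for transpiration and leaf
expansion — while staying small enough that its limits can be checked
in closed form.  Outputs per genotype x environment are grain yield, an
oil-content proxy, phenology, and four daily stress-factor series whose
deficits integrate to the abiotic-stress indicators (SFTSW, SNNI, SLT,
SHT) used for envirotyping.

Numerical conventions: all four stress factors live in [0, 1] and equal
1 in the absence of stress; in particular the water factor is the FTSW
response curve rescaled by its well-watered value so the no-stress run
reproduces the closed-form potential yield exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from heliastress.synth.climate import ClimateSeries, SoilProfile
from heliastress.traits import eval_ftsw_response

__all__ = [
    "GenotypeParameters",
    "Management",
    "SimulationOutput",
    "TABLE_GENOTYPES",
    "thermal_time",
    "temperature_factor",
    "nni",
    "simulate",
    "stress_indicators",
]

T_BASE = 4.8  # deg C, thermal-time base
CARDINALS = (4.8, 20.0, 28.0, 37.0)  # photosynthesis temperature response
DILUTION = (4.53, 0.42)  # critical N dilution curve (%N = A * biomass^-B)
BASE_OIL = 55.0  # % oil with no post-flowering water stress
OIL_PENALTY = 10.0  # % oil lost per unit mean post-flowering water deficit
SOIL_EVAP_FRAC = 0.1  # bare-soil evaporation as a fraction of PET


@dataclass(frozen=True)
class GenotypeParameters:
    """The eight genotype-dependent parameters of the simulator."""

    name: str
    a_tr: float  # transpiration response to FTSW, < 0
    a_le: float  # leaf-expansion response to FTSW, < 0
    thermal_time_to_flowering: float = 850.0  # deg C day
    thermal_time_to_maturity: float = 1600.0  # deg C day
    potential_lai: float = 3.0
    extinction_k: float = 0.9
    rue: float = 3.0  # g biomass per MJ intercepted
    harvest_index: float = 0.4
    cardinals: tuple = CARDINALS  # overridable for ideotype experiments

    def __post_init__(self):
        if self.a_tr >= 0 or self.a_le >= 0:
            raise ValueError("a_tr and a_le must be strictly negative")
        if self.thermal_time_to_maturity <= self.thermal_time_to_flowering:
            raise ValueError("maturity thermal time must exceed flowering")
        if not (0.0 < self.harvest_index < 1.0):
            raise ValueError("harvest_index must be in (0, 1)")
        for nm in ("potential_lai", "extinction_k", "rue"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be > 0")


#: the four contrasting genotypes used in the simulation experiments
#: (transpiration / leaf-expansion response parameters per platform trial)
TABLE_GENOTYPES = (
    GenotypeParameters(name="LG_5450HO", a_tr=-9.66, a_le=-4.94),
    GenotypeParameters(name="MAS_86OL", a_tr=-7.64, a_le=-2.40),
    GenotypeParameters(name="MAS_89M", a_tr=-13.98, a_le=-2.15),
    GenotypeParameters(name="SY_EXPLORER", a_tr=-13.08, a_le=-4.96),
)


@dataclass(frozen=True)
class Management:
    sowing_doy: int = 135
    irrigation: str = "none"  # "none" (rainfed) or "auto" (refill daily)
    n_fertilization: float = 0.0  # kg N / ha applied at sowing


@dataclass
class SimulationOutput:
    genotype: str
    env_id: str
    yield_g_m2: float
    oil_pct: float
    flowering_day: int
    maturity_day: int
    series: pd.DataFrame  # daily: ftsw, nni, f_water, f_nlow, f_tlow, f_thigh
    water_balance: dict = field(default_factory=dict)  # mm totals over the run


def thermal_time(tmean, t_base: float = T_BASE) -> np.ndarray:
    """Cumulative degree-days: cumsum of max(0, tmean - t_base)."""
    tmean = np.asarray(tmean, dtype=float)
    if tmean.size == 0:
        raise ValueError("empty temperature series")
    return np.cumsum(np.maximum(tmean - t_base, 0.0))


def temperature_factor(t, cardinals=CARDINALS):
    """Trapezoidal photosynthesis response to temperature, in [0, 1]."""
    t_min, t_opt1, t_opt2, t_max = cardinals
    if not (t_min < t_opt1 <= t_opt2 < t_max):
        raise ValueError(f"invalid cardinal temperatures {cardinals}")
    t = np.asarray(t, dtype=float)
    up = (t - t_min) / (t_opt1 - t_min)
    down = (t_max - t) / (t_max - t_opt2)
    out = np.clip(np.minimum(up, down), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _temperature_split(t, cardinals=CARDINALS):
    """(f_tlow, f_thigh): the rising and falling limbs of the trapezoid."""
    t_min, t_opt1, t_opt2, t_max = cardinals
    f_low = np.clip((t - t_min) / (t_opt1 - t_min), 0.0, 1.0)
    f_high = np.clip((t_max - t) / (t_max - t_opt2), 0.0, 1.0)
    return f_low, f_high


def nni(biomass_t_ha: float, n_uptake: float, dilution=DILUTION, cap: float = 2.0):
    """Nitrogen nutrition index: actual over critical N concentration.

    The critical dilution curve %N = A * biomass^-B is evaluated with a
    1 t/ha biomass floor so the index is continuous for small crops;
    the returned value is capped (default 2) for stable integration.
    """
    A, B = dilution
    if biomass_t_ha < 0:
        raise ValueError("biomass must be >= 0")
    b = max(biomass_t_ha, 1.0)
    actual_pct = n_uptake / (10.0 * b)  # kg/ha over t/ha, as percent
    critical_pct = A * b ** (-B)
    return min(actual_pct / critical_pct, cap)


def simulate(
    genotype: GenotypeParameters,
    climate: ClimateSeries,
    soil: SoilProfile,
    mgmt: Management = Management(),
) -> SimulationOutput:
    """Run the daily model from sowing to maturity for one environment.

    Daily order of computation: (1) FTSW from the bucket; (2) potential
    transpiration PET * (1 - exp(-k LAI)) scaled by the transpiration
    response curve; (3) green-LAI growth scaled by the leaf-expansion
    curve and min(1, NNI), with thermal-time senescence after flowering;
    (4) biomass gain rue * radiation * interception * temperature factor
    * water factor; (5) bucket update with precipitation, irrigation and
    soil evaporation, clamped to [0, TTSW]; (6) nitrogen uptake tracking
    the critical dilution demand, limited by soil supply.

    Raises if the weather contains NaN or maturity is not reached.
    """
    ttsw = soil.ttsw_mm
    n_days = climate.n_days
    start = mgmt.sowing_doy - 1
    if start >= n_days:
        raise ValueError("sowing date outside the climate series")
    for name in ("tmean", "radiation", "pet", "precip"):
        arr = getattr(climate, name)
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise ValueError(f"NaN in {name} at day index {bad[0]}")

    tt_flo = genotype.thermal_time_to_flowering
    tt_mat = genotype.thermal_time_to_maturity
    k = genotype.extinction_k
    r_tr_max = eval_ftsw_response(genotype.a_tr, 1.0)
    r_le_max = eval_ftsw_response(genotype.a_le, 1.0)

    # potential green-LAI trajectory: logistic rise to flowering, then
    # linear thermal-time senescence to zero at maturity
    tt_half, tt_scale = 0.5 * tt_flo, tt_flo / 8.0

    def lai_potential(tt):
        return genotype.potential_lai / (1.0 + np.exp(-(tt - tt_half) / tt_scale))

    atsw = soil.initial_water_fraction * ttsw
    tt = 0.0
    lai = 0.0
    biomass = 0.0  # g / m2
    n_pool = soil.initial_n + mgmt.n_fertilization  # kg N / ha available
    # the emerging crop starts at the critical N status of the dilution
    # curve's biomass floor, limited by what the soil can supply
    n_uptake = min(DILUTION[0] * 10.0, n_pool)
    n_pool -= n_uptake
    flowering_day = maturity_day = -1
    rows = []
    balance = {"atsw_start": atsw, "precip_in": 0.0, "irrigation_in": 0.0,
               "transpiration_out": 0.0, "evaporation_out": 0.0, "clamp_loss": 0.0}

    for day in range(start, n_days):
        tm = climate.tmean[day]
        dtt = max(tm - T_BASE, 0.0)
        ftsw = min(max(atsw / ttsw, 0.0), 1.0)
        f_water = eval_ftsw_response(genotype.a_tr, ftsw) / r_tr_max
        f_le = eval_ftsw_response(genotype.a_le, ftsw) / r_le_max
        f_tlow, f_thigh = _temperature_split(tm, genotype.cardinals)
        current_nni = nni(biomass / 100.0, n_uptake)
        f_nlow = min(current_nni, 1.0)

        interception = 1.0 - np.exp(-k * lai)
        transp = climate.pet[day] * interception * (f_water * r_tr_max)
        evap = SOIL_EVAP_FRAC * climate.pet[day] * (1.0 - interception) * ftsw

        if flowering_day < 0:
            growth = (lai_potential(tt + dtt) - lai_potential(tt)) * f_le * f_nlow
            lai = lai + max(growth, 0.0)
            lai_at_flowering = lai
        else:
            frac_left = max(tt_mat - (tt + dtt), 0.0) / (tt_mat - tt_flo)
            lai = lai_at_flowering * frac_left

        biomass += (
            genotype.rue
            * climate.radiation[day]
            * interception
            * temperature_factor(tm, genotype.cardinals)
            * f_water
        )

        irrigation = 0.0
        if mgmt.irrigation == "auto":
            irrigation = max(ttsw - (atsw + climate.precip[day] - transp - evap), 0.0)
        unclamped = atsw + climate.precip[day] + irrigation - transp - evap
        atsw = min(max(unclamped, 0.0), ttsw)
        balance["precip_in"] += climate.precip[day]
        balance["irrigation_in"] += irrigation
        balance["transpiration_out"] += transp
        balance["evaporation_out"] += evap
        balance["clamp_loss"] += unclamped - atsw

        # nitrogen: uptake chases the critical-dilution demand
        n_pool += soil.n_mineralization
        demand = max(
            DILUTION[0] * max(biomass / 100.0, 1.0) ** (1.0 - DILUTION[1]) * 10.0
            - n_uptake,
            0.0,
        )
        took = min(demand, n_pool)
        n_uptake += took
        n_pool -= took

        tt += dtt
        rows.append(
            (day + 1, tt, lai, biomass, interception, ftsw, current_nni,
             f_water, f_nlow, f_tlow, f_thigh)
        )
        if flowering_day < 0 and tt >= tt_flo:
            flowering_day = day + 1
            lai_at_flowering = lai
        if tt >= tt_mat:
            maturity_day = day + 1
            break

    if maturity_day < 0:
        raise RuntimeError(
            f"maturity not reached: attained {tt:.0f} deg C day of "
            f"{tt_mat:.0f} within the climate series"
        )

    series = pd.DataFrame(
        rows,
        columns=["doy", "tt", "lai", "biomass", "interception", "ftsw", "nni",
                 "f_water", "f_nlow", "f_tlow", "f_thigh"],
    )
    balance["atsw_end"] = atsw
    post = series["doy"] >= flowering_day
    mean_f_water_post = float(series.loc[post, "f_water"].mean())
    yield_g_m2 = biomass * genotype.harvest_index * mean_f_water_post
    oil_pct = BASE_OIL - OIL_PENALTY * (1.0 - mean_f_water_post)
    return SimulationOutput(
        genotype=genotype.name,
        env_id=climate.env_id,
        yield_g_m2=float(yield_g_m2),
        oil_pct=float(oil_pct),
        flowering_day=int(flowering_day),
        maturity_day=int(maturity_day),
        series=series,
        water_balance=balance,
    )


def stress_indicators(out: SimulationOutput) -> dict[str, float]:
    """Integrate the four daily stress deficits over the crop cycle.

    SFTSW = sum(1 - FTSW), SNNI = sum(1 - min(1, NNI)),
    SLT = sum(1 - f_tlow), SHT = sum(1 - f_thigh); all in unitless*days,
    daily trapezoid on the simulated series.
    """
    s = out.series

    def integ(deficit):
        return float(np.trapezoid(deficit, s["doy"].to_numpy(dtype=float)))

    return {
        "SFTSW": integ(1.0 - s["ftsw"].to_numpy()),
        "SNNI": integ(1.0 - np.minimum(s["nni"].to_numpy(), 1.0)),
        "SLT": integ(1.0 - s["f_tlow"].to_numpy()),
        "SHT": integ(1.0 - s["f_thigh"].to_numpy()),
    }
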