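"""Multi-year daily climate archetypes and paired soil profiles.

Each variable is a seasonal sinusoid plus AR(1) Gaussian noise,
truncated at zero for the non-negative variables.  An archetype shifts
the driver relevant to one abiotic stress: ``drought`` cuts summer
precipitation and raises evaporative demand, ``heat``/``cold`` shift
mean temperature, ``nitrogen`` pairs the (otherwise optimal) climate
with a low-mineralization soil, and ``optimal`` leaves everything
comfortable.  These are deliberate caricatures built so a clustering of
simulated stress indicators can be scored against the planted labels —
they make no claim of mimicking any real weather statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ARCHETYPES", "ClimateSeries", "SoilProfile", "gen_climate"]

ARCHETYPES = ("optimal", "drought", "heat", "cold", "nitrogen")

N_DAYS = 365
_PEAK_DOY = 200  # day of year of the summer temperature/radiation peak


@dataclass(frozen=True)
class SoilProfile:
    """Soil descriptors used by the crop water/nitrogen balance."""

    depth: float = 1000.0  # mm
    awc: float = 0.13  # available water per mm of soil
    n_mineralization: float = 3.0  # kg N / ha / day during the cycle
    initial_water_fraction: float = 1.0
    initial_n: float = 120.0  # kg N / ha

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("soil depth must be > 0")
        if not (0.0 < self.awc < 1.0):
            raise ValueError("awc must be in (0, 1)")
        if not (0.0 <= self.initial_water_fraction <= 1.0):
            raise ValueError("initial_water_fraction must be in [0, 1]")

    @property
    def ttsw_mm(self) -> float:
        return self.depth * self.awc


@dataclass
class ClimateSeries:
    """One location-year of daily weather (series of equal length >= 90)."""

    location_id: str
    year: int
    tmean: np.ndarray  # deg C
    radiation: np.ndarray  # MJ / m2
    pet: np.ndarray  # mm
    precip: np.ndarray  # mm
    archetype: str = ""

    def __post_init__(self):
        arrays = [np.asarray(a, dtype=float)
                  for a in (self.tmean, self.radiation, self.pet, self.precip)]
        n = arrays[0].size
        if n < 90 or any(a.size != n for a in arrays):
            raise ValueError("all climate series must share a length >= 90 days")
        if any(np.any(a < 0) for a in arrays[1:]):
            raise ValueError("radiation, pet and precip must be >= 0")
        self.tmean, self.radiation, self.pet, self.precip = arrays

    @property
    def env_id(self) -> str:
        return f"{self.location_id}_{self.year}"

    @property
    def n_days(self) -> int:
        return self.tmean.size


def _seasonal(doy: np.ndarray, mean: float, amp: float) -> np.ndarray:
    return mean + amp * np.cos(2.0 * np.pi * (doy - _PEAK_DOY) / 365.0)


def _ar1(rng, n, sd, rho):
    if sd == 0:
        return np.zeros(n)
    e = rng.normal(0.0, sd * np.sqrt(max(1.0 - rho**2, 1e-12)), size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + e[i]
    return x


def gen_climate(
    archetype: str,
    n_years: int,
    n_locations: int,
    seed: int = 0,
    ar_coef: float = 0.6,
    noise_scale: float = 1.0,
):
    """Generate one ClimateSeries per location x year plus paired soils.

    Returns (series, soils, labels): a list of ClimateSeries, a dict
    ``location_id -> SoilProfile``, and ``env_id -> archetype`` labels
    recorded as clustering ground truth.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(
            f"unknown archetype {archetype!r}; valid names: {', '.join(ARCHETYPES)}"
        )
    if n_years < 1 or n_locations < 1:
        raise ValueError("n_years and n_locations must be >= 1")
    rng = np.random.default_rng(seed)
    doy = np.arange(1, N_DAYS + 1, dtype=float)

    t_shift = {"heat": 7.0, "cold": -7.0}.get(archetype, 0.0)
    pet_scale = 1.3 if archetype == "drought" else 1.0
    # summer precipitation: generous (tracks PET) except under drought
    soil = SoilProfile()
    if archetype == "nitrogen":
        soil = SoilProfile(n_mineralization=0.05, initial_n=5.0)

    series, soils, labels = [], {}, {}
    for loc in range(n_locations):
        loc_id = f"{archetype[:3].upper()}{loc:02d}"
        soils[loc_id] = soil
        for year in range(n_years):
            t = _seasonal(doy, 17.0 + t_shift, 8.0) + _ar1(
                rng, N_DAYS, 0.7 * noise_scale, ar_coef
            )
            rad = np.maximum(
                _seasonal(doy, 14.0, 8.0) + _ar1(rng, N_DAYS, 1.5 * noise_scale, ar_coef),
                0.0,
            )
            pet = np.maximum(
                pet_scale * _seasonal(doy, 3.0, 2.5)
                + _ar1(rng, N_DAYS, 0.4 * noise_scale, ar_coef),
                0.0,
            )
            base_precip = 1.2 * _seasonal(doy, 3.0, 2.5)
            if archetype == "drought":
                # summer rain collapses; shoulder seasons keep some
                summer = np.exp(-0.5 * ((doy - _PEAK_DOY) / 55.0) ** 2)
                base_precip = base_precip * (1.0 - 0.95 * summer)
            precip = np.maximum(
                base_precip + _ar1(rng, N_DAYS, 1.0 * noise_scale, ar_coef), 0.0
            )
            series.append(
                ClimateSeries(
                    location_id=loc_id,
                    year=2000 + year,
                    tmean=t,
                    radiation=rad,
                    pet=pet,
                    precip=precip,
                    archetype=archetype,
                )
            )
            labels[series[-1].env_id] = archetype
    return series, soils, labels
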