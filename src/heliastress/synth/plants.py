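"""Forward model of a potted plant for controller experiments.

The model stands in for a real plant on the platform: each day it
transpires ``demand_scale * leaf_area * r(FTSW; a_TR)`` kilograms of
water, grows leaf area at ``potential_le * r(FTSW; a_LE)``, and its pot
weight is observed with Gaussian measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from heliastress.traits import eval_ftsw_response

__all__ = ["PlantModelTruth", "PlantForwardModel", "gen_plant_model"]


@dataclass(frozen=True)
class PlantModelTruth:
    """Ground-truth parameters of one simulated plant."""

    genotype_id: str
    a_tr: float  # transpiration response parameter, < 0
    a_le: float  # leaf-expansion response parameter, < 0
    potential_le: float = 0.0  # leaf area gain per day at FTSW = 1
    demand_scale: float = 0.5  # kg water per day per unit leaf area
    noise_sd_weight: float = 0.0  # weighing noise, kg
    initial_leaf_area: float = 1.0

    def __post_init__(self):
        for name in ("a_tr", "a_le", "potential_le", "demand_scale",
                     "noise_sd_weight", "initial_leaf_area"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {name} must be finite, got {v}")
        if self.a_tr >= 0:
            raise ValueError(f"a_tr must be strictly negative, got {self.a_tr}")
        if self.a_le >= 0:
            raise ValueError(f"a_le must be strictly negative, got {self.a_le}")
        if self.noise_sd_weight < 0:
            raise ValueError("noise_sd_weight must be >= 0")


class PlantForwardModel:
    """Daily-stepping plant: transpiration, leaf growth, noisy weighing."""

    def __init__(self, truth: PlantModelTruth, seed: int):
        self.truth = truth
        self.rng = np.random.default_rng(seed)
        self.leaf_area = truth.initial_leaf_area

    def step(self, atsw: float, ttsw: float, dt: float = 1.0) -> tuple[float, float]:
        """Advance dt days: returns (new transpirable water, water transpired).

        With zero demand (or FTSW = 0) and zero irrigation the true water
        content is unchanged.  Transpiration cannot take the pot below the
        lower transpiration limit.
        """
        ftsw = min(max(atsw / ttsw, 0.0), 1.0)
        demand = self.truth.demand_scale * self.leaf_area
        transp = demand * eval_ftsw_response(self.truth.a_tr, ftsw) * dt
        transp = min(transp, atsw)
        self.leaf_area += (
            self.truth.potential_le * eval_ftsw_response(self.truth.a_le, ftsw) * dt
        )
        return atsw - transp, transp

    def observe(self, true_weight: float) -> float:
        """Pot-weight observation: truth plus Gaussian measurement noise."""
        if self.truth.noise_sd_weight == 0:
            return true_weight
        return true_weight + self.rng.normal(0.0, self.truth.noise_sd_weight)


def gen_plant_model(truth: PlantModelTruth, seed: int) -> PlantForwardModel:
    """Instantiate a seeded plant forward model (validates parameters)."""
    return PlantForwardModel(truth, seed)
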