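"""Proportional correction of small-orchard yield predictions.

A regression model trained at county scale is systematically biased when
transferred to a single orchard.  The correction grounds the model with a
sampled sub-area: fruits on the sampled trees are counted (by a detector or
by hand), converted to a ground-estimated yield via the empirical
single-fruit weight and the sampling area, and compared with the model's
prediction for the same sub-area:

    alpha = Y_true_sample / Y_pre_sample
    Y_pre_end = alpha * Y_pre

The single factor assumes the sampling area is representative of the whole
orchard (uniform planting density and bias).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GroundSample:
    """Per-tree fruit counts over a sampled sub-area."""

    fruit_counts: list  # non-negative integers, one per tree
    single_fruit_weight: float  # kg
    sampling_area: float  # mu

    def __post_init__(self):
        if any(c < 0 for c in self.fruit_counts):
            raise ValueError("fruit counts must be non-negative")
        if not self.single_fruit_weight > 0:
            raise ValueError("single_fruit_weight must be positive")
        if not self.sampling_area > 0:
            raise ValueError("sampling_area must be positive")


@dataclass
class CorrectionScenario:
    """Predicted and ground-estimated yields for one orchard (kg/mu)."""

    y_pre_sample: float  # model prediction for the sampling area
    y_true_sample: float  # ground-estimated sampling-area yield
    y_pre: float  # model prediction for the whole orchard
    true_orchard_yield: float | None = None  # known only for synthetic data
    ground_sample: "GroundSample | None" = field(default=None)

    def __post_init__(self):
        for name in ("y_pre_sample", "y_true_sample", "y_pre"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def estimate_sample_yield(g: GroundSample) -> float:
    """Ground-estimated yield of the sampling area in kg/mu:
    (total fruit count * single-fruit weight) / area."""
    total = float(np.sum(g.fruit_counts))
    return total * g.single_fruit_weight / g.sampling_area


def correction_factor(y_true_sample: float, y_pre_sample: float,
                      round_dp: int | None = 2) -> float:
    """alpha = Y_true_sample / Y_pre_sample, optionally rounded for
    reporting (tables print 2 decimals); pass ``round_dp=None`` to keep
    full precision."""
    if not y_pre_sample > 0:
        raise ValueError("predicted sampling yield must be positive")
    alpha = y_true_sample / y_pre_sample
    return round(alpha, round_dp) if round_dp is not None else alpha


def corrected_yield(alpha: float, y_pre: float) -> float:
    """Y_pre_end = alpha * Y_pre."""
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    return alpha * y_pre


def correct_scenario(sc: CorrectionScenario,
                     alpha_precision: str = "rounded") -> dict:
    """Run the full correction on a scenario.

    ``alpha_precision='rounded'`` reproduces the reported two-decimal factor;
    ``'full'`` keeps machine precision (exact recovery under uniform bias).
    """
    if alpha_precision not in ("rounded", "full"):
        raise ValueError("alpha_precision must be 'rounded' or 'full'")
    dp = 2 if alpha_precision == "rounded" else None
    alpha = correction_factor(sc.y_true_sample, sc.y_pre_sample, round_dp=dp)
    return {"alpha": alpha, "corrected_yield": corrected_yield(alpha, sc.y_pre)}
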