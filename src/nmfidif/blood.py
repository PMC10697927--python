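"""Whole-blood to metabolite-corrected plasma input-function conversion.

Whole-blood activity from the image is not the quantity a compartment model
needs: the tracer distributes between plasma and blood cells, and labeled
metabolites accumulate in plasma over the scan.  Both corrections are
population-based here — a linear fit to measured plasma/whole-blood ratios
and a decreasing four-parameter logistic fit to the parent fraction — and
the corrected input function is their pointwise product with the
whole-blood curve:

    Cp_parent(t) = C_wb(t) * ratio(t) * pf(t)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import least_squares

from .io import Tac

__all__ = [
    "BloodSampleTable",
    "SigmoidParams",
    "CorrectionModel",
    "fit_ratio_linear",
    "fit_parent_sigmoid",
    "predict_ratio",
    "predict_parent_fraction",
    "correct_input_function",
]


@dataclass
class BloodSampleTable:
    """Discrete blood measurements (e.g. cardiac-puncture samples).

    All arrays share ``times_s``; ``plasma_to_wb_ratio`` and
    ``parent_fraction`` may be None when only whole-blood counts exist.
    """

    times_s: np.ndarray
    whole_blood: np.ndarray | None = None
    plasma_to_wb_ratio: np.ndarray | None = None
    parent_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if np.any(self.times_s < 0):
            raise ValueError("sample times must be non-negative")
        for name in ("whole_blood", "plasma_to_wb_ratio", "parent_fraction"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.times_s.shape:
                    raise ValueError(f"{name} must match times_s in length")
                setattr(self, name, v)
        if self.parent_fraction is not None and (
            np.any(self.parent_fraction < 0) or np.any(self.parent_fraction > 1)
        ):
            raise ValueError("parent_fraction must lie in [0, 1]")


def fit_ratio_linear(samples: BloodSampleTable) -> tuple[float, float]:
    """Ordinary-least-squares line through the plasma/whole-blood ratios.

    Returns ``(intercept, slope_per_s)``.
    """
    if samples.plasma_to_wb_ratio is None:
        raise ValueError("samples carry no plasma_to_wb_ratio")
    t, r = samples.times_s, samples.plasma_to_wb_ratio
    if len(t) < 2:
        raise ValueError("need at least 2 samples for a linear fit")
    slope, intercept = np.polyfit(t, r, 1)
    return float(intercept), float(slope)


def predict_ratio(coeffs: tuple[float, float], times_s) -> np.ndarray:
    """Evaluate the fitted ratio line, clipped below at zero."""
    intercept, slope = coeffs
    return np.clip(intercept + slope * np.asarray(times_s, float), 0.0, None)


@dataclass
class SigmoidParams:
    """Decreasing logistic: pf(t) = floor + (ceiling - floor)/(1 + (t/midpoint)^steepness)."""

    floor: float
    ceiling: float
    midpoint_s: float
    steepness: float

    def __post_init__(self) -> None:
        if not (0 <= self.floor <= self.ceiling <= 1):
            raise ValueError("need 0 <= floor <= ceiling <= 1")
        if self.midpoint_s <= 0 or self.steepness <= 0:
            raise ValueError("midpoint_s and steepness must be positive")


def predict_parent_fraction(params: SigmoidParams, times_s) -> np.ndarray:
    t = np.clip(np.asarray(times_s, float), 0.0, None)
    ratio = np.zeros_like(t)
    pos = t > 0
    ratio[pos] = (t[pos] / params.midpoint_s) ** params.steepness
    return params.floor + (params.ceiling - params.floor) / (1.0 + ratio)


def _sigmoid_from_vector(p: np.ndarray) -> SigmoidParams:
    # reparameterized so the box constraints imply floor <= ceiling <= 1
    a, b, log_mid, log_steep = p
    floor = a
    ceiling = a + (1.0 - a) * b
    return SigmoidParams(floor, ceiling, float(np.exp(log_mid)), float(np.exp(log_steep)))


def fit_parent_sigmoid(samples: BloodSampleTable, seed: int = 0) -> SigmoidParams:
    """Least-squares fit of the decreasing logistic to parent-fraction data.

    Multi-start over midpoint/steepness (grid plus seeded jitter); the best
    sum of squared residuals wins.  Raises if no start converges.
    """
    if samples.parent_fraction is None:
        raise ValueError("samples carry no parent_fraction")
    t, pf = samples.times_s, samples.parent_fraction
    if len(t) < 4:
        raise ValueError("need at least 4 samples for a sigmoid fit")

    def residuals(p):
        return predict_parent_fraction(_sigmoid_from_vector(p), t) - pf

    t_pos = t[t > 0]
    mid_grid = np.quantile(t_pos, [0.25, 0.5, 0.75]) if t_pos.size else np.array([60.0])
    rng = np.random.default_rng(seed)
    starts = []
    for mid in mid_grid:
        for steep in (0.5, 1.5, 4.0):
            starts.append([float(pf.min()), 0.9, np.log(mid), np.log(steep)])
    for _ in range(3):
        starts.append(
            [
                rng.uniform(0, pf.min() if pf.min() > 0 else 0.5),
                rng.uniform(0.5, 1.0),
                np.log(rng.uniform(t_pos.min() if t_pos.size else 1.0, t.max() + 1.0)),
                np.log(rng.uniform(0.2, 8.0)),
            ]
        )
    lower = [0.0, 0.0, np.log(1e-2), np.log(0.05)]
    upper = [1.0, 1.0, np.log(1e6), np.log(20.0)]
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lower, upper)
        try:
            res = least_squares(residuals, x0, bounds=(lower, upper))
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError("sigmoid fit failed to converge from any start")
    return _sigmoid_from_vector(best.x)


@dataclass
class CorrectionModel:
    """Population-based blood-to-plasma correction for one condition."""

    ratio_intercept: float
    ratio_slope_per_s: float
    parent_sigmoid: SigmoidParams

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "ratio_intercept": self.ratio_intercept,
                    "ratio_slope_per_s": self.ratio_slope_per_s,
                    "parent_sigmoid": asdict(self.parent_sigmoid),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "CorrectionModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            ratio_intercept=d["ratio_intercept"],
            ratio_slope_per_s=d["ratio_slope_per_s"],
            parent_sigmoid=SigmoidParams(**d["parent_sigmoid"]),
        )

    @classmethod
    def identity(cls) -> "CorrectionModel":
        """No-op correction (ratio = 1, parent fraction = 1)."""
        return cls(1.0, 0.0, SigmoidParams(1.0, 1.0, 1e5, 1.0))

    @classmethod
    def fit(cls, samples: BloodSampleTable, seed: int = 0) -> "CorrectionModel":
        intercept, slope = fit_ratio_linear(samples)
        return cls(intercept, slope, fit_parent_sigmoid(samples, seed=seed))


def correct_input_function(wb: Tac, model: CorrectionModel) -> Tac:
    """Metabolite-corrected plasma parent curve from a whole-blood TAC."""
    t = wb.times_s
    ratio = predict_ratio((model.ratio_intercept, model.ratio_slope_per_s), t)
    pf = predict_parent_fraction(model.parent_sigmoid, t)
    return wb.with_values(np.clip(wb.values * ratio * pf, 0.0, None))
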