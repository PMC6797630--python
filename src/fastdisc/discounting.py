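"""Discount-function families and derived summaries.

The subjective present value ``V`` of a reward of magnitude ``R`` delivered
after a delay ``D`` (in days) is modelled by one of four standard discount
functions:

========================  =============================
family                    V(R, D)
========================  =============================
``hyperbolic``            ``R / (1 + k D)``
``exponential``           ``R exp(-k D)``
``myerson_green``         ``R / (1 + k D)**s``
``modified_rachlin``      ``R / (1 + (k D)**s)``
========================  =============================

``k`` is the discount rate in days^-1; larger ``k`` means steeper
devaluation.  ``s > 0`` is a dimensionless curvature parameter used only by
the two hyperboloid families.  The hyperbolic form is the primary model;
the others support robustness analyses.  All delays are in days internally
(convert hours on ingest: 1 h = 1/24 day).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FAMILIES = ("hyperbolic", "exponential", "myerson_green", "modified_rachlin")
_HYPERBOLOIDS = ("myerson_green", "modified_rachlin")


@dataclass(frozen=True)
class DiscountFunction:
    """A discount-function family with its parameters.

    Parameters
    ----------
    family:
        One of :data:`FAMILIES`.
    k:
        Discount rate in days^-1.  Must be >= 0 (``k == 0`` is the
        no-discounting limit, permitted for testing).
    s:
        Curvature exponent, required for the hyperboloid families and
        ignored otherwise.
    """

    family: str = "hyperbolic"
    k: float = 0.02
    s: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown discount family {self.family!r}; expected one of {FAMILIES}"
            )
        if not np.isfinite(self.k) or self.k < 0:
            raise ValueError(f"discount rate k must be finite and >= 0, got {self.k}")
        if self.family in _HYPERBOLOIDS:
            if self.s is None or not self.s > 0:
                raise ValueError(f"family {self.family!r} requires curvature s > 0")

    def to_config(self) -> dict[str, float | str]:
        """Serialize to a plain key-value mapping."""
        out: dict[str, float | str] = {"family": self.family, "k": self.k}
        if self.s is not None:
            out["s"] = self.s
        return out

    @classmethod
    def from_config(cls, cfg: dict) -> "DiscountFunction":
        return cls(
            family=str(cfg["family"]),
            k=float(cfg["k"]),
            s=float(cfg["s"]) if "s" in cfg and cfg["s"] is not None else None,
        )


def present_value(spec: DiscountFunction, reward, delay):
    """Subjective present value of ``reward`` delivered after ``delay`` days.

    Vectorized over ``reward`` and ``delay``.  ``V == reward`` at delay 0,
    and V is strictly decreasing in delay when ``k > 0`` and ``reward > 0``.
    """
    reward = np.asarray(reward, dtype=float)
    delay = np.asarray(delay, dtype=float)
    if not np.all(np.isfinite(reward)):
        raise ValueError("reward must be finite")
    if np.any(delay < 0):
        raise ValueError("delay must be nonnegative (days)")
    kD = spec.k * delay
    if spec.family == "hyperbolic":
        frac = 1.0 / (1.0 + kD)
    elif spec.family == "exponential":
        frac = np.exp(-kD)
    elif spec.family == "myerson_green":
        frac = (1.0 + kD) ** (-spec.s)
    else:  # modified_rachlin
        frac = 1.0 / (1.0 + kD**spec.s)
    return reward * frac


def half_life(k: float) -> float:
    """Delay (days) at which hyperbolic value falls to half the reward.

    For V = R/(1 + kD), V = R/2 exactly at D = 1/k.
    """
    if not (np.isfinite(k) and k > 0):
        raise ValueError(f"half_life requires k > 0, got {k}")
    return 1.0 / k


def normalized_discount_auc(spec: DiscountFunction, delays, max_delay: float) -> float:
    """Normalized area under the discounting curve, in [0, 1].

    Trapezoidal area under (delay / max_delay, V / R) with an implicit
    anchor at (0, 1).  A model-agnostic discounting index: 1 for no
    discounting, -> 0 for immediate devaluation.
    """
    delays = np.asarray(delays, dtype=float)
    if delays.size == 0:
        raise ValueError("delays must be nonempty")
    if np.any(np.diff(delays) <= 0):
        raise ValueError("delays must be strictly increasing")
    if not max_delay > 0 or np.any(delays > max_delay):
        raise ValueError("all delays must be <= max_delay and max_delay > 0")
    x = np.concatenate(([0.0], delays / max_delay))
    y = np.concatenate(([1.0], present_value(spec, 1.0, delays)))
    return float(np.trapezoid(y, x))
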