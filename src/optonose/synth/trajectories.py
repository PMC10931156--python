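"""Fruit ripening trajectories: VOC emission versus storage time.

Stage boundaries (storage days at 25 degC / 95 % RH) come from combined
firmness and sensory staging of the three fruits:

* banana: unripe 0 <= d < 2, ripe 2 <= d < 6, overripe 6 <= d <= 8
* mango:  unripe 0 <= d < 3, ripe 3 <= d < 8, overripe 8 <= d <= 10
* peach:  unripe 0 <= d < 2, ripe 2 <= d < 7, overripe 7 <= d <= 10

Emission of each marker VOC rises sigmoidally with time (climacteric burst
around mid-ripening) on top of a small basal emission, so even unripe fruit
is distinguishable from an empty (blank) container.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .library import FRUIT_VOCS

#: (end of unripe, end of ripe, end of span) in storage days.
STAGE_BOUNDS: dict[str, tuple[float, float, float]] = {
    "banana": (2.0, 6.0, 8.0),
    "mango": (3.0, 8.0, 10.0),
    "peach": (2.0, 7.0, 10.0),
}

STAGES = ("unripe", "ripe", "overripe")


def stage_at(fruit: str, t_days: float) -> str:
    """Ripeness stage label at storage time ``t_days`` (half-open intervals,
    last day inclusive)."""
    u_end, r_end, span = STAGE_BOUNDS[fruit]
    if t_days < 0 or t_days > span:
        raise ValueError(f"{fruit} trajectory spans 0..{span} days, got {t_days}")
    if t_days < u_end:
        return "unripe"
    if t_days < r_end:
        return "ripe"
    return "overripe"


@dataclass(frozen=True)
class EmissionCurve:
    """Hill-in-time emission of one VOC: basal + burst around ``t50_days``."""

    basal_ppm: float
    cmax_ppm: float
    t50_days: float
    hill: float = 3.0

    def at(self, t_days: float) -> float:
        if t_days < 0:
            raise ValueError("storage time must be >= 0")
        if t_days == 0:
            return self.basal_ppm
        th = t_days**self.hill
        return self.basal_ppm + self.cmax_ppm * th / (th + self.t50_days**self.hill)


@dataclass(frozen=True)
class RipenessTrajectory:
    fruit: str
    curves: Mapping[str, EmissionCurve]

    def stage_at(self, t_days: float) -> str:
        return stage_at(self.fruit, t_days)

    def concentrations_at(self, t_days: float) -> dict[str, float]:
        return {voc: curve.at(t_days) for voc, curve in self.curves.items()}

    @property
    def span_days(self) -> float:
        return STAGE_BOUNDS[self.fruit][2]


# Per-fruit defaults, one triple per marker VOC: basal emission and burst
# amplitude in ppm.  Burst centres are staggered across the trajectory —
# one VOC peaks early (around the unripe/ripe boundary), one mid-ripe, one
# late (around the ripe/overripe boundary) — mirroring how the marker-VOC
# balance itself shifts with ripening, so the concentration *ratios* keep
# evolving even after the early curves saturate.
_BASALS = (25.0, 45.0, 65.0)
_CMAXES = (300.0, 500.0, 700.0)


def default_trajectory(
    fruit: str,
    *,
    rng: np.random.Generator | None = None,
    variability: float = 0.0,
    batch_shift: bool = False,
) -> RipenessTrajectory:
    """The nominal emission trajectory of one fruit specimen.

    ``variability`` applies a multiplicative jitter (fraction) to all curve
    parameters, emulating specimen-to-specimen spread.  ``batch_shift``
    applies the larger redraw used for test batches from different fruit
    lots: amplitudes scaled by U(0.7, 1.3) and burst centres shifted by up to
    15 % of the storage span.
    """
    u_end, r_end, span = STAGE_BOUNDS[fruit]
    mid_ripe = 0.5 * (u_end + r_end)
    t50s = (u_end, mid_ripe, r_end)
    curves: dict[str, EmissionCurve] = {}
    for voc, basal, cmax, t50 in zip(FRUIT_VOCS[fruit], _BASALS, _CMAXES, t50s):
        c = EmissionCurve(basal_ppm=basal, cmax_ppm=cmax, t50_days=t50)
        if batch_shift:
            if rng is None:
                raise ValueError("batch_shift requires an rng")
            c = replace(
                c,
                basal_ppm=c.basal_ppm * rng.uniform(0.7, 1.3),
                cmax_ppm=c.cmax_ppm * rng.uniform(0.7, 1.3),
                t50_days=max(0.5, c.t50_days + rng.uniform(-0.15, 0.15) * span),
            )
        if variability > 0:
            if rng is None:
                raise ValueError("variability requires an rng")
            jit = lambda x: x * (1.0 + variability * rng.uniform(-1.0, 1.0))  # noqa: E731
            c = replace(
                c,
                basal_ppm=jit(c.basal_ppm),
                cmax_ppm=jit(c.cmax_ppm),
                t50_days=max(0.5, jit(c.t50_days)),
            )
        curves[voc] = c
    return RipenessTrajectory(fruit=fruit, curves=curves)
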