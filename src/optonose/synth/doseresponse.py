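"""Pre/post exposure image pairs along a concentration series.

Blank arrays are not perfectly stable between the two photographs: membrane
drying, scanner repositioning and dye ageing produce a small per-spot colour
drift, so the blank control has a nonzero total ED.  The generator realizes
that drift as integer per-spot colour offsets whose 25-spot total ED is
driven to a target drawn from N(blank_total_mean, blank_total_sd) — the
defaults reproduce a blank control with mean total ED 47.75 and sigma 2
(three sigma = 6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .library import DyeSpec, simulate_delta
from .render import ArrayImage, render_array_image, spot_colors
from .scene import SceneParams, canonical_scene

#: Blank-control total-ED statistics used throughout by default.
BLANK_TOTAL_ED_MEAN = 47.75
BLANK_TOTAL_ED_SD = 2.0


def draw_blank_drift(rng: np.random.Generator, target_total_ed: float) -> np.ndarray:
    """Integer (25, 3) per-spot drift whose summed per-spot ED is within
    ~0.6 counts of ``target_total_ed``.

    A continuous isotropic draw is scaled to the target and rounded; single
    +/-1 channel adjustments then repair the quantization error, since each
    adjustment moves the total by less than one count.
    """
    if target_total_ed <= 0:
        return np.zeros((25, 3), dtype=int)
    g = rng.normal(size=(25, 3))
    norms = np.linalg.norm(g, axis=1)
    norms[norms == 0] = 1.0
    drift = np.rint(g * (target_total_ed / norms.sum())).astype(int)

    def total(d: np.ndarray) -> float:
        return float(np.linalg.norm(d, axis=1).sum())

    cur = total(drift)
    for _ in range(500):
        if abs(cur - target_total_ed) <= 0.6:
            break
        i = int(rng.integers(0, 25))
        j = int(rng.integers(0, 3))
        step = 1 if cur < target_total_ed else -1
        # move the channel magnitude up or down by one count
        sign = 1 if drift[i, j] >= 0 else -1
        drift[i, j] += step * sign
        cur = total(drift)
    return drift


@dataclass(frozen=True)
class ExposurePair:
    """One replicate: the same membrane photographed before and after
    exposure."""

    pre: ArrayImage
    post: ArrayImage
    voc: str
    concentration: float
    replicate: int


def signal_total_ed(library: list[DyeSpec], voc: str, concentration: float) -> float:
    """Deterministic quantized total ED of the pure dose-response signal.

    This is exactly what canonical-scene, zero-drift image extraction
    measures: per-spot colours are quantized once to 8-bit before
    differencing, so the oracle applies the same rounding.
    """
    total = 0.0
    for dye in library:
        base = np.asarray(dye.baseline_rgb, dtype=float)
        delta = simulate_delta(dye, {voc: concentration})
        quantized = np.clip(np.rint(base + delta), 0, 255) - np.clip(np.rint(base), 0, 255)
        total += float(np.linalg.norm(quantized))
    return total


def planted_lod(
    library: list[DyeSpec],
    voc: str,
    concentrations: list[float],
    threshold: float,
) -> float | None:
    """Oracle LOD: smallest tested concentration whose quantized signal ED
    exceeds ``threshold``; None if the series never crosses."""
    for c in concentrations:
        if signal_total_ed(library, voc, c) > threshold:
            return c
    return None


def generate_dose_response_images(
    library: list[DyeSpec],
    voc: str,
    concentrations: list[float],
    replicates: int,
    seed: int,
    *,
    blank_total_mean: float = BLANK_TOTAL_ED_MEAN,
    blank_total_sd: float = BLANK_TOTAL_ED_SD,
    scene: SceneParams | None = None,
    side: int = 120,
) -> list[ExposurePair]:
    """Pre/post image pairs for one VOC across a concentration series.

    Concentrations must be sorted ascending; a concentration of 0 renders a
    blank-exposure pair (drift only).  With ``blank_total_mean = 0`` and
    ``blank_total_sd = 0`` the drift is disabled and a zero-concentration
    pair is pixel-identical on the spots.
    """
    if len(concentrations) == 0:
        raise ValueError("concentration list must not be empty")
    if any(b > a for a, b in zip(concentrations[1:], concentrations[:-1])):
        raise ValueError("concentrations must be sorted ascending")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    pairs: list[ExposurePair] = []
    for conc in concentrations:
        for rep in range(replicates):
            sc = scene if scene is not None else canonical_scene(
                background_texture_seed=int(rng.integers(0, 2**31 - 1))
            )
            if blank_total_sd > 0 or blank_total_mean > 0:
                target = rng.normal(blank_total_mean, blank_total_sd)
                drift = draw_blank_drift(rng, max(target, 0.0))
            else:
                drift = None
            meta = {"voc": voc, "concentration": float(conc), "replicate": rep}
            pre = render_array_image(
                library, {}, sc, seed=int(rng.integers(0, 2**31 - 1)), side=side,
                metadata=dict(meta, exposure="pre"),
            )
            post = render_array_image(
                library, {voc: float(conc)}, sc, seed=int(rng.integers(0, 2**31 - 1)),
                side=side, drift=drift, metadata=dict(meta, exposure="post"),
            )
            pairs.append(ExposurePair(pre=pre, post=post, voc=voc,
                                      concentration=float(conc), replicate=rep))
    return pairs


def blank_spot_colors(library: list[DyeSpec]) -> np.ndarray:
    """Quantized baseline spot colours (no gas, no drift)."""
    return spot_colors(library, {})
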