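"""Synthetic 25-dye colorimetric sensor library and its gas response model.

A colorimetric sensor array carries 25 chemo-responsive dyes in a 5 x 5 grid.
Each dye has a baseline membrane colour and, for each of the nine fruit
marker volatiles (VOCs), a saturating dose-response: the colour shift
approaches a dye-and-VOC-specific maximum ``max_drgb`` with half-saturation
concentration ``k_ppm``.  Cross-reactivity (many dyes responding, each with a
different pattern) is what makes the joint colour change a usable gas
fingerprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

# Marker volatiles per fruit, as identified by headspace GC-MS of ripening
# mango, peach and banana.
MANGO_VOCS = ("(+)-limonene", "beta-myrcene", "3-carene")
PEACH_VOCS = ("benzaldehyde", "ethyl acetate", "hexyl acetate")
BANANA_VOCS = ("ethanol", "trans-2-hexenal", "isoamyl acetate")
ALL_VOCS = MANGO_VOCS + PEACH_VOCS + BANANA_VOCS

FRUIT_VOCS: dict[str, tuple[str, ...]] = {
    "mango": MANGO_VOCS,
    "peach": PEACH_VOCS,
    "banana": BANANA_VOCS,
}
VOC_FRUIT: dict[str, str] = {v: f for f, vs in FRUIT_VOCS.items() for v in vs}

# Fixed 25-dye panel: two aldehyde/ketone-sensitive dyes, three solvatochromic
# dyes, three redox dyes, three Lewis-acidic dyes and fourteen pH indicators.
DYE_PANEL: tuple[tuple[str, str], ...] = (
    ("pararosaniline", "aldehyde/ketone-sensitive"),
    ("leuco malachite green", "aldehyde/ketone-sensitive"),
    ("nile red", "solvatochromic"),
    ("merocyanine 540", "solvatochromic"),
    ("disperse orange 3", "solvatochromic"),
    ("o-tolidine", "redox"),
    ("o-dianisidine", "redox"),
    ("methylene blue", "redox"),
    ("indigo carmine", "lewis-acidic"),
    ("basic yellow 1", "lewis-acidic"),
    ("crystal violet", "lewis-acidic"),
    ("bromophenol blue", "ph-indicator"),
    ("cresol red", "ph-indicator"),
    ("tetraiodophenolsulfonphthalein", "ph-indicator"),
    ("m-cresol purple", "ph-indicator"),
    ("bromocresol green", "ph-indicator"),
    ("bromocresol purple", "ph-indicator"),
    ("methyl red", "ph-indicator"),
    ("methyl orange", "ph-indicator"),
    ("thymol blue", "ph-indicator"),
    ("phenol red", "ph-indicator"),
    ("chlorophenol red", "ph-indicator"),
    ("bromothymol blue", "ph-indicator"),
    ("neutral red", "ph-indicator"),
    ("alizarin", "ph-indicator"),
)

DYE_CLASS_CENSUS: dict[str, int] = {
    "aldehyde/ketone-sensitive": 2,
    "solvatochromic": 3,
    "redox": 3,
    "lewis-acidic": 3,
    "ph-indicator": 14,
}


@dataclass(frozen=True)
class VOCProfile:
    """One volatile at a given gas-phase concentration.

    ``fruit`` is derived from the volatile identity; concentrations are in
    ppm and must be non-negative.
    """

    voc_name: str
    concentration: float
    fruit: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.voc_name not in VOC_FRUIT:
            raise ValueError(f"unknown VOC {self.voc_name!r}; expected one of {ALL_VOCS}")
        if not np.isfinite(self.concentration) or self.concentration < 0:
            raise ValueError(f"concentration must be >= 0 ppm, got {self.concentration}")
        object.__setattr__(self, "fruit", VOC_FRUIT[self.voc_name])


@dataclass(frozen=True)
class DyeSpec:
    """One dye spot: identity, baseline colour, and per-VOC sensitivity.

    ``sensitivity`` maps each VOC name to ``(max_drgb, k_ppm)`` where
    ``max_drgb`` is the signed saturation colour shift per channel (8-bit
    counts) and ``k_ppm`` the half-saturation concentration.
    """

    dye_id: int
    name: str
    dye_class: str
    baseline_rgb: tuple[int, int, int]
    sensitivity: Mapping[str, tuple[np.ndarray, float]]

    def max_abs_shift(self) -> np.ndarray:
        """Per-channel cap on the total colour shift (counts)."""
        mags = np.stack([np.abs(m) for m, _ in self.sensitivity.values()])
        return mags.max(axis=0)


def make_dye_library(
    seed: int,
    *,
    strong_floor: float = 40.0,
    weak_ceiling: float = 6.0,
    n_strong_range: tuple[int, int] = (5, 9),
) -> list[DyeSpec]:
    """Draw a seeded 25-dye library with controlled cross-reactivity.

    Every VOC gets a strong response (dominant channel magnitude at least
    ``strong_floor`` counts) from between 5 and 9 dyes and only a weak
    response (all channels below ``weak_ceiling``) from the rest, so each
    VOC's fingerprint involves a distinct subset of spots.
    """
    rng = np.random.default_rng(seed)
    baselines = rng.integers(40, 216, size=(25, 3))
    strong_sets = {
        voc: set(rng.choice(25, size=rng.integers(*n_strong_range, endpoint=True), replace=False))
        for voc in ALL_VOCS
    }
    dyes = []
    for dye_id, (name, dye_class) in enumerate(DYE_PANEL):
        sens: dict[str, tuple[np.ndarray, float]] = {}
        for voc in ALL_VOCS:
            if dye_id in strong_sets[voc]:
                shift = rng.uniform(10.0, 60.0, size=3) * rng.choice([-1.0, 1.0], size=3)
                dom = rng.integers(0, 3)
                shift[dom] = np.sign(shift[dom]) * rng.uniform(strong_floor + 5.0, 75.0)
                k = float(rng.uniform(30.0, 300.0))
            else:
                shift = rng.uniform(-weak_ceiling, weak_ceiling, size=3)
                k = float(rng.uniform(50.0, 300.0))
            sens[voc] = (shift, k)
        dyes.append(
            DyeSpec(
                dye_id=dye_id,
                name=name,
                dye_class=dye_class,
                baseline_rgb=tuple(int(c) for c in baselines[dye_id]),
                sensitivity=sens,
            )
        )
    return dyes


def _as_gas_dict(gas: Iterable[VOCProfile] | Mapping[str, float]) -> dict[str, float]:
    if isinstance(gas, Mapping):
        out = dict(gas)
    else:
        out = {}
        for p in gas:
            out[p.voc_name] = out.get(p.voc_name, 0.0) + p.concentration
    for voc, c in out.items():
        if voc not in VOC_FRUIT:
            raise ValueError(f"unknown VOC {voc!r}")
        if not np.isfinite(c) or c < 0:
            raise ValueError(f"concentration must be >= 0 ppm, got {c} for {voc}")
    return out


def simulate_delta(
    dye: DyeSpec,
    gas: Iterable[VOCProfile] | Mapping[str, float],
    *,
    hill_coefficient: float = 1.0,
) -> np.ndarray:
    """Equilibrium colour shift (ΔR, ΔG, ΔB) of one dye under a gas mixture.

    Each VOC contributes a Hill-form saturating term
    ``max_drgb * c**h / (c**h + k**h)``; mixtures sum channel-wise and the
    total is clipped to the dye's per-channel saturation envelope.  The
    response is exactly zero at zero concentration and monotone in every
    concentration.
    """
    conc = _as_gas_dict(gas)
    h = float(hill_coefficient)
    delta = np.zeros(3)
    for voc, c in conc.items():
        if c == 0.0:
            continue
        max_drgb, k = dye.sensitivity[voc]
        delta += max_drgb * (c**h / (c**h + k**h))
    cap = dye.max_abs_shift()
    return np.clip(delta, -cap, cap)


def library_census(library: list[DyeSpec]) -> dict[str, int]:
    census: dict[str, int] = {}
    for d in library:
        census[d.dye_class] = census.get(d.dye_class, 0) + 1
    return census
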