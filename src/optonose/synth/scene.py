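"""Photographic scene model for array image capture.

Real array photographs are taken "in the wild": lighting colour and
intensity, camera angle and sensor noise all vary between shots.  The scene
model is deliberately small: per-channel multiplicative illumination gain,
a small in-plane rotation plus a mild perspective (corner-displacement)
warp, and additive Gaussian pixel noise.  The canonical scene (all gains 1,
zero jitter, zero noise) is the identity of the perturbation model.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


@dataclass(frozen=True)
class SceneParams:
    illumination_gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    rotation_deg: float = 0.0
    perspective: float = 0.0  # corner displacement as a fraction of the side
    additive_noise_sd: float = 0.0  # 8-bit counts
    background_texture_seed: int = 0

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.illumination_gain):
            raise ValueError("illumination gains must be > 0")
        if self.additive_noise_sd < 0 or self.perspective < 0:
            raise ValueError("noise sd and perspective magnitude must be >= 0")

    @property
    def is_canonical(self) -> bool:
        return (
            self.illumination_gain == (1.0, 1.0, 1.0)
            and self.rotation_deg == 0.0
            and self.perspective == 0.0
            and self.additive_noise_sd == 0.0
        )

    def to_dict(self) -> dict:
        return asdict(self)


def canonical_scene(background_texture_seed: int = 0) -> SceneParams:
    return SceneParams(background_texture_seed=background_texture_seed)


#: Scene presets.  "easy" is near-laboratory capture; "hard" emulates the
#: arbitrarily transformed light and angles of in-container photography.
SCENE_PRESETS: dict[str, dict] = {
    "easy": dict(gain=(0.98, 1.02), rotation=1.0, perspective=0.0, noise=0.5),
    "hard": dict(gain=(0.80, 1.20), rotation=5.0, perspective=0.015, noise=3.0),
}


def random_scene(rng: np.random.Generator, preset: str = "hard") -> SceneParams:
    p = SCENE_PRESETS[preset]
    return SceneParams(
        illumination_gain=tuple(rng.uniform(*p["gain"], size=3)),
        rotation_deg=float(rng.uniform(-p["rotation"], p["rotation"])),
        perspective=float(rng.uniform(0.0, p["perspective"])),
        additive_noise_sd=p["noise"],
        background_texture_seed=int(rng.integers(0, 2**31 - 1)),
    )
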