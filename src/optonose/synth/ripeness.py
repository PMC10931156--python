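"""Labeled ripeness image datasets.

Each image emulates one 12-hour monitoring photograph of an array mounted
inside a fruit storage container: the array colour state reflects the
container's VOC composition at that storage time, and the photograph is
taken under a randomized scene.  Labels are the ten classes
{banana, mango, peach} x {unripe, ripe, overripe} plus "blank" (an
unreacted array photographed under the same scene variation).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import DyeSpec
from .render import ArrayImage, render_array_image
from .scene import random_scene
from .trajectories import STAGE_BOUNDS, STAGES, default_trajectory, stage_at

#: The ten classification targets, in fixed label order.
CLASSES: tuple[str, ...] = tuple(
    f"{fruit}_{stage}" for fruit in ("banana", "mango", "peach") for stage in STAGES
) + ("blank",)

SAMPLING_INTERVAL_H = 12.0


@dataclass
class RipenessDataset:
    """Labeled image manifest plus the in-memory rasters.

    ``manifest`` has one row per image with columns: index, fruit, stage,
    class_label, timestamp_h, split, seed and the scene parameters.
    """

    images: list[ArrayImage]
    manifest: pd.DataFrame
    classes: tuple[str, ...] = field(default=CLASSES)

    def __len__(self) -> int:
        return len(self.images)

    def labels(self) -> np.ndarray:
        idx = {c: i for i, c in enumerate(self.classes)}
        return np.array([idx[c] for c in self.manifest["class_label"]])

    def subset(self, split: str) -> "RipenessDataset":
        mask = (self.manifest["split"] == split).to_numpy()
        return RipenessDataset(
            images=[im for im, m in zip(self.images, mask) if m],
            manifest=self.manifest[mask].reset_index(drop=True),
            classes=self.classes,
        )

    def save(self, out_dir: str) -> str:
        """Write PNGs plus manifest.csv; returns the manifest path."""
        from PIL import Image

        os.makedirs(out_dir, exist_ok=True)
        paths = []
        for i, im in enumerate(self.images):
            path = os.path.join(out_dir, f"array_{i:05d}.png")
            Image.fromarray(im.pixels).save(path)
            paths.append(path)
        manifest = self.manifest.copy()
        manifest["path"] = paths
        manifest_path = os.path.join(out_dir, "manifest.csv")
        manifest.to_csv(manifest_path, index=False)
        return manifest_path


def split_assignments(n: int, split_ratio: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Seeded random train/val partition at the given ratio, rounding toward
    the training split (20 items at 17:3 give exactly 17/3; 21 give 18/3)."""
    train_w, val_w = split_ratio
    n_val = int(np.floor(n * val_w / (train_w + val_w)))
    labels = np.array(["train"] * n, dtype=object)
    labels[rng.permutation(n)[:n_val]] = "val"
    return labels


#: Dataset difficulty presets.  "easy" samples away from stage boundaries
#: with low specimen variability under near-laboratory scenes, giving
#: classes that are well separated by construction; "hard" samples the full
#: stage intervals with realistic specimen spread under wide scene variation,
#: so neighbouring stages genuinely overlap near their boundaries.
DATASET_PRESETS: dict[str, dict] = {
    "easy": dict(scene_preset="easy", trajectory_variability=0.02,
                 boundary_margin_days=1.0),
    "hard": dict(scene_preset="hard", trajectory_variability=0.08,
                 boundary_margin_days=0.0),
}


def _stage_timestamps(fruit: str, stage: str, margin_days: float = 0.0) -> np.ndarray:
    """12-hour sampling grid points inside one ripeness stage, optionally
    keeping ``margin_days`` clear of the internal stage boundaries."""
    u_end, r_end, span = STAGE_BOUNDS[fruit]
    grid = np.arange(0.0, span * 24.0 + 1e-9, SAMPLING_INTERVAL_H)
    keep = []
    for t in grid:
        d = t / 24.0
        if stage_at(fruit, d) != stage:
            continue
        if margin_days > 0 and any(abs(d - b) < margin_days for b in (u_end, r_end)):
            continue
        keep.append(t)
    if not keep:
        raise ValueError(f"no 12 h grid points left in {fruit} {stage} "
                         f"with margin {margin_days} d")
    return np.array(keep)


def generate_ripeness_dataset(
    library: list[DyeSpec],
    n_images_per_class: int,
    seed: int,
    *,
    split_ratio: tuple[int, int] = (17, 3),
    scene_preset: str = "hard",
    batch: str = "train",
    trajectory_variability: float = 0.08,
    boundary_margin_days: float = 0.0,
    side: int = 96,
    out_dir: str | None = None,
) -> RipenessDataset:
    """Generate a balanced, labeled 10-class image dataset.

    ``batch="test"`` redraws every specimen's trajectory parameters with the
    larger batch-shift spread, emulating a test set from different fruit
    lots; its images are all assigned split "test".
    """
    if n_images_per_class < 1:
        raise ValueError("need at least one image per class")
    rng = np.random.default_rng(seed)
    batch_shift = batch == "test"
    images: list[ArrayImage] = []
    rows = []
    for class_label in CLASSES:
        for _ in range(n_images_per_class):
            scene = random_scene(rng, preset=scene_preset)
            if class_label == "blank":
                fruit, stage = "none", "blank"
                t_h = float(rng.choice(_stage_timestamps("banana", "unripe")))
                gas: dict[str, float] = {}
            else:
                fruit, stage = class_label.split("_")
                traj = default_trajectory(
                    fruit, rng=rng,
                    variability=trajectory_variability,
                    batch_shift=batch_shift,
                )
                t_h = float(rng.choice(
                    _stage_timestamps(fruit, stage, boundary_margin_days)))
                gas = traj.concentrations_at(t_h / 24.0)
            img = render_array_image(
                library, gas, scene, seed=int(rng.integers(0, 2**31 - 1)), side=side,
                metadata={"fruit": fruit, "stage": stage, "class_label": class_label,
                          "timestamp_h": t_h},
            )
            images.append(img)
            rows.append({
                "fruit": fruit, "stage": stage, "class_label": class_label,
                "timestamp_h": t_h, "seed": seed,
                **{f"scene_{k}": v for k, v in scene.to_dict().items()},
            })
    manifest = pd.DataFrame(rows)
    if batch == "test":
        manifest["split"] = "test"
    else:
        manifest["split"] = split_assignments(len(manifest), split_ratio, rng)
    ds = RipenessDataset(images=images, manifest=manifest)
    if out_dir is not None:
        ds.save(out_dir)
    return ds
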