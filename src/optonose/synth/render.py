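"""Rasterize synthetic sensor-array photographs.

An array image is a textured membrane with 25 dye spots in a 5 x 5 grid
(row-major from top-left) plus in-frame white and black calibration patches
rendered at known reference values.  Scene perturbations (geometry, then
illumination gain, then pixel noise) are applied to the whole composite;
the ground-truth spot colours and the transformed spot/patch coordinates
are carried in the image metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.transform import AffineTransform, ProjectiveTransform, warp

from .library import DyeSpec, VOCProfile, simulate_delta
from .scene import SceneParams

#: Reference values at which the calibration patches are painted.  The white
#: reference is kept below 255/1.25 so realistic illumination gains do not
#: clip it, which would make two-point calibration unrecoverable.
WHITE_REF = (200, 200, 200)
BLACK_REF = (20, 20, 20)

_MEMBRANE_RGB = np.array([236.0, 232.0, 226.0])


@dataclass
class ArrayImage:
    """One photographed sensor membrane.

    ``spot_centers`` are (row, col) pixel coordinates of the 25 spots in
    row-major grid order, already mapped through any geometric scene
    transform; the patch boxes are axis-aligned (r0, c0, r1, c1) rectangles
    guaranteed to lie inside the transformed patches.
    """

    pixels: np.ndarray  # (H, W, 3) uint8
    spot_centers: np.ndarray  # (25, 2) float, (row, col)
    white_patch_box: tuple[int, int, int, int]
    black_patch_box: tuple[int, int, int, int]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) raster")
        h, w = self.pixels.shape[:2]
        if len(self.spot_centers) != 25:
            raise ValueError("an array image carries exactly 25 spots")
        r, c = self.spot_centers[:, 0], self.spot_centers[:, 1]
        if (r < 0).any() or (r >= h).any() or (c < 0).any() or (c >= w).any():
            raise ValueError("spot centers must lie inside the raster")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def save(self, path: str) -> None:
        """Write the raster as PNG plus a JSON sidecar with the centres,
        patch boxes and scalar metadata."""
        import json

        from PIL import Image

        Image.fromarray(self.pixels).save(path)
        meta = {k: v for k, v in self.metadata.items() if not isinstance(v, np.ndarray)}
        sidecar = {
            "spot_centers": self.spot_centers.tolist(),
            "white_patch_box": list(self.white_patch_box),
            "black_patch_box": list(self.black_patch_box),
            "metadata": meta,
        }
        with open(path + ".json", "w") as fh:
            json.dump(sidecar, fh)

    @classmethod
    def load(cls, path: str) -> "ArrayImage":
        import json

        from PIL import Image

        pixels = np.asarray(Image.open(path).convert("RGB"))
        with open(path + ".json") as fh:
            sidecar = json.load(fh)
        return cls(
            pixels=pixels,
            spot_centers=np.asarray(sidecar["spot_centers"], dtype=float),
            white_patch_box=tuple(sidecar["white_patch_box"]),
            black_patch_box=tuple(sidecar["black_patch_box"]),
            metadata=sidecar["metadata"],
        )


#: Border (fraction of the side) kept free of spots so that the calibration
#: patches and small geometric jitter never collide with the grid.
_MARGIN_FRAC = 0.12


def grid_pitch(side: int) -> float:
    return (1.0 - 2.0 * _MARGIN_FRAC) * side / 6.0


def grid_centers(side: int) -> np.ndarray:
    """Canonical (row, col) centres of the 5 x 5 grid, row-major from
    top-left, at uniform pitch inside the membrane margin."""
    m = _MARGIN_FRAC * side
    pitch = grid_pitch(side)
    rows, cols = np.mgrid[1:6, 1:6]
    return np.column_stack([m + rows.ravel() * pitch, m + cols.ravel() * pitch])


def default_spot_radius(side: int) -> float:
    return 0.35 * grid_pitch(side)


def _patch_boxes(side: int) -> tuple[tuple[int, int, int, int], tuple[int, int, int, int]]:
    s = max(6, round(0.09 * side))
    white = (4, 4, 4 + s, 4 + s)
    black = (4, side - 4 - s, 4 + s, side - 4)
    return white, black


def _inner_box(corners_rc: np.ndarray, shrink: float = 0.6) -> tuple[int, int, int, int]:
    """Axis-aligned rectangle safely inside a (slightly) warped patch."""
    centroid = corners_rc.mean(axis=0)
    half = 0.5 * shrink * min(np.ptp(corners_rc[:, 0]), np.ptp(corners_rc[:, 1]))
    half = max(half, 1.0)
    r0, c0 = np.floor(centroid - half).astype(int)
    r1, c1 = np.ceil(centroid + half).astype(int)
    return int(max(r0, 0)), int(max(c0, 0)), int(r1), int(c1)


def _background(side: int, texture_seed: int, amplitude: float = 3.0) -> np.ndarray:
    rng = np.random.default_rng(texture_seed)
    field_ = rng.normal(size=(side, side))
    field_ = gaussian_filter(field_, sigma=side / 8.0)
    sd = field_.std()
    if sd > 0:
        field_ = field_ / sd * amplitude
    return _MEMBRANE_RGB[None, None, :] + field_[:, :, None]


def _box_corners(box: tuple[int, int, int, int]) -> np.ndarray:
    r0, c0, r1, c1 = box
    return np.array([[r0, c0], [r0, c1], [r1, c0], [r1, c1]], dtype=float)


def spot_colors(
    library: list[DyeSpec],
    gas: list[VOCProfile] | dict[str, float],
    drift: np.ndarray | None = None,
) -> np.ndarray:
    """Ground-truth 8-bit spot colours: baseline + dose response (+ drift)."""
    cols = np.empty((25, 3))
    for i, dye in enumerate(library):
        cols[i] = np.asarray(dye.baseline_rgb, dtype=float) + simulate_delta(dye, gas)
    if drift is not None:
        cols = cols + drift
    return np.clip(np.rint(cols), 0, 255).astype(np.uint8)


def render_array_image(
    library: list[DyeSpec],
    gas: list[VOCProfile] | dict[str, float],
    scene: SceneParams,
    seed: int,
    *,
    side: int = 120,
    spot_radius: float | None = None,
    drift: np.ndarray | None = None,
    metadata: dict | None = None,
) -> ArrayImage:
    """Render one array photograph under the given scene.

    Under the canonical scene the mean colour inside every spot equals the
    ground-truth spot colour exactly (spots are filled uniform disks and the
    raster is quantized once).
    """
    if len(library) != 25:
        raise ValueError("a sensor array carries exactly 25 dyes")
    rng = np.random.default_rng(seed)
    radius = default_spot_radius(side) if spot_radius is None else float(spot_radius)
    centers = grid_centers(side)
    white_box, black_box = _patch_boxes(side)

    canvas = _background(side, scene.background_texture_seed)
    truth = spot_colors(library, gas, drift)
    for i, (r, c) in enumerate(centers):
        rr, cc = draw_disk((r, c), radius, shape=(side, side))
        canvas[rr, cc] = truth[i]
    for box, ref in ((white_box, WHITE_REF), (black_box, BLACK_REF)):
        r0, c0, r1, c1 = box
        canvas[r0:r1, c0:c1] = np.asarray(ref, dtype=float)

    # Geometric perturbation (shared by spots, patches and background).
    if scene.rotation_deg != 0.0 or scene.perspective > 0.0:
        centre_xy = np.array([(side - 1) / 2.0, (side - 1) / 2.0])
        tform = (
            AffineTransform(translation=-centre_xy)
            + AffineTransform(rotation=np.deg2rad(scene.rotation_deg))
            + AffineTransform(translation=centre_xy)
        )
        if scene.perspective > 0.0:
            src = np.array([[0, 0], [side - 1, 0], [side - 1, side - 1], [0, side - 1]], float)
            dst = src + rng.uniform(-1.0, 1.0, size=(4, 2)) * scene.perspective * side
            if hasattr(ProjectiveTransform, "from_estimate"):
                persp = ProjectiveTransform.from_estimate(src, dst)
            else:  # older scikit-image
                persp = ProjectiveTransform()
                persp.estimate(src, dst)
            tform = tform + persp
        canvas = warp(
            canvas, tform.inverse, order=1, cval=float(_MEMBRANE_RGB.mean()), preserve_range=True
        )
        xy = tform(centers[:, ::-1])  # transforms act on (x, y) = (col, row)
        centers = np.clip(xy[:, ::-1], 0, side - 1)
        white_box = _inner_box(tform(_box_corners(white_box)[:, ::-1])[:, ::-1])
        black_box = _inner_box(tform(_box_corners(black_box)[:, ::-1])[:, ::-1])

    canvas = canvas * np.asarray(scene.illumination_gain)[None, None, :]
    if scene.additive_noise_sd > 0:
        canvas = canvas + rng.normal(0.0, scene.additive_noise_sd, size=canvas.shape)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    meta = dict(metadata or {})
    meta.setdefault("scene", scene.to_dict())
    meta["true_spot_rgb"] = truth
    meta["spot_radius"] = radius
    meta["seed"] = int(seed)
    return ArrayImage(
        pixels=pixels,
        spot_centers=centers,
        white_patch_box=white_box,
        black_patch_box=black_box,
        metadata=meta,
    )
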