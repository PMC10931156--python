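"""Calibrated spot-colour extraction and ED response signatures.

The processing chain for one pre/post exposure pair is:

1. two-point colour calibration per channel from the in-frame white and
   black patches (undoes illumination gain/offset between shots),
2. mean RGB over a sampling disk at each of the 25 spot centres,
3. per-spot differences post - pre, giving the signed (ΔR, ΔG, ΔB)
   triplets, the per-spot Euclidean response ED = sqrt(ΔR² + ΔG² + ΔB²)
   and the 25-spot total response,
4. optionally, a 5 x 5 differential map that stretches |Δ| from the 3-10
   count range onto the full 0-255 display range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth.render import ArrayImage, WHITE_REF, BLACK_REF, default_spot_radius


@dataclass(frozen=True)
class SpotGrid:
    """25 (row, col) sampling centres in row-major grid order."""

    centers: np.ndarray
    sampling_radius: float

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        if centers.shape != (25, 2):
            raise ValueError("a spot grid has exactly 25 (row, col) centres")
        object.__setattr__(self, "centers", centers)
        d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() <= 2 * self.sampling_radius:
            raise ValueError("spot centres must be separated by more than twice "
                             "the sampling radius")

    @classmethod
    def from_image(cls, image: ArrayImage, sampling_radius: float | None = None) -> "SpotGrid":
        if sampling_radius is None:
            side = image.pixels.shape[0]
            sampling_radius = 0.6 * image.metadata.get("spot_radius", default_spot_radius(side))
        return cls(centers=image.spot_centers, sampling_radius=float(sampling_radius))


@dataclass(frozen=True)
class CalibrationMap:
    """Per-channel affine colour correction fitted from the two patches."""

    gain: np.ndarray  # (3,)
    offset: np.ndarray  # (3,)
    reference_black: np.ndarray
    reference_white: np.ndarray

    def apply(self, image: ArrayImage) -> ArrayImage:
        px = image.pixels.astype(float) * self.gain[None, None, :] + self.offset[None, None, :]
        return ArrayImage(
            pixels=np.clip(np.rint(px), 0, 255).astype(np.uint8),
            spot_centers=image.spot_centers.copy(),
            white_patch_box=image.white_patch_box,
            black_patch_box=image.black_patch_box,
            metadata=dict(image.metadata, calibrated=True),
        )

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.gain, 1.0, atol=1e-6) and np.allclose(self.offset, 0.0, atol=1e-6)


def _patch_mean(image: ArrayImage, box: tuple[int, int, int, int]) -> np.ndarray:
    r0, c0, r1, c1 = box
    patch = image.pixels[r0:r1, c0:c1].astype(float)
    if patch.size == 0:
        raise ValueError("degenerate calibration patch box")
    return patch.reshape(-1, 3).mean(axis=0)


def fit_calibration(
    image: ArrayImage,
    reference_black=BLACK_REF,
    reference_white=WHITE_REF,
) -> CalibrationMap:
    """Fit the two-point per-channel affine map sending the measured patch
    means onto the reference black/white values.

    Raises a degenerate-lighting error when the white patch does not measure
    brighter than the black patch in every channel.
    """
    b_ref = np.asarray(reference_black, dtype=float)
    w_ref = np.asarray(reference_white, dtype=float)
    b_meas = _patch_mean(image, image.black_patch_box)
    w_meas = _patch_mean(image, image.white_patch_box)
    if np.any(w_meas <= b_meas):
        raise ValueError(
            f"degenerate lighting: white patch {w_meas} not brighter than black {b_meas} "
            "in every channel"
        )
    gain = (w_ref - b_ref) / (w_meas - b_meas)
    offset = b_ref - gain * b_meas
    return CalibrationMap(gain=gain, offset=offset,
                          reference_black=b_ref, reference_white=w_ref)


def extract_spot_rgb(image: ArrayImage, grid: SpotGrid | None = None) -> np.ndarray:
    """Mean RGB over a disk of ``sampling_radius`` at each centre, (25, 3)."""
    if grid is None:
        grid = SpotGrid.from_image(image)
    h, w = image.pixels.shape[:2]
    out = np.empty((25, 3))
    yy, xx = np.mgrid[0:h, 0:w]
    for i, (r, c) in enumerate(grid.centers):
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"spot centre {i} at ({r:.1f}, {c:.1f}) lies outside the raster")
        mask = (yy - r) ** 2 + (xx - c) ** 2 <= grid.sampling_radius**2
        if not mask.any():  # radius 0: fall back to the nearest pixel
            out[i] = image.pixels[int(round(r)), int(round(c))]
        else:
            out[i] = image.pixels[mask].reshape(-1, 3).mean(axis=0)
    return out


@dataclass(frozen=True)
class DeltaSignature:
    """Signed per-spot colour differences and their ED aggregates."""

    delta_rgb: np.ndarray  # (25, 3) signed counts
    ed_per_spot: np.ndarray = field(init=False)
    total_ed: float = field(init=False)
    total_mode: str = "sum"  # "sum" | "rss"

    def __post_init__(self) -> None:
        delta = np.asarray(self.delta_rgb, dtype=float)
        if delta.shape != (25, 3):
            raise ValueError("delta_rgb must have shape (25, 3)")
        if not np.isfinite(delta).all():
            raise ValueError("delta_rgb must be finite")
        ed = np.linalg.norm(delta, axis=1)
        object.__setattr__(self, "delta_rgb", delta)
        object.__setattr__(self, "ed_per_spot", ed)
        if self.total_mode == "sum":
            total = float(ed.sum())
        elif self.total_mode == "rss":
            total = float(np.sqrt((ed**2).sum()))
        else:
            raise ValueError(f"unknown total_mode {self.total_mode!r}")
        object.__setattr__(self, "total_ed", total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "spot_id": np.arange(25),
            "dR": self.delta_rgb[:, 0],
            "dG": self.delta_rgb[:, 1],
            "dB": self.delta_rgb[:, 2],
            "ED": self.ed_per_spot,
        })


def delta_signature(pre_rgb: np.ndarray, post_rgb: np.ndarray,
                    total_mode: str = "sum") -> DeltaSignature:
    """Signed differences post - pre for 25 spot colour triplets."""
    pre = np.asarray(pre_rgb, dtype=float)
    post = np.asarray(post_rgb, dtype=float)
    if pre.shape != (25, 3) or post.shape != (25, 3):
        raise ValueError("pre and post must both be (25, 3) RGB arrays")
    return DeltaSignature(delta_rgb=post - pre, total_mode=total_mode)


def signature_from_pair(
    pre: ArrayImage,
    post: ArrayImage,
    *,
    calibrate: bool = False,
    total_mode: str = "sum",
) -> DeltaSignature:
    """Extract the ED signature of a pre/post pair, optionally calibrating
    both images from their own patches first."""
    if calibrate:
        pre = fit_calibration(pre).apply(pre)
        post = fit_calibration(post).apply(post)
    pre_rgb = extract_spot_rgb(pre)
    post_rgb = extract_spot_rgb(post)
    return delta_signature(pre_rgb, post_rgb, total_mode=total_mode)


def render_differential_map(
    sig: DeltaSignature,
    in_range: tuple[float, float] = (3.0, 10.0),
    out_range: tuple[float, float] = (0.0, 255.0),
    tile: int = 24,
) -> np.ndarray:
    """5 x 5 tile raster of |Δ| linearly stretched from ``in_range`` onto
    ``out_range`` (values outside the input range clip to the endpoints)."""
    lo, hi = in_range
    if not lo < hi:
        raise ValueError("in_range lower bound must be below the upper bound")
    out_lo, out_hi = out_range
    mag = np.abs(sig.delta_rgb)
    scaled = out_lo + (mag - lo) * (out_hi - out_lo) / (hi - lo)
    tiles = np.clip(np.rint(scaled), min(out_lo, out_hi), max(out_lo, out_hi))
    tiles = tiles.reshape(5, 5, 3).astype(np.uint8)
    return np.kron(tiles, np.ones((tile, tile, 1), dtype=np.uint8))


def locate_grid(image: ArrayImage, sampling_radius: float | None = None,
                search: int = 6) -> SpotGrid:
    """Template-grid fit for images without centre metadata: translate the
    canonical 5 x 5 lattice to maximize mean colour saturation at the spots."""
    from .synth.render import grid_centers

    side = image.pixels.shape[0]
    base = grid_centers(side)
    px = image.pixels.astype(float)
    sat = px.max(axis=2) - px.min(axis=2)
    # candidates ordered by shift magnitude with strict improvement only,
    # so plateaus (shifts smaller than the spot radius) resolve to the
    # smallest displacement
    candidates = sorted(
        ((dr, dc) for dr in range(-search, search + 1) for dc in range(-search, search + 1)),
        key=lambda s: (s[0] ** 2 + s[1] ** 2, s),
    )
    best, best_shift = -np.inf, (0, 0)
    for dr, dc in candidates:
        pts = np.clip(np.rint(base + [dr, dc]).astype(int), 0, side - 1)
        score = sat[pts[:, 0], pts[:, 1]].sum()
        if score > best:
            best, best_shift = score, (dr, dc)
    if sampling_radius is None:
        sampling_radius = 0.6 * default_spot_radius(side)
    return SpotGrid(centers=base + np.asarray(best_shift, dtype=float),
                    sampling_radius=float(sampling_radius))
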