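"""Statistical layer over ED responses.

Covers the four analyses run on array ED data: dose-response summaries with
the blank + 3 sigma limit of detection, sensitive-dye ranking, min-max
reference-range ripeness classification, and Ward-linkage hierarchical
clustering of the VOC x concentration response matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .imaging import signature_from_pair
from .synth.doseresponse import BLANK_TOTAL_ED_MEAN, BLANK_TOTAL_ED_SD, ExposurePair


@dataclass
class DoseResponseSeries:
    """Replicate-averaged ED response of the array to one VOC.

    ``total_ed[i]`` and ``per_spot_ed[i]`` correspond to
    ``concentrations[i]``; ``lod_ppm`` is filled by :func:`estimate_lod`
    (None encodes "not reached").
    """

    voc_name: str
    concentrations: np.ndarray  # ascending, ppm
    total_ed: np.ndarray  # (n_conc,)
    per_spot_ed: np.ndarray  # (n_conc, 25)
    blank_mean: float = BLANK_TOTAL_ED_MEAN
    blank_sd: float = BLANK_TOTAL_ED_SD
    lod_ppm: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.total_ed = np.asarray(self.total_ed, dtype=float)
        self.per_spot_ed = np.asarray(self.per_spot_ed, dtype=float)
        n = len(self.concentrations)
        if not (len(self.total_ed) == n and self.per_spot_ed.shape == (n, 25)):
            raise ValueError("concentrations, total_ed and per_spot_ed lengths disagree")
        if self.blank_sd < 0:
            raise ValueError("blank_sd must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "voc": self.voc_name,
            "concentration_ppm": self.concentrations,
            "total_ed": self.total_ed,
        })


def series_from_pairs(
    pairs: Sequence[ExposurePair],
    *,
    blank_mean: float = BLANK_TOTAL_ED_MEAN,
    blank_sd: float = BLANK_TOTAL_ED_SD,
    calibrate: bool = False,
) -> DoseResponseSeries:
    """Build a replicate-averaged series from rendered exposure pairs."""
    if not pairs:
        raise ValueError("no exposure pairs")
    voc = pairs[0].voc
    by_conc: dict[float, list[ExposurePair]] = {}
    for p in pairs:
        by_conc.setdefault(p.concentration, []).append(p)
    concs = sorted(by_conc)
    totals, spots = [], []
    for c in concs:
        sigs = [signature_from_pair(p.pre, p.post, calibrate=calibrate) for p in by_conc[c]]
        totals.append(np.mean([s.total_ed for s in sigs]))
        spots.append(np.mean([s.ed_per_spot for s in sigs], axis=0))
    return DoseResponseSeries(
        voc_name=voc,
        concentrations=np.array(concs),
        total_ed=np.array(totals),
        per_spot_ed=np.array(spots),
        blank_mean=blank_mean,
        blank_sd=blank_sd,
    )


def estimate_lod(series: DoseResponseSeries, *, spot: int | None = None,
                 threshold: float | None = None) -> float | None:
    """Limit of detection: the smallest tested concentration whose total ED
    exceeds blank_mean + 3 * blank_sd; None when no concentration crosses.

    ``spot`` switches to a per-dye LOD on that spot's ED column, in which
    case an explicit ``threshold`` should be supplied (the stored blank
    statistics describe the 25-spot total).
    """
    c = series.concentrations
    if np.any(np.diff(c) < 0):
        raise ValueError("concentrations must be sorted ascending")
    if threshold is None:
        threshold = series.blank_mean + 3.0 * series.blank_sd
    response = series.total_ed if spot is None else series.per_spot_ed[:, spot]
    above = response > threshold
    lod = float(c[int(np.argmax(above))]) if above.any() else None
    if spot is None:
        series.lod_ppm = lod
    return lod


def rank_sensitive_dyes(series: DoseResponseSeries, k: int = 25) -> np.ndarray:
    """Dye ids ordered by per-spot ED at the highest tested concentration,
    descending (ties broken by smaller dye id)."""
    if k > 25:
        raise ValueError("k must be <= 25")
    peak = series.per_spot_ed[-1]
    order = np.lexsort((np.arange(25), -peak))
    return order[:k]


@dataclass(frozen=True)
class ReferenceRanges:
    """Per-class [lo, hi] intervals of total ED from calibration samples."""

    ranges: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for label, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"range for {label!r} has lo > hi")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(label, lo, hi) for label, (lo, hi) in self.ranges.items()],
            columns=["class_label", "ed_lo", "ed_hi"],
        )


def build_reference_ranges(labeled_eds: Mapping[str, Sequence[float]]) -> ReferenceRanges:
    """Min-max interval of the calibration samples of each class."""
    ranges = {}
    for label, samples in labeled_eds.items():
        vals = np.asarray(list(samples), dtype=float)
        if vals.size == 0:
            raise ValueError(f"class {label!r} has no calibration samples")
        ranges[label] = (float(vals.min()), float(vals.max()))
    return ReferenceRanges(ranges=ranges)


@dataclass(frozen=True)
class EDClassification:
    label: str | None
    status: str  # "unique" | "ambiguous" | "out_of_range"


def classify_by_ed(total_ed: float, ranges: ReferenceRanges) -> EDClassification:
    """Assign the class whose reference interval contains ``total_ed``.

    When several intervals contain the value the narrowest wins and the
    result is flagged ambiguous; when none does the status is out_of_range.
    """
    hits = [(hi - lo, label) for label, (lo, hi) in ranges.ranges.items()
            if lo <= total_ed <= hi]
    if not hits:
        return EDClassification(label=None, status="out_of_range")
    if len(hits) == 1:
        return EDClassification(label=hits[0][1], status="unique")
    hits.sort(key=lambda t: (t[0], t[1]))
    return EDClassification(label=hits[0][1], status="ambiguous")


@dataclass(frozen=True)
class LinkageResult:
    """Agglomerative merge tree in SciPy's flat (n-1, 4) linkage layout."""

    merges: np.ndarray
    labels: tuple
    method: str = "ward"

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.merges.shape != (n - 1, 4):
            raise ValueError("a merge tree over n samples has n - 1 merges")

    def cut(self, k: int) -> np.ndarray:
        return hierarchy.fcluster(self.merges, t=k, criterion="maxclust")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges, columns=["left", "right", "height", "size"])


def hca_ward(matrix: np.ndarray, labels: Sequence | None = None) -> LinkageResult:
    """Ward minimum-variance agglomeration of row vectors under Euclidean
    distance (the clustering applied to the 27 x 25 VOC response matrix)."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    if not np.isfinite(X).all():
        raise ValueError("response matrix contains non-finite entries")
    if labels is None:
        labels = tuple(range(X.shape[0]))
    if len(labels) != X.shape[0]:
        raise ValueError("one label per row required")
    Z = hierarchy.ward(X)
    return LinkageResult(merges=Z, labels=tuple(labels))


def cluster_success_rate(linkage: LinkageResult, true_labels: Sequence, k: int) -> float:
    """Cut into k clusters; success = fraction of samples whose cluster's
    majority label matches their own (singleton clusters are always pure)."""
    true = np.asarray(true_labels)
    if len(true) != len(linkage.labels):
        raise ValueError("one true label per clustered sample required")
    if k > len(true):
        raise ValueError("cannot cut into more clusters than samples")
    assign = linkage.cut(k)
    correct = 0
    for cluster in np.unique(assign):
        members = true[assign == cluster]
        values, counts = np.unique(members, return_counts=True)
        majority = values[np.argmax(counts)]
        correct += int((members == majority).sum())
    return correct / len(true)


def make_voc_condition_matrix(
    seed: int,
    *,
    n_vocs: int = 9,
    n_concentrations: int = 3,
    n_replicates: int = 3,
    separation_ratio: float = 10.0,
    base_ed: float = 30.0,
    pattern_scale: float = 250.0,
) -> dict:
    """Synthetic per-dye ED responses for the VOC x concentration panel.

    Each VOC gets a random non-negative 25-dye response pattern; each
    concentration scales it (0.8x, 1.0x, 1.2x, ...), a spread kept narrow
    enough that VOC identity dominates the between-condition geometry while
    concentrations remain distinct conditions.  Within-condition
    replicate noise sd is set to the minimum between-condition mean
    separation divided by ``separation_ratio``, so the conditions are
    separated by at least that factor.

    Returns a dict with the replicate matrix (conditions x replicates rows),
    the replicate-averaged condition matrix, and condition/VOC labels.
    """
    rng = np.random.default_rng(seed)
    factors = 1.0 + 0.2 * (np.arange(n_concentrations) - (n_concentrations - 1) / 2.0)
    patterns = rng.uniform(0.0, 1.0, size=(n_vocs, 25))
    means, cond_labels, voc_labels = [], [], []
    for v in range(n_vocs):
        for f in factors:
            means.append(base_ed + pattern_scale * patterns[v] * f)
            cond_labels.append(f"voc{v}_c{f:.1f}")
            voc_labels.append(f"voc{v}")
    means = np.array(means)
    d = np.linalg.norm(means[:, None, :] - means[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    noise_sd = d.min() / separation_ratio / np.sqrt(25)
    n_cond = len(means)
    reps = means[:, None, :] + rng.normal(0.0, noise_sd, size=(n_cond, n_replicates, 25))
    reps = np.clip(reps, 0.0, None)
    return {
        "replicates": reps.reshape(n_cond * n_replicates, 25),
        "replicate_labels": np.repeat(cond_labels, n_replicates),
        "averaged": reps.mean(axis=1),
        "condition_labels": np.array(cond_labels),
        "voc_labels": np.array(voc_labels),
        "noise_sd": float(noise_sd),
    }
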