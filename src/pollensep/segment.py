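"""Pollen-region segmentation: mean shift on (a*, b*) followed by Otsu.

Every pixel is described by its chromaticity vector ``x_i = [a, b]`` only
(lightness is deliberately excluded: the stain signature is chromatic).
Mean shift with a flat kernel of bandwidth ``h`` collapses the image to a
handful of color modes — chosen so the scene reduces to two or three
regions — after which Otsu's threshold on the mode image's a* values
yields a single pollen/background split. The purple stain sits at high a*,
so the foreground is the side of the cut with the larger mean a*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "ModeMap",
    "Region",
    "mean_shift_modes",
    "otsu_threshold",
    "binarize_pollen",
    "extract_regions",
]


@dataclass
class ModeMap:
    """Per-pixel cluster labels and the (a, b) mode of each cluster."""

    labels: np.ndarray          # H×W int, values in [0, len(modes))
    modes: np.ndarray           # M×2 float, (a, b) per cluster

    @property
    def n_modes(self) -> int:
        return len(self.modes)


@dataclass
class Region:
    """One 8-connected foreground component."""

    mask: np.ndarray            # H×W bool (full-frame)
    bbox: tuple[int, int, int, int]   # (row_min, col_min, row_max, col_max), half-open
    area: int


def mean_shift_modes(
    lab: np.ndarray,
    bandwidth: float = 25.0,
    tol: float = 0.1,
    max_iter: int = 100,
    bin_width: float = 0.5,
) -> ModeMap:
    """Cluster pixels by flat-kernel mean shift on the (a*, b*) plane.

    Each feature point iterates to the mean of all points (weighted by
    pixel multiplicity) within ``bandwidth`` until it moves less than
    ``tol``. Converged modes closer than ``bandwidth / 2`` are merged,
    largest-mass first. Pixels whose quantized (a, b) coincide (bins of
    ``bin_width`` Lab units) share one trajectory; exact colors collide
    heavily in practice so this changes nothing observable.

    Parameters
    ----------
    lab : H×W×3 float array
        CIELAB image; only channels 1 and 2 are used.
    bandwidth : float
        Kernel radius ``h`` in native a/b units. The working default of 25
        makes a stained grain plus its surround resolve into two or three
        color regions.
    """
    lab = np.asarray(lab, dtype=np.float64)
    if lab.ndim != 3 or lab.shape[2] != 3 or lab[..., 0].size == 0:
        raise ValueError("expected non-empty H×W×3 Lab image")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")

    ab = lab[..., 1:3].reshape(-1, 2)
    # quantize to shared trajectories
    q = np.round(ab / bin_width).astype(np.int64)
    uniq, inverse, counts = np.unique(q, axis=0, return_inverse=True, return_counts=True)
    points = uniq.astype(np.float64) * bin_width
    weights = counts.astype(np.float64)

    tree = cKDTree(points)
    traj = points.copy()
    active = np.ones(len(points), dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        idx_active = np.flatnonzero(active)
        neigh = tree.query_ball_point(traj[idx_active], r=bandwidth)
        for row, nbrs in zip(idx_active, neigh):
            w = weights[nbrs]
            new = (points[nbrs] * w[:, None]).sum(axis=0) / w.sum()
            if np.hypot(*(new - traj[row])) < tol:
                active[row] = False
            traj[row] = new

    # merge modes closer than bandwidth/2, heaviest mass first
    merge_r = bandwidth / 2.0
    order = np.argsort(-weights)
    mode_list: list[np.ndarray] = []
    mode_mass: list[float] = []
    assign = np.empty(len(points), dtype=np.int64)
    for i in order:
        placed = False
        for m, center in enumerate(mode_list):
            if np.hypot(*(traj[i] - center)) < merge_r:
                assign[i] = m
                mode_mass[m] += weights[i]
                placed = True
                break
        if not placed:
            assign[i] = len(mode_list)
            mode_list.append(traj[i])
            mode_mass.append(weights[i])

    modes = np.asarray(mode_list)
    labels = assign[inverse].reshape(lab.shape[:2])
    return ModeMap(labels=labels, modes=modes)


def otsu_threshold(hist: np.ndarray) -> int:
    """Otsu cut index for a 1-D histogram.

    Returns the bin index ``t`` maximizing the between-class variance of
    the split ``bins <= t`` versus ``bins > t`` (lowest index on ties).
    """
    hist = np.asarray(hist, dtype=np.float64)
    n = hist.sum()
    if n <= 0:
        raise ValueError("empty histogram")
    bins = np.arange(len(hist))
    w0 = np.cumsum(hist)[:-1]
    w1 = n - w0
    cum_mean = np.cumsum(hist * bins)[:-1]
    total_mean = (hist * bins).sum()
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(valid, cum_mean / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(valid, (total_mean - cum_mean) / np.where(w1 > 0, w1, 1), 0.0)
    between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    return int(np.argmax(between))


def binarize_pollen(lab: np.ndarray, modemap: ModeMap, n_bins: int = 256) -> np.ndarray:
    """Threshold the mode image into a solid pollen mask.

    The mode-value image (each pixel replaced by its mode's a* coordinate)
    is histogrammed into ``n_bins`` equal-width bins and cut by Otsu's
    threshold; the foreground is the side with the higher mean a*
    (the stain), and interior holes are filled so regions are solid for
    the erosion stage.

    Raises
    ------
    ValueError
        If the mode map contains a single mode — nothing to threshold.
    """
    if modemap.n_modes < 2:
        raise ValueError("nothing to threshold: mode map has a single mode")
    mode_a = modemap.modes[:, 0][modemap.labels]
    lo, hi = float(mode_a.min()), float(mode_a.max())
    hist, edges = np.histogram(mode_a, bins=n_bins, range=(lo, hi))
    t = otsu_threshold(hist)
    cut = edges[t + 1]
    high = mode_a > cut
    # foreground is the high-a side by construction; guard the degenerate flip
    if high.any() and (~high).any():
        if mode_a[high].mean() < mode_a[~high].mean():
            high = ~high
    filled = ndimage.binary_fill_holes(high)
    return filled


def extract_regions(mask: np.ndarray, min_region_area: int = 150) -> list[Region]:
    """Split a binary mask into 8-connected components of sufficient area.

    Components smaller than ``min_region_area`` (debris, specks) are
    dropped; the survivors come back sorted by decreasing area.
    """
    mask = np.asarray(mask, dtype=bool)
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    regions: list[Region] = []
    for sl, lab_id in zip(ndimage.find_objects(labeled), range(1, n + 1)):
        comp = labeled == lab_id
        area = int(comp.sum())
        if area < min_region_area:
            continue
        regions.append(
            Region(
                mask=comp,
                bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
                area=area,
            )
        )
    regions.sort(key=lambda r: -r.area)
    return regions
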