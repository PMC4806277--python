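"""Per-grain shape, first-order and co-occurrence texture descriptors.

Each separated grain is summarized by 33 numbers:

* 6 shape descriptors from its binary mask — bounding-box length ``MA``
  and width ``mA``, area ``A``, perimeter ``P``, roundness
  ``R = 4·π·A / P²`` (1 for an ideal circle) and compactness
  ``C = A / P²`` — so ``C = R / (4π)`` identically;
* 5 first-order statistics (mean, median, population variance, standard
  deviation, histogram entropy in bits) of each of the three Lab channels
  inside the mask — 15 values;
* 4 Haralick statistics (contrast, correlation, energy, local
  homogeneity) of a symmetric, offset-averaged gray-level co-occurrence
  matrix per Lab channel — 12 values.

The perimeter is the length of the polygon through the ordered border
pixel centers (Moore-neighbor trace), i.e. Σ√((xᵢ−xᵢ₋₁)² + (yᵢ−yᵢ₋₁)²)
around the closed border: a 10×10 solid square has P = 36.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ShapeFeatures",
    "FirstOrderFeatures",
    "GLCMFeatures",
    "GrainFeatures",
    "FEATURE_NAMES",
    "CHANNEL_RANGES",
    "trace_boundary",
    "shape_features",
    "first_order_features",
    "glcm",
    "glcm_features",
    "feature_vector",
]

# native value ranges of the Lab planes, used for histogram/GLCM binning
CHANNEL_RANGES: dict[str, tuple[float, float]] = {
    "L": (0.0, 100.0),
    "a": (-128.0, 127.0),
    "b": (-128.0, 127.0),
}

_CHANNELS = ("L", "a", "b")

FEATURE_NAMES: list[str] = (
    ["MA", "mA", "A", "P", "R", "C"]
    + [f"{stat}_{ch}" for ch in _CHANNELS for stat in ("mu", "m", "var", "sd", "S")]
    + [f"{stat}_{ch}" for ch in _CHANNELS for stat in ("CM", "r", "e", "HL")]
)
assert len(FEATURE_NAMES) == 33


@dataclass
class ShapeFeatures:
    MA: float   # bounding-box length (longer side), px
    mA: float   # bounding-box width (shorter side), px
    A: float    # area, px
    P: float    # traced-border perimeter, px
    R: float    # roundness 4πA/P²
    C: float    # compactness A/P²

    def as_array(self) -> np.ndarray:
        return np.array([self.MA, self.mA, self.A, self.P, self.R, self.C])


@dataclass
class FirstOrderFeatures:
    mu: float
    m: float
    var: float
    sd: float
    S: float    # entropy, bits

    def as_array(self) -> np.ndarray:
        return np.array([self.mu, self.m, self.var, self.sd, self.S])


@dataclass
class GLCMFeatures:
    CM: float   # contrast
    r: float    # correlation
    e: float    # energy
    HL: float   # local homogeneity

    def as_array(self) -> np.ndarray:
        return np.array([self.CM, self.r, self.e, self.HL])


@dataclass
class GrainFeatures:
    shape: ShapeFeatures
    first_order: dict[str, FirstOrderFeatures]   # keyed L, a, b
    glcm: dict[str, GLCMFeatures]                # keyed L, a, b
    label: int | None = None

    def as_array(self) -> np.ndarray:
        parts = [self.shape.as_array()]
        parts += [self.first_order[ch].as_array() for ch in _CHANNELS]
        parts += [self.glcm[ch].as_array() for ch in _CHANNELS]
        vec = np.concatenate(parts)
        assert vec.shape == (33,)
        return vec


# Moore neighborhood in clockwise order starting east
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered border pixel centers of a single-component mask.

    Moore-neighbor tracing with Jacob's stopping criterion; returns an
    (N, 2) array of (row, col). A single-pixel mask returns that pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask")
    # start at the top-most, then left-most foreground pixel
    start = (int(rows.min()), int(cols[rows == rows.min()].min()))
    if rows.size == 1:
        return np.array([start])

    H, W = mask.shape

    def fg(p: tuple[int, int]) -> bool:
        return 0 <= p[0] < H and 0 <= p[1] < W and mask[p]

    boundary = [start]
    current = start
    # the pixel north of the topmost-leftmost start is background, so the
    # clockwise scan begins at its successor (NE)
    search_from = 7
    while True:
        nxt = None
        for k in range(8):
            d = (search_from + k) % 8
            cand = (current[0] + _MOORE[d][0], current[1] + _MOORE[d][1])
            if fg(cand):
                nxt = (cand, d)
                break
        if nxt is None:
            return np.asarray(boundary)  # isolated pixel
        current, d = nxt
        if current == start:
            return np.asarray(boundary)
        boundary.append(current)
        search_from = ((d + 4) % 8 + 1) % 8  # resume after the backtrack
        if len(boundary) > 4 * mask.size:
            raise RuntimeError("boundary trace failed to terminate")


def _perimeter(border: np.ndarray) -> float:
    if len(border) < 2:
        return 1.0  # degenerate single-pixel grain
    closed = np.vstack([border, border[:1]]).astype(float)
    return float(np.hypot(*np.diff(closed, axis=0).T).sum())


def shape_features(mask: np.ndarray) -> ShapeFeatures:
    """Shape descriptors of a single 8-connected grain mask."""
    mask = np.asarray(mask, dtype=bool)
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise ValueError("empty mask")
    if n > 1:
        raise ValueError(f"mask has {n} components; expected exactly 1")
    rows, cols = np.nonzero(mask)
    height = float(rows.max() - rows.min() + 1)
    width = float(cols.max() - cols.min() + 1)
    MA, mA = max(height, width), min(height, width)
    A = float(mask.sum())
    P = _perimeter(trace_boundary(mask))
    R = 4.0 * np.pi * A / P**2
    C = A / P**2
    return ShapeFeatures(MA=MA, mA=mA, A=A, P=P, R=R, C=C)


def first_order_features(
    values: np.ndarray,
    n_bins: int = 256,
    value_range: tuple[float, float] | None = None,
) -> FirstOrderFeatures:
    """First-order statistics of the intensity sample inside a grain.

    Variance uses the population divisor N; entropy is −Σ p·log₂p over an
    ``n_bins`` histogram of ``value_range`` (the sample's own range when
    not given, as for a channel's native scale in :func:`feature_vector`).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("no values")
    mu = float(values.mean())
    m = float(np.median(values))
    var = float(values.var())  # population (divisor N)
    sd = float(np.sqrt(var))
    if value_range is None:
        value_range = (float(values.min()), float(values.max()))
    lo, hi = value_range
    if hi <= lo:
        hi = lo + 1.0
    hist, _ = np.histogram(values, bins=n_bins, range=(lo, hi))
    p = hist[hist > 0] / values.size
    S = float(-(p * np.log2(p)).sum())
    return FirstOrderFeatures(mu=mu, m=m, var=var, sd=sd, S=S)


def glcm(
    channel: np.ndarray,
    mask: np.ndarray,
    levels: int = 32,
    distance: int = 1,
    value_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Masked, symmetric, offset-averaged co-occurrence matrix.

    The channel is quantized to ``levels`` equal-width bins over
    ``value_range`` (native channel range in the pipeline). Pairs at the
    four offsets 0°, 45°, 90° and 135° at the given distance — both
    pixels inside the mask — are accumulated, symmetrized, averaged over
    offsets, and normalized to sum 1.
    """
    channel = np.asarray(channel, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if channel.shape != mask.shape:
        raise ValueError("channel and mask shapes differ")
    if mask.sum() < 2:
        raise ValueError("region too small for any co-occurring pair")
    if value_range is None:
        vals = channel[mask]
        value_range = (float(vals.min()), float(vals.max()))
    lo, hi = value_range
    span = hi - lo if hi > lo else 1.0
    quant = np.clip(((channel - lo) / span * levels).astype(np.int64), 0, levels - 1)

    d = distance
    offsets = [(0, d), (-d, d), (-d, 0), (-d, -d)]  # 0°, 45°, 90°, 135°
    acc = np.zeros((levels, levels), dtype=np.float64)
    total_pairs = 0
    H, W = mask.shape
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(H, H - dr)
        c0, c1 = max(0, -dc), min(W, W - dc)
        m1 = mask[r0:r1, c0:c1]
        m2 = mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        valid = m1 & m2
        i = quant[r0:r1, c0:c1][valid]
        j = quant[r0 + dr:r1 + dr, c0 + dc:c1 + dc][valid]
        co = np.zeros((levels, levels), dtype=np.float64)
        np.add.at(co, (i, j), 1.0)
        acc += co + co.T  # symmetric
        total_pairs += 2 * i.size
    if total_pairs == 0:
        raise ValueError("region too small for any co-occurring pair")
    return acc / acc.sum()


def glcm_features(c: np.ndarray) -> GLCMFeatures:
    """Contrast, correlation, energy and local homogeneity of a
    normalized co-occurrence matrix (correlation is 0 when either
    marginal deviation vanishes)."""
    c = np.asarray(c, dtype=np.float64)
    L = c.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    CM = float(((i - j) ** 2 * c).sum())
    pi = c.sum(axis=1)
    pj = c.sum(axis=0)
    mu_i = float((np.arange(L) * pi).sum())
    mu_j = float((np.arange(L) * pj).sum())
    sd_i = float(np.sqrt(((np.arange(L) - mu_i) ** 2 * pi).sum()))
    sd_j = float(np.sqrt(((np.arange(L) - mu_j) ** 2 * pj).sum()))
    if sd_i * sd_j > 0:
        r = float((((i - mu_i) * (j - mu_j) * c).sum()) / (sd_i * sd_j))
    else:
        r = 0.0
    e = float((c**2).sum())
    HL = float((c / (1.0 + np.abs(i - j))).sum())
    return GLCMFeatures(CM=CM, r=r, e=e, HL=HL)


def feature_vector(
    grain_mask: np.ndarray,
    lab: np.ndarray,
    n_bins: int = 256,
    glcm_levels: int = 32,
    glcm_distance: int = 1,
    label: int | None = None,
) -> GrainFeatures:
    """The full 33-value descriptor of one grain on a Lab image."""
    grain_mask = np.asarray(grain_mask, dtype=bool)
    lab = np.asarray(lab, dtype=np.float64)
    if grain_mask.shape != lab.shape[:2]:
        raise ValueError("mask and image shapes differ")
    shape = shape_features(grain_mask)
    first_order: dict[str, FirstOrderFeatures] = {}
    texture: dict[str, GLCMFeatures] = {}
    for k, ch in enumerate(_CHANNELS):
        plane = lab[..., k]
        rng = CHANNEL_RANGES[ch]
        first_order[ch] = first_order_features(
            plane[grain_mask], n_bins=n_bins, value_range=rng
        )
        c = glcm(plane, grain_mask, levels=glcm_levels, distance=glcm_distance,
                 value_range=rng)
        texture[ch] = glcm_features(c)
    return GrainFeatures(shape=shape, first_order=first_order, glcm=texture,
                         label=label)
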