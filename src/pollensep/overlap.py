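"""Detection and separation of overlapping pollen grains.

A segmented pollen region is either a single grain (Case I) or a clump of
overlapping grains (Case II). The discriminator is a morphological erosion
schedule whose disk radii follow the Fibonacci numbers: eroding the region
at successively larger radii, a single convex-ish grain stays one object
until it vanishes, whereas a clump pinches apart at its necks and the
object count near the end of the schedule exceeds the count at the start.
For Case II regions the eroded fragments just after the split are grown
back by simultaneous unit dilations (stopping before any two would touch)
into per-grain seeds, and each seed drives a gradient-vector-flow (GVF)
active contour toward the region boundary. The final contours partition
the region into one mask per grain.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.draw import polygon as draw_polygon
from skimage.morphology import disk as disk_footprint

__all__ = [
    "RegionCase",
    "ErosionProfile",
    "GVFField",
    "SnakeCollapseError",
    "fibonacci_schedule",
    "erode_disk",
    "erosion_profile",
    "classify_case",
    "extract_seeds",
    "gvf_field",
    "evolve_snake",
    "separate_region",
    "split_region",
]

_STRUCT8 = np.ones((3, 3), dtype=int)


class RegionCase(Enum):
    CASE_I = "CASE_I"     # isolated grain(s): object count preserved under erosion
    CASE_II = "CASE_II"   # overlapping grains: count changes near the end


@dataclass
class ErosionProfile:
    """Object counts along the erosion schedule for one region."""

    steps: list[tuple[int, int]]   # (disk radius px, object count)
    initial_count: int             # count at radius 0
    final_count: int               # count at the last radius with >= 1 object


@dataclass
class GVFField:
    """Diffused edge-force field (x-component u, y-component v)."""

    u: np.ndarray
    v: np.ndarray
    mu: float
    iterations: int


class SnakeCollapseError(RuntimeError):
    pass


def fibonacci_schedule(n_terms: int = 21) -> np.ndarray:
    """Disk radii for the erosion schedule: the Fibonacci numbers 0, 1, 1,
    2, 3, ... (21 terms end at 6765)."""
    if n_terms < 2:
        raise ValueError("n_terms must be >= 2")
    radii = [0, 1]
    while len(radii) < n_terms:
        radii.append(radii[-1] + radii[-2])
    return np.asarray(radii[:n_terms], dtype=np.int64)


def erode_disk(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary erosion by the Euclidean disk {‖o‖ <= radius}.

    A pixel survives iff every pixel within ``radius`` of it (including
    out-of-frame positions, treated as background) is foreground, which is
    exactly {distance-to-background > radius}; one distance transform
    serves every radius.
    """
    mask = np.asarray(mask, dtype=bool)
    if radius <= 0:
        return mask.copy()
    padded = np.pad(mask, 1, constant_values=False)
    edt = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    return edt > radius


def _count_objects(mask: np.ndarray, min_object_area: int) -> tuple[int, np.ndarray]:
    labeled, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return 0, labeled
    areas = np.bincount(labeled.ravel())[1:]
    keep = np.flatnonzero(areas >= min_object_area) + 1
    relabeled = np.where(np.isin(labeled, keep), labeled, 0)
    return len(keep), relabeled


def erosion_profile(
    region: np.ndarray,
    schedule: np.ndarray | None = None,
    min_object_area: int = 8,
) -> ErosionProfile:
    """Count surviving objects after erosion at every schedule radius.

    Each radius erodes the *original* region mask (not the previous step's
    output — the results coincide for disks, the contract is simpler), and
    8-connected components of at least ``min_object_area`` pixels are
    counted. Once the mask empties, later steps are recorded as zero
    without being computed; radii beyond the frame can never contribute.
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("empty region")
    if schedule is None:
        schedule = fibonacci_schedule()

    padded = np.pad(region, 1, constant_values=False)
    edt = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]

    steps: list[tuple[int, int]] = []
    empty = False
    for radius in np.asarray(schedule, dtype=np.int64):
        if empty:
            steps.append((int(radius), 0))
            continue
        eroded = edt > radius if radius > 0 else region
        count, _ = _count_objects(eroded, min_object_area)
        steps.append((int(radius), count))
        if not eroded.any():
            empty = True

    counts = [c for _, c in steps]
    nonzero = [c for c in counts if c > 0]
    initial = counts[0]
    final = nonzero[-1] if nonzero else 0
    return ErosionProfile(steps=steps, initial_count=initial, final_count=final)


def classify_case(profile: ErosionProfile) -> RegionCase:
    """Case II iff the final object count differs from the initial one."""
    if profile.final_count != profile.initial_count:
        return RegionCase.CASE_II
    return RegionCase.CASE_I


def extract_seeds(
    region: np.ndarray,
    profile: ErosionProfile,
    schedule: np.ndarray | None = None,
    min_object_area: int = 8,
    max_steps: int = 10_000,
) -> list[np.ndarray]:
    """Grow per-grain seeds back from the split eroded fragments.

    Starting from the eroded fragments at the smallest radius whose object
    count equals the profile's final count, all fragments are dilated
    simultaneously with unit-radius disks, clipped to the region mask, and
    growth stops one step before any two fragments would become
    8-connected. The returned seeds are pairwise disjoint subsets of the
    region and initialize the active contours.
    """
    region = np.asarray(region, dtype=bool)
    if classify_case(profile) is RegionCase.CASE_I:
        raise ValueError("extract_seeds requires a Case II profile")

    if schedule is None:
        schedule = np.asarray([r for r, _ in profile.steps], dtype=np.int64)

    target = profile.final_count
    split_radius = None
    for radius, count in profile.steps:
        if count == target:
            split_radius = radius
            break
    if split_radius is None:  # cannot happen for a valid profile
        raise ValueError("profile never reaches its final count")

    eroded = erode_disk(region, int(split_radius))
    _, labeled = _count_objects(eroded, min_object_area)
    seed_ids = np.unique(labeled)
    seed_ids = seed_ids[seed_ids > 0]
    seeds = [labeled == sid for sid in seed_ids]

    unit = disk_footprint(1).astype(bool)
    for _ in range(max_steps):
        grown = [
            ndimage.binary_dilation(s, structure=unit) & region for s in seeds
        ]
        # stop one step before any two fragments become 8-connected
        occupancy = np.zeros(region.shape, dtype=np.int32)
        for g in grown:
            occupancy += g
        if (occupancy > 1).any():
            break
        union, n = ndimage.label(np.logical_or.reduce(grown), structure=_STRUCT8)
        if n < len(grown):
            break
        if all((g == s).all() for g, s in zip(grown, seeds)):
            break  # region exhausted
        seeds = grown
    return seeds


def gvf_field(
    region: np.ndarray,
    mu: float = 0.2,
    n_iter: int = 80,
    sigma: float = 1.5,
) -> GVFField:
    """Gradient vector flow of the region's Gaussian edge map.

    The edge map is f = |∇(G_sigma ∗ mask)|², normalized to [0, 1]; the
    field (u, v) starts at ∇f and relaxes under
    u ← u + Δt·[mu·∇²u − (u − f_x)(f_x² + f_y²)] (likewise v), which
    diffuses boundary forces into the flat interior so a distant contour
    is still pulled toward the edge. Δt respects the explicit-scheme
    stability bound Δt ≤ 1/(4·mu).
    """
    if not (np.isfinite(mu) and np.isfinite(n_iter) and np.isfinite(sigma)):
        raise ValueError("non-finite GVF parameters")
    if mu < 0 or n_iter < 1 or sigma <= 0:
        raise ValueError("require mu >= 0, n_iter >= 1, sigma > 0")
    mask = np.asarray(region, dtype=np.float64)
    smooth = ndimage.gaussian_filter(mask, sigma=sigma)
    gy, gx = np.gradient(smooth)
    f = gx**2 + gy**2
    fmax = f.max()
    if fmax > 0:
        f = f / fmax
    fy, fx = np.gradient(f)
    b = fx**2 + fy**2
    u = fx.copy()
    v = fy.copy()
    dt = 1.0 if mu == 0 else min(1.0, 1.0 / (4.0 * mu))
    for _ in range(int(n_iter)):
        if mu > 0:
            u = u + dt * (mu * ndimage.laplace(u) - (u - fx) * b)
            v = v + dt * (mu * ndimage.laplace(v) - (v - fy) * b)
        else:
            u = u - dt * (u - fx) * b
            v = v - dt * (v - fy) * b
    return GVFField(u=u, v=v, mu=float(mu), iterations=int(n_iter))


def _boundary_contour(mask: np.ndarray) -> np.ndarray:
    """Longest 0.5-level contour of a mask, as (x, y) columns."""
    padded = np.pad(mask.astype(np.float64), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("mask has no boundary contour")
    longest = max(contours, key=len)
    rc = longest - 1.0  # undo padding offset
    return np.column_stack([rc[:, 1], rc[:, 0]])  # (x=col, y=row)


def _resample_closed(points: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed polyline to n_points at uniform arc length."""
    pts = np.asarray(points, dtype=np.float64)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return np.repeat(pts[:1], n_points, axis=0)
    t = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(t, s, closed[:, 0])
    y = np.interp(t, s, closed[:, 1])
    return np.column_stack([x, y])


def _internal_matrix(n: int, alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Inverse of (I + gamma·A) for the circulant internal-energy matrix."""
    a2 = beta
    a1 = -alpha - 4.0 * beta
    a0 = 2.0 * alpha + 6.0 * beta
    A = np.zeros((n, n))
    idx = np.arange(n)
    A[idx, idx] = a0
    A[idx, (idx + 1) % n] = a1
    A[idx, (idx - 1) % n] = a1
    A[idx, (idx + 2) % n] = a2
    A[idx, (idx - 2) % n] = a2
    return np.linalg.inv(np.eye(n) + gamma * A)


def _polygon_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def evolve_snake(
    seed: np.ndarray,
    field: GVFField,
    alpha: float = 0.1,
    beta: float = 0.05,
    gamma: float = 1.0,
    kappa: float = 0.6,
    n_iter: int = 100,
    n_points: int = 64,
) -> np.ndarray:
    """Evolve a closed active contour from a seed under the GVF field.

    The contour starts as the seed's boundary polygon resampled to
    ``n_points`` at uniform arc length and follows the standard
    semi-implicit update: internal tension ``alpha`` and rigidity ``beta``
    are folded into a precomputed circulant solve, the external force is
    ``kappa``·(u, v) sampled bilinearly at the contour points, and the
    contour is re-resampled every 10 iterations to keep points evenly
    spread. Returns the final contour as an (n_points, 2) array of (x, y);
    the polygon is closed implicitly (last point neighbors the first).

    Raises
    ------
    SnakeCollapseError
        If the enclosed area falls below 10 px².
    """
    seed = np.asarray(seed, dtype=bool)
    if not seed.any():
        raise ValueError("empty seed")
    if field.u.shape != field.v.shape:
        raise ValueError("field component shapes differ")

    contour = _resample_closed(_boundary_contour(seed), n_points)
    inv = _internal_matrix(n_points, alpha, beta, gamma)
    H, W = field.u.shape

    def sample(comp: np.ndarray, pts: np.ndarray) -> np.ndarray:
        coords = np.vstack([np.clip(pts[:, 1], 0, H - 1), np.clip(pts[:, 0], 0, W - 1)])
        return ndimage.map_coordinates(comp, coords, order=1, mode="nearest")

    for it in range(int(n_iter)):
        fx = sample(field.u, contour)
        fy = sample(field.v, contour)
        ext = kappa * np.column_stack([fx, fy])
        contour = inv @ (contour + gamma * ext)
        if (it + 1) % 10 == 0:
            contour = _resample_closed(contour, n_points)
            if _polygon_area(contour) < 10.0:
                raise SnakeCollapseError("snake collapsed (area < 10 px)")
    contour = _resample_closed(contour, n_points)
    if _polygon_area(contour) < 10.0:
        raise SnakeCollapseError("snake collapsed (area < 10 px)")
    return contour


def _contour_interior(contour: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = draw_polygon(contour[:, 1], contour[:, 0], shape=shape)
    interior = np.zeros(shape, dtype=bool)
    interior[rr, cc] = True
    return interior


def separate_region(
    region: np.ndarray, contours: list[np.ndarray]
) -> list[np.ndarray]:
    """Partition a region's pixels among the final snake contours.

    Pixels inside exactly one contour go to that grain; contested pixels
    (inside several contours) and orphans (inside none) go to the contour
    with the nearest centroid. The outputs are disjoint and their union is
    exactly the region.
    """
    region = np.asarray(region, dtype=bool)
    if len(contours) < 2:
        raise ValueError("separate_region requires at least 2 contours")
    shape = region.shape
    interiors = [_contour_interior(c, shape) for c in contours]
    centroids = np.asarray([c.mean(axis=0) for c in contours])  # (x, y)

    count = np.zeros(shape, dtype=np.int32)
    for interior in interiors:
        count += interior

    masks = [np.zeros(shape, dtype=bool) for _ in contours]
    sole = count == 1
    for i, interior in enumerate(interiors):
        masks[i] |= interior & sole & region

    ambiguous = region & ~sole
    if ambiguous.any():
        rows, cols = np.nonzero(ambiguous)
        pts = np.column_stack([cols, rows]).astype(np.float64)  # (x, y)
        d2 = ((pts[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        nearest = np.argmin(d2, axis=1)
        for i in range(len(contours)):
            sel = nearest == i
            masks[i][rows[sel], cols[sel]] = True
    return masks


def split_region(
    region: np.ndarray,
    schedule: np.ndarray | None = None,
    min_object_area: int = 8,
    mu: float = 0.2,
    gvf_iter: int = 80,
    sigma: float = 1.5,
    alpha: float = 0.1,
    beta: float = 0.05,
    gamma: float = 1.0,
    kappa: float = 0.6,
    snake_iter: int = 100,
    n_points: int = 64,
) -> tuple[RegionCase, list[np.ndarray], ErosionProfile]:
    """Run the full Case decision and (if needed) separation for one region.

    Returns the region case, one mask per recovered grain (the region
    itself for Case I), and the erosion profile that drove the decision.
    """
    region = np.asarray(region, dtype=bool)
    if schedule is None:
        schedule = fibonacci_schedule()
    profile = erosion_profile(region, schedule, min_object_area)
    case = classify_case(profile)
    if case is RegionCase.CASE_I:
        return case, [region.copy()], profile

    seeds = extract_seeds(region, profile, schedule, min_object_area)
    field = gvf_field(region, mu=mu, n_iter=gvf_iter, sigma=sigma)
    contours = []
    for seed in seeds:
        try:
            contours.append(
                evolve_snake(
                    seed, field, alpha=alpha, beta=beta, gamma=gamma,
                    kappa=kappa, n_iter=snake_iter, n_points=n_points,
                )
            )
        except SnakeCollapseError:
            contours.append(_resample_closed(_boundary_contour(seed), n_points))
    masks = separate_region(region, contours)
    masks = [m for m in masks if m.any()]
    return case, masks, profile
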