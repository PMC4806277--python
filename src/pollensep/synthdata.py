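"""Seeded generator of synthetic stained-pollen scenes with ground truth.

The generator emulates the statistics of methyl-green-stained slide
photographs: purple elliptical grains (the 12 species differ in size,
elongation, stain shade, exine-ring width and texture noise) on a pale
background littered with low-saturation "Vaseline" blobs. Grains appear
either isolated (Case I) or in overlapping conspecific clumps of two or
three (Case II) — clumped grains in real slides usually originate from
one anther, so clump members share a species and hence a size class.
Every scene carries exact per-grain ground-truth masks (the rasterized
ellipse interiors) and case labels, so each pipeline stage is testable
without any external image download.

Geometry is expressed at a nominal 0.5 µm/px, mapping the 10–60 µm
equivalent-diameter range of airborne pollen onto 20–120 px; the class
means used here span 26–84 px so that several grains fit a 278×208
frame. Semi-minor axes are kept a few percent away from the informative
Fibonacci radii (13, 21, 34) so that clump members never straddle an
erosion step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color

from .features import feature_vector
from .classify import FeatureDataset

__all__ = [
    "GrainSpec",
    "SceneSpec",
    "CLASS_PROFILES",
    "sample_scene",
    "render_scene",
    "generate_feature_dataset",
]


@dataclass
class GrainSpec:
    center: tuple[float, float]          # (x, y) px
    semi_axes: tuple[float, float]       # (a_px, b_px), a >= b
    rotation: float                      # radians
    fill_lab: tuple[float, float, float]
    exine_width: float                   # px, 0 = no ring
    noise_sigma: tuple[float, float, float]
    class_id: int                        # 1..12


@dataclass
class SceneSpec:
    image_size: tuple[int, int]          # (H, W)
    grains: list[GrainSpec]
    clusters: list[list[int]]            # grain indices per clump
    clutter: list[dict]                  # ellipse blobs: center/axes/rotation
    background_lab: tuple[float, float, float]
    render_seed: int

    @property
    def case_labels(self) -> list[str]:
        return ["CASE_II" if len(c) > 1 else "CASE_I" for c in self.clusters]


# per-class priors: (equiv. diameter px, elongation a/b, ΔL, Δa, Δb,
# exine ring width px, per-channel texture noise σ)
CLASS_PROFILES: dict[int, dict] = {
    1:  dict(diameter=26, ecc=1.20, dL=+6, da=-4, db=+4, exine=0.0, noise=0.8),
    2:  dict(diameter=36, ecc=1.05, dL=-4, da=+3, db=-3, exine=1.5, noise=1.2),
    3:  dict(diameter=38, ecc=1.30, dL=+2, da=-2, db=+6, exine=0.0, noise=2.2),
    4:  dict(diameter=40, ecc=1.25, dL=-6, da=+5, db=+2, exine=2.0, noise=0.6),
    5:  dict(diameter=54, ecc=1.10, dL=+4, da=0,  db=-6, exine=0.0, noise=1.6),
    6:  dict(diameter=57, ecc=1.25, dL=-2, da=-5, db=-2, exine=2.5, noise=1.0),
    7:  dict(diameter=58, ecc=1.10, dL=+8, da=+4, db=+3, exine=0.0, noise=2.4),
    8:  dict(diameter=62, ecc=1.30, dL=-8, da=-3, db=-5, exine=1.5, noise=0.7),
    9:  dict(diameter=64, ecc=1.10, dL=0,  da=+6, db=+5, exine=3.0, noise=1.4),
    10: dict(diameter=70, ecc=1.40, dL=+5, da=-6, db=0,  exine=0.0, noise=1.9),
    11: dict(diameter=68, ecc=1.35, dL=-5, da=+2, db=-4, exine=2.0, noise=1.1),
    12: dict(diameter=84, ecc=1.05, dL=+3, da=+5, db=+6, exine=3.5, noise=1.5),
}

_STAIN_LAB = (45.0, 35.0, -25.0)       # methyl-green/purple stain prior
_BACKGROUND_LAB = (92.0, 2.0, 2.0)
_CLUTTER_LAB = (85.0, 4.0, 12.0)       # low-saturation Vaseline smear
_EDGE_SOFTNESS = 1.2                   # px, anti-aliasing ramp


def _sample_grain(rng: np.random.Generator, class_id: int,
                  base: GrainSpec | None = None) -> tuple[float, float, float, dict]:
    """Sample (a, b, rotation, profile) for one grain; clump partners
    (``base`` given) inherit their mate's size up to a few percent."""
    prof = CLASS_PROFILES[class_id]
    if base is None:
        d = prof["diameter"] * (1.0 + rng.normal(0.0, 0.03))
        ecc = prof["ecc"] + rng.normal(0.0, 0.03)
    else:
        d = 2.0 * np.sqrt(base.semi_axes[0] * base.semi_axes[1])
        d *= 1.0 + rng.normal(0.0, 0.02)
        ecc = base.semi_axes[0] / base.semi_axes[1] + rng.normal(0.0, 0.02)
    ecc = max(1.0, ecc)
    b = d / (2.0 * np.sqrt(ecc))
    a = d * np.sqrt(ecc) / 2.0
    theta = rng.uniform(0.0, np.pi)
    return a, b, theta, prof


def _grain_color(rng: np.random.Generator, prof: dict) -> tuple[float, float, float]:
    return (
        _STAIN_LAB[0] + prof["dL"] + rng.normal(0.0, 1.0),
        _STAIN_LAB[1] + prof["da"] + rng.normal(0.0, 0.8),
        _STAIN_LAB[2] + prof["db"] + rng.normal(0.0, 0.8),
    )


def _directional_radius(g: GrainSpec, heading: float) -> float:
    """Radius of a grain's ellipse along an image-frame direction."""
    psi = heading - g.rotation
    a, b = g.semi_axes
    return 1.0 / np.sqrt((np.cos(psi) / a) ** 2 + (np.sin(psi) / b) ** 2)


def sample_scene(
    seed: int,
    n_grains: int,
    p_overlap: float = 0.0,
    image_size: tuple[int, int] = (208, 278),
    max_attempts: int = 1000,
) -> SceneSpec:
    """Draw a deterministic scene layout.

    Grains are grouped into clumps: after the first grain of a clump,
    each subsequent grain joins it with probability ``p_overlap`` (clump
    size capped at 3), sharing the clump's species. Clump members are
    placed at center separation c·(r₁(φ)+r₂(φ)) with c ∈ [0.84, 0.96],
    where r(φ) is each ellipse's radius along the center line — a
    shallow, monolayer-style overlap that guarantees intersecting
    interiors while respecting the ≥ 0.8·(b₁+b₂) separability floor
    (r(φ) ≥ b). Distinct clumps and clutter keep clear margins from each
    other and the frame.
    """
    if n_grains < 1:
        raise ValueError("n_grains must be >= 1")
    if not 0.0 <= p_overlap <= 1.0:
        raise ValueError("p_overlap must be in [0, 1]")
    rng = np.random.default_rng(seed)
    H, W = image_size

    # clump plan
    clusters: list[list[int]] = []
    for g in range(n_grains):
        if clusters and len(clusters[-1]) < 3 and rng.random() < p_overlap:
            clusters[-1].append(g)
        else:
            clusters.append([g])

    grains: list[GrainSpec] = [None] * n_grains  # type: ignore[list-item]
    placed_clusters: list[tuple[float, float, float]] = []  # (x, y, radius)

    for cluster in clusters:
        # re-draw species/geometry when a clump cannot be placed: crowded
        # frames reject the largest species rather than failing outright
        attempts_left = max_attempts
        placed = False
        while attempts_left > 0 and not placed:
            class_id = int(rng.integers(1, 13))
            geoms = []
            base: GrainSpec | None = None
            for gi in cluster:
                a, b, theta, prof = _sample_grain(rng, class_id, base)
                spec = GrainSpec(
                    center=(0.0, 0.0),
                    semi_axes=(a, b),
                    rotation=theta,
                    fill_lab=_grain_color(rng, prof),
                    exine_width=prof["exine"],
                    noise_sigma=(prof["noise"],) * 3,
                    class_id=class_id,
                )
                geoms.append(spec)
                base = base or spec

            # relative positions within the clump (chain of shallow
            # overlaps): grains in a monolayer clump interpenetrate only a
            # small fraction of their directional radii, so the separation
            # is c·(r₁(φ)+r₂(φ)) with r(φ) the ellipse radius along the
            # center line — always ≥ c·(b₁+b₂)
            offsets = [(0.0, 0.0)]
            heading = rng.uniform(0.0, 2 * np.pi)
            for k in range(1, len(geoms)):
                heading += rng.uniform(-np.pi / 4, np.pi / 4)
                r_prev = _directional_radius(geoms[k - 1], heading)
                r_this = _directional_radius(geoms[k], heading)
                d = rng.uniform(0.84, 0.96) * (r_prev + r_this)
                offsets.append(
                    (offsets[k - 1][0] + d * np.cos(heading),
                     offsets[k - 1][1] + d * np.sin(heading))
                )
            ox = np.array([o[0] for o in offsets])
            oy = np.array([o[1] for o in offsets])
            amax = max(g.semi_axes[0] for g in geoms)
            radius = 0.5 * max(ox.max() - ox.min(), oy.max() - oy.min()) + amax
            cx0 = (ox.max() + ox.min()) / 2.0
            cy0 = (oy.max() + oy.min()) / 2.0

            margin = radius + 4.0
            if 2 * margin >= min(H, W):
                attempts_left -= 50  # clump cannot fit at all; re-draw
                continue
            for _ in range(min(50, attempts_left)):
                attempts_left -= 1
                x = rng.uniform(margin, W - margin)
                y = rng.uniform(margin, H - margin)
                if all(
                    np.hypot(x - px, y - py) >= radius + pr + 12.0
                    for px, py, pr in placed_clusters
                ):
                    placed = True
                    break
        if not placed:
            raise RuntimeError(
                f"could not place clump after {max_attempts} attempts"
            )
        placed_clusters.append((x, y, radius))
        for spec, dx, dy, gi in zip(geoms, ox, oy, cluster):
            spec.center = (x + dx - cx0, y + dy - cy0)
            grains[gi] = spec

    # clutter blobs, clear of every grain
    clutter: list[dict] = []
    for _ in range(int(rng.integers(2, 6))):
        ca = rng.uniform(6.0, 16.0)
        cb = rng.uniform(4.0, ca)
        for attempt in range(200):
            x = rng.uniform(ca, W - ca)
            y = rng.uniform(ca, H - ca)
            if all(
                np.hypot(x - g.center[0], y - g.center[1])
                >= g.semi_axes[0] + ca + 6.0
                for g in grains
            ):
                clutter.append(
                    dict(center=(x, y), axes=(ca, cb),
                         rotation=rng.uniform(0.0, np.pi))
                )
                break

    return SceneSpec(
        image_size=image_size,
        grains=grains,
        clusters=clusters,
        clutter=clutter,
        background_lab=_BACKGROUND_LAB,
        render_seed=int(rng.integers(0, 2**31 - 1)),
    )


def _ellipse_rho(shape: tuple[int, int], center, axes, rotation) -> np.ndarray:
    """Normalized elliptical radius (1 on the boundary) at pixel centers."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    dx = xx - center[0]
    dy = yy - center[1]
    c, s = np.cos(rotation), np.sin(rotation)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    return np.sqrt((u / axes[0]) ** 2 + (v / axes[1]) ** 2)


def render_scene(
    spec: SceneSpec,
) -> tuple[np.ndarray, list[np.ndarray], list[str]]:
    """Render a scene to (RGB uint8 image, per-grain masks, case labels).

    The image is composed in Lab: background with faint sensor noise,
    then clutter, then grains (soft anti-aliased edge, darker exine ring,
    per-channel Gaussian texture noise), and finally converted to sRGB.
    Ground-truth masks are the exact rasterized ellipse interiors and are
    independent of rendering noise. Fully deterministic given the spec.
    """
    rng = np.random.default_rng(spec.render_seed)
    H, W = spec.image_size
    img = np.empty((H, W, 3), dtype=np.float64)
    for k in range(3):
        img[..., k] = spec.background_lab[k] + rng.normal(0.0, 0.4, size=(H, W))

    for blob in spec.clutter:
        rho = _ellipse_rho((H, W), blob["center"], blob["axes"], blob["rotation"])
        alpha = np.clip(0.5 + (1.0 - rho) * min(blob["axes"]) / _EDGE_SOFTNESS, 0.0, 1.0)
        for k in range(3):
            img[..., k] = img[..., k] * (1 - alpha) + _CLUTTER_LAB[k] * alpha

    masks: list[np.ndarray] = []
    for g in spec.grains:
        rho = _ellipse_rho((H, W), g.center, g.semi_axes, g.rotation)
        masks.append(rho <= 1.0)
        # anti-aliasing ramp centered on the true boundary, so the rendered
        # footprint matches the ground-truth ellipse to within half a pixel
        alpha = np.clip(0.5 + (1.0 - rho) * g.semi_axes[1] / _EDGE_SOFTNESS, 0.0, 1.0)
        sel = alpha > 0
        ring = sel & (rho >= 1.0 - g.exine_width / g.semi_axes[1]) if g.exine_width > 0 else None
        for k in range(3):
            col = np.full((H, W), g.fill_lab[k])
            if ring is not None:
                # exine: darker and slightly redder band at the rim
                delta = (-12.0, 8.0, -4.0)[k]
                col[ring] += delta
            if g.noise_sigma[k] > 0:
                col[sel] += rng.normal(0.0, g.noise_sigma[k], size=int(sel.sum()))
            img[..., k] = img[..., k] * (1 - alpha) + col * alpha

    rgb = color.lab2rgb(img)
    rgb8 = np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)
    cases = spec.case_labels
    grain_case = [None] * len(spec.grains)
    for cluster, case in zip(spec.clusters, cases):
        for gi in cluster:
            grain_case[gi] = case
    return rgb8, masks, grain_case  # type: ignore[return-value]


def generate_feature_dataset(seed: int, n_per_class: int) -> FeatureDataset:
    """Labeled 33-column dataset from isolated rendered grains.

    Renders ``n_per_class`` single-grain scenes per species, extracts the
    descriptor on each ground-truth mask, and stacks the rows in class
    order (labels 1..12, each repeated ``n_per_class`` times).
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    from .preprocess import rgb_to_lab

    rng = np.random.default_rng(seed)
    rows = []
    labels = []
    for class_id in range(1, 13):
        for _ in range(n_per_class):
            sub = int(rng.integers(0, 2**31 - 1))
            spec = _single_grain_scene(sub, class_id)
            rgb, masks, _ = render_scene(spec)
            lab = rgb_to_lab(rgb)
            gf = feature_vector(masks[0], lab, label=class_id)
            rows.append(gf.as_array())
            labels.append(class_id)
    return FeatureDataset(np.asarray(rows), np.asarray(labels))


def _single_grain_scene(seed: int, class_id: int,
                        image_size: tuple[int, int] = (160, 160)) -> SceneSpec:
    """A one-grain scene of a forced class on a small frame."""
    rng = np.random.default_rng(seed)
    a, b, theta, prof = _sample_grain(rng, class_id)
    H, W = image_size
    spec = GrainSpec(
        center=(W / 2.0 + rng.uniform(-5, 5), H / 2.0 + rng.uniform(-5, 5)),
        semi_axes=(a, b),
        rotation=theta,
        fill_lab=_grain_color(rng, prof),
        exine_width=prof["exine"],
        noise_sigma=(prof["noise"],) * 3,
        class_id=class_id,
    )
    return SceneSpec(
        image_size=image_size,
        grains=[spec],
        clusters=[[0]],
        clutter=[],
        background_lab=_BACKGROUND_LAB,
        render_seed=int(rng.integers(0, 2**31 - 1)),
    )
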