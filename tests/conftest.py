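import numpy as np
import pytest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def two_disk_region():
    """Union of two radius-20 disks, centers 35 px apart.

    The separation satisfies the 0.8·(b₁+b₂) floor (35 = 0.875·40), the
    union's neck breaks at erosion radius ≥ √(20² − 17.5²) ≈ 9.7, and the
    Fibonacci radius 13 lands inside the split window before both disks
    vanish at 20 — the canonical Case II geometry.
    """
    yy, xx = np.mgrid[0:100, 0:110]
    c1 = (50, 37)
    c2 = (50, 72)
    m = ((yy - c1[0]) ** 2 + (xx - c1[1]) ** 2 <= 400) | (
        (yy - c2[0]) ** 2 + (xx - c2[1]) ** 2 <= 400
    )
    gt = [
        (yy - c1[0]) ** 2 + (xx - c1[1]) ** 2 <= 400,
        (yy - c2[0]) ** 2 + (xx - c2[1]) ** 2 <= 400,
    ]
    return m, gt, (c1, c2)


def random_blob(rng, size=48, n_seeds=3, r_lo=4, r_hi=12):
    """A random union of disks: a small single/multi-component test mask."""
    yy, xx = np.mgrid[0:size, 0:size]
    m = np.zeros((size, size), bool)
    for _ in range(n_seeds):
        cy, cx = rng.integers(r_hi, size - r_hi, size=2)
        r = int(rng.integers(r_lo, r_hi))
        m |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    return m
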