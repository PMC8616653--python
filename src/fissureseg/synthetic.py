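"""Synthetic fissured-tongue image generator with pixel-exact ground truth.

The clinical data this package targets — close-up tongue photographs in
which thin, darker cracks crisscross the textured tongue surface — is not
publicly available, so this module produces structurally similar scenes:
a convex, textured foreground ellipse (the tongue body) on a dark
background, carrying a small number of branching random-walk cracks that
are darkened relative to the surrounding tissue. The mask is exactly the
set of crack pixels, so segmentation quality is measured against a
noise-free ground truth.

The defaults aim at the qualitative regime of clinical fissure photos:
cracks occupy a few percent of the image, are 1–4 px wide at 128 px
resolution, branch occasionally, and contrast clearly but not extremely
with the papillae texture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from .data_io import Sample

__all__ = ["SyntheticParams", "generate_skeleton", "render_sample", "generate_dataset"]


@dataclass
class SyntheticParams:
    """Parameters of the synthetic crack-image model.

    Attributes
    ----------
    image_size : (H, W) in pixels, each >= 32.
    crack_count_range : inclusive interval for the number of primary cracks.
    branch_probability : per-step probability that a walk spawns a branch.
    step_length : random-walk step, pixels.
    crack_width_range : inclusive interval of crack stroke widths, pixels.
    crack_intensity_delta : signed intensity offset applied to crack pixels
        (negative = darker than tissue), 8-bit units.
    background_base_color : RGB of the tongue tissue before texturing.
    texture_noise_scale : amplitude of the low-frequency tissue texture.
    foreground_ellipse_axes_fraction : ellipse semi-axes as fractions of
        (W/2, H/2).
    seed : default seed used when none is passed explicitly.
    """

    image_size: Tuple[int, int] = (128, 128)
    crack_count_range: Tuple[int, int] = (3, 6)
    branch_probability: float = 0.06
    step_length: float = 3.0
    crack_width_range: Tuple[int, int] = (1, 3)
    crack_intensity_delta: float = -70.0
    background_base_color: Tuple[int, int, int] = (182, 112, 118)
    texture_noise_scale: float = 14.0
    foreground_ellipse_axes_fraction: Tuple[float, float] = (0.86, 0.88)
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValueError(f"image_size must be >= 32 in both dims, got {self.image_size}")
        lo, hi = self.crack_count_range
        if not (0 <= lo <= hi):
            raise ValueError(f"invalid crack_count_range {self.crack_count_range}")
        wlo, whi = self.crack_width_range
        if not (1 <= wlo <= whi):
            raise ValueError(f"invalid crack_width_range {self.crack_width_range}")
        if not 0.0 <= self.branch_probability <= 1.0:
            raise ValueError("branch_probability must be in [0, 1]")
        for f in self.foreground_ellipse_axes_fraction:
            if not 0.0 < f <= 1.0:
                raise ValueError("foreground_ellipse_axes_fraction entries must be in (0, 1]")


def _ellipse_geometry(params: SyntheticParams):
    h, w = params.image_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    fx, fy = params.foreground_ellipse_axes_fraction
    ax = fx * w / 2.0
    ay = fy * h / 2.0
    return cx, cy, ax, ay


def ellipse_mask(params: SyntheticParams) -> np.ndarray:
    """Boolean (H, W) membership of pixel centers in the foreground ellipse."""
    h, w = params.image_size
    cx, cy, ax, ay = _ellipse_geometry(params)
    yy, xx = np.mgrid[0:h, 0:w]
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


_MAX_STEPS = 50
_MAX_TURN = 0.5  # rad per step
_BRANCH_CAP_FACTOR = 3  # total polylines <= factor * primary crack count


def generate_skeleton(params: SyntheticParams, seed: int) -> List[np.ndarray]:
    """Sample crack centerlines as bounded-turning random walks.

    Each primary crack starts inside the (shrunken) foreground ellipse with
    a uniform heading; at each step the heading turns by a uniform bounded
    angle and advances by ``step_length``. With probability
    ``branch_probability`` per step a branch walk spawns from the current
    point at roughly 60 degrees. Walks terminate when they leave the
    ellipse or reach a step cap. Deterministic given the seed.

    Returns a list of (n_points, 2) float arrays in (x, y) coordinates.
    """
    rng = np.random.default_rng(seed)
    cx, cy, ax, ay = _ellipse_geometry(params)
    lo, hi = params.crack_count_range
    n_primary = int(rng.integers(lo, hi + 1))
    if n_primary == 0:
        return []

    def inside(x, y, shrink=1.0):
        return ((x - cx) / (ax * shrink)) ** 2 + ((y - cy) / (ay * shrink)) ** 2 <= 1.0

    max_polylines = max(1, _BRANCH_CAP_FACTOR * n_primary)
    polylines: List[np.ndarray] = []
    # (x, y, heading) seeds for walks yet to run; branches are appended
    queue = []
    for _ in range(n_primary):
        while True:
            x = cx + (rng.uniform(-1, 1)) * ax * 0.7
            y = cy + (rng.uniform(-1, 1)) * ay * 0.7
            if inside(x, y, shrink=0.7):
                break
        queue.append((x, y, rng.uniform(0.0, 2 * np.pi)))

    while queue and len(polylines) < max_polylines:
        x, y, heading = queue.pop(0)
        pts = [(x, y)]
        for _ in range(_MAX_STEPS):
            heading += rng.uniform(-_MAX_TURN, _MAX_TURN)
            x += params.step_length * np.cos(heading)
            y += params.step_length * np.sin(heading)
            if not inside(x, y):
                break
            pts.append((x, y))
            if rng.random() < params.branch_probability and len(queue) + len(polylines) < max_polylines:
                side = 1.0 if rng.random() < 0.5 else -1.0
                queue.append((x, y, heading + side * rng.uniform(0.8, 1.3)))
        if len(pts) >= 2:
            polylines.append(np.asarray(pts, dtype=float))
    return polylines


def _draw_polyline(canvas: np.ndarray, pts: np.ndarray) -> None:
    """Mark integer pixels along the segments of `pts` ((x, y) coords)."""
    from skimage.draw import line

    h, w = canvas.shape
    ipts = np.round(pts).astype(int)
    for (x0, y0), (x1, y1) in zip(ipts[:-1], ipts[1:]):
        rr, cc = line(y0, x0, y1, x1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        canvas[rr[keep], cc[keep]] = True


def _tongue_texture(params: SyntheticParams, rng: np.random.Generator) -> np.ndarray:
    """Tissue texture: low-frequency smooth field plus fine grain, (H, W)."""
    h, w = params.image_size
    coarse = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=max(h, w) / 16.0)
    coarse /= max(np.abs(coarse).max(), 1e-9)
    grain = rng.normal(0.0, 0.25, (h, w))
    return params.texture_noise_scale * (coarse + grain)


def render_sample(params: SyntheticParams, seed: int) -> Sample:
    """Render one synthetic tongue image with its exact binary crack mask."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    h, w = params.image_size
    fg = ellipse_mask(params)

    base = np.array(params.background_base_color, dtype=float)
    image = np.empty((h, w, 3), dtype=float)
    image[:] = np.array([38.0, 26.0, 28.0])  # dark backdrop outside the tongue
    texture = _tongue_texture(params, rng)
    for ch in range(3):
        tissue = base[ch] + texture * (1.0 if ch == 0 else 0.8)
        image[:, :, ch][fg] = tissue[fg]

    skeletons = generate_skeleton(params, seed)
    crack = np.zeros((h, w), dtype=bool)
    wlo, whi = params.crack_width_range
    for pts in skeletons:
        stroke = np.zeros((h, w), dtype=bool)
        _draw_polyline(stroke, pts)
        width = int(rng.integers(wlo, whi + 1))
        if width > 1:
            radius = (width - 1) / 2.0
            yy, xx = np.mgrid[-int(np.ceil(radius)) : int(np.ceil(radius)) + 1,
                              -int(np.ceil(radius)) : int(np.ceil(radius)) + 1]
            disk = xx**2 + yy**2 <= radius**2 + 1e-9
            stroke = ndimage.binary_dilation(stroke, structure=disk)
        crack |= stroke
    crack &= fg

    jitter = rng.normal(0.0, 6.0, size=(h, w))
    delta = params.crack_intensity_delta + jitter
    for ch in range(3):
        image[:, :, ch][crack] += delta[crack]

    image = np.clip(image, 0, 255).astype(np.uint8)
    mask = crack.astype(np.uint8)
    return Sample(image=image, mask=mask, identifier=f"synthetic-{seed}")


def generate_dataset(params: SyntheticParams, n: int, seed: int) -> List[Sample]:
    """Generate `n` samples with per-sample seeds derived from (seed, index).

    Seeds are derived through independent ``SeedSequence([seed, index])``
    streams, so any subset of indices reproduces the same samples
    regardless of generation order.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    samples = []
    for index in range(n):
        sub = int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))
        s = render_sample(params, sub)
        s.identifier = f"synthetic-{seed:04d}-{index:04d}"
        samples.append(s)
    return samples
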