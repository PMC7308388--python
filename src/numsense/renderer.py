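"""Rendering stimulus points into binary dot-array images.

Dots are non-overlapping discs of a common radius, placed uniformly at
random inside a circular field of area FA centred on a square canvas
(white dots on black).  The module also measures empirical image
features -- including the convex hull of the dot union -- back from a
rendered image, which the representational analysis uses for features
that have no exact analytic form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint, Point

from .errors import InvalidArgumentError, PlacementInfeasibleError
from .stimulus_space import StimulusPoint, derive_features

__all__ = [
    "DotArrayImage",
    "EmpiricalFeatures",
    "render_dot_array",
    "downscale_image",
    "measure_empirical_features",
    "save_image",
    "load_image",
]

#: Minimum gap between dot edges (px).  Chosen > 1 so rasterised dots can
#: never share 4-connected pixels, keeping connected-component counts exact.
MIN_GAP = 1.2


@dataclass
class DotArrayImage:
    """A rendered dot array: binary pixels plus placement geometry."""

    pixels: np.ndarray
    centers: np.ndarray  # (n, 2) array of (x, y) pixel coordinates
    radius: float
    point: StimulusPoint = field(repr=False)


@dataclass(frozen=True)
class EmpiricalFeatures:
    """Features measured from a rendered image rather than derived analytically."""

    count: int
    total_area: float
    mean_item_area: float
    convex_hull_area: float
    total_perimeter: float
    field_extent: float  # area of the smallest centred disc containing all dots


def _sample_centers(
    n: int,
    field_radius: float,
    dot_radius: float,
    canvas: int,
    rng: np.random.Generator,
    max_attempts: int,
) -> np.ndarray | None:
    """Rejection-sample n centers in the field disc with pairwise separation."""
    cx = canvas / 2.0
    min_dist = 2.0 * dot_radius + MIN_GAP
    centers = np.empty((n, 2))
    placed = 0
    attempts = 0
    while placed < n:
        if attempts >= max_attempts:
            return None
        attempts += 1
        r = field_radius * math.sqrt(rng.random())
        theta = 2.0 * math.pi * rng.random()
        c = np.array([cx + r * math.cos(theta), cx + r * math.sin(theta)])
        # keep the whole disc on the canvas so pixel counts stay honest
        if (c - dot_radius < 0).any() or (c + dot_radius > canvas).any():
            continue
        if placed and (np.linalg.norm(centers[:placed] - c, axis=1) < min_dist).any():
            continue
        centers[placed] = c
        placed += 1
    return centers


def _rasterize(centers: np.ndarray, radius: float, canvas: int) -> np.ndarray:
    img = np.zeros((canvas, canvas), dtype=np.uint8)
    coords = np.arange(canvas) + 0.5  # pixel-center convention
    for cx, cy in centers:
        x0 = max(int(cx - radius) - 1, 0)
        x1 = min(int(cx + radius) + 2, canvas)
        y0 = max(int(cy - radius) - 1, 0)
        y1 = min(int(cy + radius) + 2, canvas)
        xs = coords[x0:x1] - cx
        ys = coords[y0:y1] - cy
        mask = xs[None, :] ** 2 + ys[:, None] ** 2 <= radius**2
        img[y0:y1, x0:x1][mask] = 1
    return img


def render_dot_array(
    p: StimulusPoint,
    canvas: int = 200,
    rng: np.random.Generator | None = None,
    max_attempts: int = 10_000,
    max_restarts: int = 50,
) -> DotArrayImage:
    """Render ``p`` as a binary image of ``canvas`` x ``canvas`` pixels.

    Raises :class:`PlacementInfeasibleError` if the field disc does not
    fit on the canvas or dot placement keeps failing.
    """
    rng = np.random.default_rng() if rng is None else rng
    f = derive_features(p)
    field_radius = math.sqrt(f.fa / math.pi)
    dot_radius = math.sqrt(f.isa / math.pi)
    if 2.0 * field_radius > canvas:
        raise PlacementInfeasibleError(
            f"field disc (radius {field_radius:.1f}) exceeds canvas {canvas} for {p}"
        )
    for _ in range(max_restarts):
        centers = _sample_centers(p.n, field_radius, dot_radius, canvas, rng, max_attempts)
        if centers is not None:
            return DotArrayImage(
                pixels=_rasterize(centers, dot_radius, canvas),
                centers=centers,
                radius=dot_radius,
                point=p,
            )
    raise PlacementInfeasibleError(f"could not place {p.n} dots for {p}")


def downscale_image(img: np.ndarray, target: int) -> np.ndarray:
    """Downscale a square image to ``target`` x ``target``, values in [0, 1].

    Uses exact block averaging when ``target`` divides the source side,
    otherwise area-preserving interpolation.
    """
    img = np.asarray(img, dtype=float)
    side = img.shape[0]
    if img.shape[0] != img.shape[1]:
        raise InvalidArgumentError("image must be square")
    if target > side:
        raise InvalidArgumentError(f"target {target} exceeds source side {side}")
    if img.max() > 1.0:
        img = img / img.max()
    if target == side:
        return img
    if side % target == 0:
        b = side // target
        return img.reshape(target, b, target, b).mean(axis=(1, 3))
    from skimage.transform import resize

    return np.clip(resize(img, (target, target), anti_aliasing=True), 0.0, 1.0)


def save_image(img: DotArrayImage, path) -> None:
    """Write an 8-bit grayscale PNG plus a CSV sidecar of placement geometry.

    The sidecar (same stem, ``.csv`` suffix) holds one row per dot
    (x, y, radius) followed by the source point coordinates, so a saved
    image can be reloaded without loss.
    """
    from pathlib import Path

    from PIL import Image

    path = Path(path)
    Image.fromarray((np.asarray(img.pixels) * 255).astype(np.uint8), mode="L").save(
        path
    )
    p = img.point
    lines = ["x,y,radius,n,size,spacing,instance_id"]
    for x, y in img.centers:
        lines.append(
            f"{float(x)!r},{float(y)!r},{float(img.radius)!r},"
            f"{p.n},{float(p.size)!r},{float(p.spacing)!r},{p.instance_id}"
        )
    path.with_suffix(".csv").write_text("\n".join(lines) + "\n")


def load_image(path) -> DotArrayImage:
    """Reload a PNG + sidecar pair written by :func:`save_image`."""
    from pathlib import Path

    from PIL import Image

    path = Path(path)
    pixels = (np.asarray(Image.open(path)) > 127).astype(np.uint8)
    rows = path.with_suffix(".csv").read_text().strip().splitlines()[1:]
    if not rows:
        raise InvalidArgumentError(f"sidecar for {path} has no dots")
    parsed = [r.split(",") for r in rows]
    centers = np.array([[float(r[0]), float(r[1])] for r in parsed])
    radius = float(parsed[0][2])
    first = parsed[0]
    point = StimulusPoint(
        n=int(first[3]),
        size=float(first[4]),
        spacing=float(first[5]),
        instance_id=int(first[6]),
    )
    return DotArrayImage(pixels=pixels, centers=centers, radius=radius, point=point)


def measure_empirical_features(img: DotArrayImage) -> EmpiricalFeatures:
    """Measure features from a rendered image.

    Count comes from 4-connected components of the binary pixels; the
    convex hull is taken over the dot discs (centers padded by the
    radius), so a single dot has hull area ~ pi r^2.
    """
    pixels = np.asarray(img.pixels)
    if not pixels.any():
        raise InvalidArgumentError("image contains no white pixels")
    four_conn = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    _, count = ndimage.label(pixels, structure=four_conn)
    total_area = float(pixels.sum())

    discs = [Point(x, y).buffer(img.radius, quad_segs=64) for x, y in img.centers]
    hull = MultiPoint(
        [pt for d in discs for pt in d.exterior.coords]
    ).convex_hull
    hull_area = float(hull.area)

    total_perimeter = len(img.centers) * 2.0 * math.pi * img.radius
    center = pixels.shape[0] / 2.0
    extent_radius = max(
        float(np.linalg.norm(c - center)) + img.radius for c in img.centers
    )
    return EmpiricalFeatures(
        count=int(count),
        total_area=total_area,
        mean_item_area=total_area / count,
        convex_hull_area=hull_area,
        total_perimeter=total_perimeter,
        field_extent=math.pi * extent_radius**2,
    )
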