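"""Shape and color parameterization of masked plant images.

Sixteen shape descriptors plus a per-degree (360-bin) hue histogram are
extracted from an RGB image and its binary foreground mask, mirroring the
trait set of high-throughput phenotyping image pipelines.

Conventions: raster coordinates, origin at the top-left corner, x rightward
(columns), y downward (rows), 0-based pixel centers.  Hue is measured in
degrees on the 0-360 color wheel (yellow ~60, green ~120), never in 8-bit
0-255 codes.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage.color import rgb2hsv
from skimage.measure import regionprops
from skimage.morphology import convex_hull_image

N_SHAPE_FEATURES = 16


@dataclass
class ShapeFeatures:
    """The 16 shape descriptors of one plant mask.

    Areas are pixel counts; lengths are in pixels; ``ellipse_angle`` is the
    orientation of the moment-equivalent ellipse's major axis in degrees.
    ``hull_area`` counts the pixels of the filled convex hull, so
    ``solidity = area / hull_area`` lies in (0, 1]; ``hull_vertices`` and
    ``longest_axis`` are computed on the convex hull of pixel centers.
    """

    area: float
    hull_area: float
    solidity: float
    perimeter: float
    width: float
    height: float
    longest_axis: float
    com_x: float
    com_y: float
    hull_vertices: float
    ellipse_cx: float
    ellipse_cy: float
    ellipse_major: float
    ellipse_minor: float
    ellipse_angle: float
    ellipse_eccentricity: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class HueHistogram:
    """Per-degree hue pixel counts (or mask fractions once normalized).

    Pixels with undefined hue (zero saturation or zero value) are excluded
    from the bins but still count toward ``n_mask_pixels``, so a normalized
    histogram sums to the defined-hue fraction of the mask (<= 1).
    """

    bins: np.ndarray
    n_mask_pixels: int
    normalized: bool = False

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.shape != (360,):
            raise ValueError("hue histogram must have 360 per-degree bins")


def segment_plant(image: np.ndarray, background_color=None,
                  tolerance: float = 20.0) -> np.ndarray:
    """Threshold segmentation against a known uniform background.

    A pixel is foreground when its Euclidean RGB distance from
    ``background_color`` exceeds ``tolerance``.  An all-background image
    yields an empty mask (not an error).
    """
    if image.size == 0:
        raise ValueError("empty image")
    if background_color is None:
        from .synthetic import BACKGROUND_RGB
        background_color = BACKGROUND_RGB
    bg = np.asarray(background_color, dtype=float)
    dist = np.sqrt(((image.astype(float) - bg) ** 2).sum(axis=-1))
    return dist > tolerance


def crack_perimeter(mask: np.ndarray) -> float:
    """Boundary length along pixel edges (crack following).

    Every unit pixel edge between a foreground pixel and background (or the
    image border) contributes 1.  Exactly invariant under 90-degree rotation
    and reflection.
    """
    m = mask.astype(np.int64)
    horiz = (m[:, :-1] & m[:, 1:]).sum()
    vert = (m[:-1, :] & m[1:, :]).sum()
    return float(4 * m.sum() - 2 * (horiz + vert))


def extract_shape_features(mask: np.ndarray) -> ShapeFeatures:
    """Compute the 16 shape descriptors from a boolean mask.

    All foreground pixels are treated as one object (plants may fragment
    into leaves).  Raises ``ValueError("no plant")`` on an empty mask; with
    fewer than 3 non-collinear pixels the hull- and ellipse-derived fields
    are NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no plant")

    rows, cols = np.nonzero(mask)
    com_x = float(cols.mean())
    com_y = float(rows.mean())
    width = float(cols.max() - cols.min() + 1)
    height = float(rows.max() - rows.min() + 1)
    perimeter = crack_perimeter(mask)

    hull_area = hull_vertices = longest_axis = float("nan")
    pts = np.column_stack([cols, rows]).astype(float)
    if n >= 3:
        try:
            hull = ConvexHull(pts)
            hv = pts[hull.vertices]
            hull_vertices = float(len(hull.vertices))
            longest_axis = float(pdist(hv).max())
            hull_area = float(convex_hull_image(mask).sum())
        except Exception:  # collinear pixels: degenerate hull
            longest_axis = float(pdist(pts).max())
    elif n == 2:
        longest_axis = float(pdist(pts).max())

    # moment-equivalent ellipse via regionprops on the single-object mask
    props = regionprops(mask.astype(np.uint8))[0]
    try:
        major = float(props.axis_major_length)
        minor = float(props.axis_minor_length)
        ecc = float(props.eccentricity)
        # regionprops orientation: angle between major axis and row (y) axis,
        # in (-pi/2, pi/2]; convert to degrees from the x axis
        angle = float(np.degrees(np.pi / 2 - props.orientation))
    except Exception:
        major = minor = ecc = angle = float("nan")

    return ShapeFeatures(
        area=float(n),
        hull_area=hull_area,
        solidity=float(n) / hull_area if hull_area == hull_area else float("nan"),
        perimeter=perimeter,
        width=width,
        height=height,
        longest_axis=longest_axis,
        com_x=com_x,
        com_y=com_y,
        hull_vertices=hull_vertices,
        ellipse_cx=com_x,
        ellipse_cy=com_y,
        ellipse_major=major,
        ellipse_minor=minor,
        ellipse_angle=angle,
        ellipse_eccentricity=ecc,
    )


def extract_hue_histogram(image: np.ndarray, mask: np.ndarray) -> HueHistogram:
    """Per-degree hue counts over the foreground pixels.

    Zero-saturation / zero-value pixels have no defined hue; they are left
    out of the bins but included in ``n_mask_pixels``.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    px = image[mask].reshape(1, -1, 3)
    hsv = rgb2hsv(px)[0]
    defined = (hsv[:, 1] > 0) & (hsv[:, 2] > 0)
    deg = np.floor(hsv[defined, 0] * 360.0).astype(int) % 360
    bins = np.bincount(deg, minlength=360).astype(float)
    return HueHistogram(bins=bins, n_mask_pixels=n, normalized=False)


def normalize_histogram(hist: HueHistogram) -> HueHistogram:
    """Convert counts to mask-pixel fractions (divide by total mask pixels)."""
    if hist.n_mask_pixels <= 0:
        raise ValueError("cannot normalize a histogram over an empty mask")
    return HueHistogram(bins=hist.bins / hist.n_mask_pixels,
                        n_mask_pixels=hist.n_mask_pixels, normalized=True)


def rebin_hue(hist, width_deg: int = 2) -> np.ndarray:
    """Sum adjacent degree bins into ``width_deg``-degree bins.

    Accepts a :class:`HueHistogram` or a length-360 vector; the default 2
    degrees gives the 180 bins used for color PCA.  Total mass is conserved.
    """
    bins = hist.bins if isinstance(hist, HueHistogram) else np.asarray(hist, dtype=float)
    if bins.shape[-1] != 360:
        raise ValueError("expected 360 per-degree bins")
    if 360 % width_deg != 0:
        raise ValueError("width_deg must divide 360")
    return bins.reshape(*bins.shape[:-1], 360 // width_deg, width_deg).sum(axis=-1)
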