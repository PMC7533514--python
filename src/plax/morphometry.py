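"""Geometric measurements on segmented placenta scenes.

Implements the measurement chain used to categorize the umbilical cord
insertion type from a 4-class label map:

1.  *Disc recovery* — the cord occludes part of the disc, so the raw
    disc class has a bite taken out of it.  The occluded area is filled
    by the polygon through disc-boundary pixels that touch the cord,
    taken in contour order, followed by a morphological closing.
2.  *Ruler scale* — a minimum-area rectangle is fitted to the ruler
    class, intensities inside are binarized (Otsu), the marker pixels
    are projected on the ruler's long edge and a 1-D Gaussian KDE is
    fitted; the pixels-per-centimeter scale is the median spacing of
    adjacent density crests (one tick per centimeter by default).
3.  *Caliper axes* — the disc's long and short axis are measured as
    support-line (Feret) widths over orientations at 1-degree steps,
    mimicking a pathologist's vernier caliper.
4.  *Margin distance* — Euclidean distance from the insertion point to
    the nearest boundary pixel of the recovered disc.
5.  *Categorization* — the ratio of margin distance to the mean of the
    long and short axis classifies the insertion as marginal /
    eccentric / central; the two thresholds are fitted by exhaustive
    accuracy maximization on labeled ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde
from skimage.draw import polygon as draw_polygon
from skimage.filters import threshold_otsu
from skimage.measure import find_contours
from skimage.morphology import disk

from .scene import CORD, DISC, RULER

__all__ = [
    "RulerScale", "InsertionMeasurement", "CategoryThresholds",
    "recover_disc", "ruler_scale", "disc_axes", "margin_distance",
    "categorize_insertion", "fit_thresholds", "px_to_cm",
    "measure_insertion", "RulerUnreadableError",
]

EIGHT = np.ones((3, 3), dtype=bool)

# Placeholder defaults: the fitted thresholds from clinical training data
# are unpublished; fit_thresholds on labeled ratios is the supported route.
DEFAULT_T_MARGINAL = 0.10
DEFAULT_T_CENTRAL = 1.0 / 3.0


class RulerUnreadableError(RuntimeError):
    pass


@dataclass(frozen=True)
class RulerScale:
    pixels_per_cm: float
    crest_positions: list[float]
    rect_angle: float

    def __post_init__(self) -> None:
        if self.pixels_per_cm <= 0:
            raise ValueError("pixels_per_cm must be positive")
        if len(self.crest_positions) < 2:
            raise ValueError("a readable ruler needs at least two crests")


@dataclass(frozen=True)
class CategoryThresholds:
    t_marginal: float = DEFAULT_T_MARGINAL
    t_central: float = DEFAULT_T_CENTRAL

    def __post_init__(self) -> None:
        if not (self.t_marginal < self.t_central):
            raise ValueError("require t_marginal < t_central")


@dataclass
class InsertionMeasurement:
    insertion_point: tuple[float, float]
    margin_point: tuple[float, float]
    margin_distance_px: float
    long_axis_px: float
    short_axis_px: float
    ratio: float
    category: str
    margin_distance_cm: float | None = None
    long_axis_cm: float | None = None
    short_axis_cm: float | None = None

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}


# ---------------------------------------------------------------------------
# step 1: disc recovery


def recover_disc(label_map: np.ndarray, closing_radius: int = 5) -> np.ndarray:
    """Merge the disc class with the cord-occluded polygon and close holes.

    The polygon vertices are disc-boundary pixels that have an
    8-neighbor in the cord class, ordered along the disc contour; the
    filled polygon covers the strip of disc hidden under the cord.  The
    result is always a superset of the input disc pixels.
    """
    disc = label_map == DISC
    if not disc.any():
        raise ValueError("label map contains no disc pixels")
    cord = label_map == CORD
    boundary = disc & ~ndimage.binary_erosion(disc, structure=EIGHT)
    junction = boundary & ndimage.binary_dilation(cord, structure=EIGHT)
    merged = disc.copy()
    jpix = np.argwhere(junction)
    if jpix.shape[0] >= 3:
        contours = find_contours(disc.astype(float), 0.5)
        contour = max(contours, key=len)
        order = cKDTree(contour).query(jpix.astype(float))[1]
        ordered = jpix[np.argsort(order)]
        rr, cc = draw_polygon(ordered[:, 0], ordered[:, 1], shape=disc.shape)
        merged[rr, cc] = True
    closed = ndimage.binary_closing(merged, structure=disk(closing_radius))
    return closed | disc


# ---------------------------------------------------------------------------
# step 2: ruler scale


def ruler_scale(image: np.ndarray, label_map: np.ndarray, *,
                min_ruler_pixels: int = 500, tick_unit: str = "cm",
                min_expected_pitch: float = 6.0,
                crest_prominence: float = 0.10) -> RulerScale:
    """Read the pixels-per-centimeter scale off the ruler class.

    KDE bandwidth follows Silverman's rule, guarded above by half the
    smallest expected tick pitch so that densely and sparsely ticked
    rulers both resolve individual crests; crests must reach a
    prominence of ``crest_prominence`` times the density maximum.
    """
    from shapely.geometry import MultiPoint

    mask = label_map == RULER
    npix = int(mask.sum())
    if npix == 0:
        raise RulerUnreadableError("ruler class is empty")
    if npix < min_ruler_pixels:
        raise RulerUnreadableError(
            f"ruler region too small ({npix} < {min_ruler_pixels} px)")

    # minimum-area rectangle on the ruler's boundary pixels (col, row)
    boundary = mask & ~ndimage.binary_erosion(mask, structure=EIGHT)
    pts = np.argwhere(boundary)
    rect = MultiPoint([(c, r) for r, c in pts]).minimum_rotated_rectangle
    corners = np.asarray(rect.exterior.coords)[:4]           # (x=col, y=row)
    e1 = corners[1] - corners[0]
    e2 = corners[2] - corners[1]
    long_edge = e1 if np.linalg.norm(e1) >= np.linalg.norm(e2) else e2
    u = long_edge / np.linalg.norm(long_edge)
    rect_angle = float(np.arctan2(u[1], u[0]))

    gray = image.mean(axis=2) if image.ndim == 3 else image.astype(float)
    vals = gray[mask]
    if vals.max() - vals.min() < 1e-9:
        raise RulerUnreadableError("ruler region has uniform intensity")
    t = threshold_otsu(vals)
    dark = vals < t
    marker = dark if dark.sum() <= (~dark).sum() else ~dark   # ticks are minority
    coords = np.argwhere(mask)[marker]                        # (row, col)
    proj = coords[:, 1] * u[0] + coords[:, 0] * u[1]
    if proj.size < 10:
        raise RulerUnreadableError("too few marker pixels after binarization")

    sd = float(np.std(proj))
    silverman = 0.9 * sd * proj.size ** (-0.2) if sd > 0 else 1.0
    bw = min(max(silverman, 0.5), min_expected_pitch / 2.0)
    kde = gaussian_kde(proj, bw_method=bw / max(sd, 1e-9))
    grid = np.arange(proj.min() - 2.0, proj.max() + 2.0, 0.5)
    dens = kde(grid)
    peaks, _ = find_peaks(dens, prominence=crest_prominence * dens.max())
    # parabolic sub-grid refinement of each crest position
    crests = []
    for i in peaks:
        if 0 < i < len(grid) - 1:
            denom = dens[i - 1] - 2.0 * dens[i] + dens[i + 1]
            off = 0.5 * (dens[i - 1] - dens[i + 1]) / denom if denom != 0 else 0.0
            crests.append(grid[i] + np.clip(off, -1.0, 1.0) * (grid[1] - grid[0]))
        else:
            crests.append(grid[i])
    crests = np.asarray(crests)
    if crests.size < 2:
        raise RulerUnreadableError("ruler unreadable: fewer than 2 crests")
    spacing = float(np.median(np.diff(np.sort(crests))))
    if tick_unit == "cm":
        ppcm = spacing
    elif tick_unit == "mm":
        ppcm = spacing * 10.0
    else:
        raise ValueError("tick_unit must be 'cm' or 'mm'")
    return RulerScale(pixels_per_cm=ppcm,
                      crest_positions=[float(c) for c in crests],
                      rect_angle=rect_angle)


# ---------------------------------------------------------------------------
# step 3: caliper axes


def disc_axes(disc_mask: np.ndarray, angular_step_deg: float = 1.0
              ) -> tuple[float, float, float]:
    """Long/short axis of a mask as caliper (Feret) widths.

    Returns ``(long_axis_px, short_axis_px, long_axis_angle)`` where the
    angle (radians, from the +column axis) is the orientation of the
    widest support-line pair; the short axis is the width perpendicular
    to it.  A single-pixel mask has both axes equal to 1.
    """
    mask = np.asarray(disc_mask, dtype=bool)
    pts = np.argwhere(mask & ~ndimage.binary_erosion(mask, structure=EIGHT))
    if pts.shape[0] == 0:
        pts = np.argwhere(mask)
    if pts.shape[0] == 0:
        raise ValueError("empty mask")
    angles = np.deg2rad(np.arange(0.0, 180.0, angular_step_deg))
    dirs = np.stack([np.sin(angles), np.cos(angles)])        # (row, col) rows
    proj = pts.astype(float) @ dirs                          # N x n_angles
    widths = proj.max(axis=0) - proj.min(axis=0) + 1.0       # pixel extent
    i = int(np.argmax(widths))
    long_axis = float(widths[i])
    j = int(round(i + 90.0 / angular_step_deg)) % len(angles)
    short_axis = float(widths[j])
    return long_axis, short_axis, float(angles[i])


# ---------------------------------------------------------------------------
# step 4: margin distance


def margin_distance(point: tuple[float, float], disc_mask: np.ndarray
                    ) -> tuple[float, tuple[int, int]]:
    """Distance from a point to the nearest disc-boundary pixel.

    Ties are broken toward the smallest row, then the smallest column.
    """
    mask = np.asarray(disc_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    # 4-connected erosion: boundary pixels have a face-neighbor outside,
    # keeping the boundary band one pixel thin
    boundary = mask & ~ndimage.binary_erosion(mask)
    pts = np.argwhere(boundary)
    d = np.linalg.norm(pts - np.asarray(point, dtype=float), axis=1)
    dmin = d.min()
    tied = pts[np.isclose(d, dmin)]
    best = tied[np.lexsort((tied[:, 1], tied[:, 0]))][0]
    return float(dmin), (int(best[0]), int(best[1]))


# ---------------------------------------------------------------------------
# step 5: categorization


def categorize_insertion(ratio_or_meas, thresholds: CategoryThresholds | None = None
                         ) -> str:
    """3-way insertion category from the normalized margin-distance ratio.

    marginal if ratio < t_marginal; central if ratio >= t_central
    (boundary assigned upward); eccentric otherwise.
    """
    thresholds = thresholds or CategoryThresholds()
    ratio = ratio_or_meas.ratio if isinstance(ratio_or_meas, InsertionMeasurement) \
        else float(ratio_or_meas)
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    if ratio < thresholds.t_marginal:
        return "marginal"
    if ratio >= thresholds.t_central:
        return "central"
    return "eccentric"


_CATEGORIES = ("marginal", "eccentric", "central")


def fit_thresholds(labeled_ratios: list[tuple[float, str]]) -> CategoryThresholds:
    """Exhaustive threshold-pair search maximizing 3-class accuracy.

    Candidate thresholds are midpoints of adjacent sorted unique ratios
    (plus extremes); ties resolve to the lexicographically smallest
    (t_marginal, t_central) pair.
    """
    if not labeled_ratios:
        raise ValueError("no labeled ratios")
    for _, cat in labeled_ratios:
        if cat not in _CATEGORIES:
            raise ValueError(f"unknown category {cat!r}")
    vals = np.array([v for v, _ in labeled_ratios], dtype=float)
    cats = np.array([_CATEGORIES.index(c) for _, c in labeled_ratios])
    present = set(cats.tolist())
    if len(present) < 3:
        warnings.warn("not all three categories present; degenerate thresholds",
                      stacklevel=2)
    order = [np.mean(vals[cats == c]) for c in range(3) if (cats == c).any()]
    if any(b < a for a, b in zip(order, order[1:])):
        warnings.warn("category ordering violated in the training ratios",
                      stacklevel=2)
    uniq = np.unique(vals)
    eps = 1e-9
    cand = np.concatenate([[uniq[0] - eps], (uniq[:-1] + uniq[1:]) / 2.0,
                           [uniq[-1] + eps]])
    best = None
    best_acc = -1.0
    for i, t1 in enumerate(cand):
        for t2 in cand[i + 1:]:
            pred = np.where(vals < t1, 0, np.where(vals >= t2, 2, 1))
            acc = float(np.mean(pred == cats))
            if acc > best_acc:
                best, best_acc = (t1, t2), acc
    return CategoryThresholds(t_marginal=float(best[0]), t_central=float(best[1]))


def px_to_cm(value_px: float, scale: RulerScale) -> float:
    return float(value_px) / scale.pixels_per_cm


# ---------------------------------------------------------------------------
# composed measurement


def measure_insertion(label_map: np.ndarray,
                      insertion_point: tuple[float, float],
                      scale: RulerScale | None = None,
                      thresholds: CategoryThresholds | None = None,
                      disc_mask: np.ndarray | None = None) -> InsertionMeasurement:
    """Run steps (1) and (3)-(5) for one scene.

    The margin distance and axes are measured on the recovered
    (unoccluded) disc.  Centimeter fields are filled when a ruler scale
    is supplied.
    """
    if disc_mask is None:
        disc_mask = recover_disc(label_map)
    long_px, short_px, _ = disc_axes(disc_mask)
    dist_px, margin_pt = margin_distance(insertion_point, disc_mask)
    ratio = dist_px / ((long_px + short_px) / 2.0)
    if ratio > 0.5:
        warnings.warn(f"ratio {ratio:.3f} exceeds 0.5; non-convex disc or "
                      "exterior insertion point", stacklevel=2)
    meas = InsertionMeasurement(
        insertion_point=(float(insertion_point[0]), float(insertion_point[1])),
        margin_point=margin_pt,
        margin_distance_px=dist_px,
        long_axis_px=long_px, short_axis_px=short_px,
        ratio=float(ratio),
        category=categorize_insertion(ratio, thresholds),
    )
    if scale is not None:
        meas.margin_distance_cm = px_to_cm(dist_px, scale)
        meas.long_axis_cm = px_to_cm(long_px, scale)
        meas.short_axis_cm = px_to_cm(short_px, scale)
    return meas
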