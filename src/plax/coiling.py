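"""Cord coiling quantification from the cord mask and photo.

A hypercoiled umbilical cord shows closely spaced helical coils; in a
photo each coil leaves a visible *fold crevice* — a short dark groove
crossing a cord boundary roughly perpendicular to the cord axis.  The
coiling analysis:

1.  extracts the cord's central skeleton (ordered, pruned to its
    longest path, extended to the cord ends) and the two boundary
    polylines;
2.  finds candidate crevices with Canny edge detection restricted to
    the cord interior, rejecting segments that are very short, that
    geometrically cross an already accepted segment, or whose
    orientation is within ``min_angle`` of the local skeleton tangent;
3.  counts coils with a spacing rule that avoids double-counting when
    one crevice yields several edge segments: walking along the
    boundary, a segment is counted only when its entry point is more
    than twice the previous counted segment's boundary span away;
4.  reports the coilness index C = n * 10 / l (coils per ten
    centimeters of cord); a cord is hypercoiled when C >= 4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, Point
from skimage.feature import canny
from skimage.measure import find_contours, label as cc_label
from skimage.morphology import skeletonize

__all__ = [
    "CordGeometry", "CreviceSegment", "CoilResult",
    "cord_geometry", "detect_crevices", "count_coils", "coilness",
    "classify_hypercoiled", "analyze_cord", "HYPERCOIL_THRESHOLD",
]

HYPERCOIL_THRESHOLD = 4.0


@dataclass
class CordGeometry:
    skeleton: np.ndarray          # ordered (row, col) polyline
    boundary_a: np.ndarray        # ordered (row, col) polyline
    boundary_b: np.ndarray
    length_px: float

    def boundary(self, which: int) -> np.ndarray:
        return self.boundary_a if which == 0 else self.boundary_b


@dataclass
class CreviceSegment:
    pixels: np.ndarray                     # (row, col) edge pixels
    e1: tuple[float, float]                # entry point on the near boundary
    e2: tuple[float, float]                # far-boundary hit or deepest point
    e3: tuple[float, float]                # nearest skeleton point
    e4: tuple[float, float]                # perpendicular projection of e2
    boundary_side: int                     # 0 = boundary_a, 1 = boundary_b
    boundary_pos: float                    # arc position of e1 on its boundary
    boundary_span: float                   # T_i = |arc(e1, e4)|
    position: float                        # arc position along the skeleton
    angle_to_skeleton: float               # radians in [0, pi/2]
    length_px: float


@dataclass
class CoilResult:
    segments: list[CreviceSegment]
    counted: list[bool]
    n: int
    length_cm: float | None = None
    coilness: float | None = None
    hypercoiled: bool | None = None


# ---------------------------------------------------------------------------
# skeleton and boundaries


def _longest_path(skel: np.ndarray) -> list[tuple[int, int]]:
    """Longest path through the skeleton's pixel graph via double BFS."""
    pix = [tuple(p) for p in np.argwhere(skel)]
    pset = set(pix)

    def neighbors(p):
        r, c = p
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                q = (r + dr, c + dc)
                if q in pset:
                    yield q

    def bfs(start):
        dist = {start: 0.0}
        prev = {start: None}
        frontier = [start]
        far, fard = start, 0.0
        while frontier:
            nxt = []
            for p in frontier:
                for q in neighbors(p):
                    if q not in dist:
                        step = np.hypot(q[0] - p[0], q[1] - p[1])
                        dist[q] = dist[p] + step
                        prev[q] = p
                        nxt.append(q)
                        if dist[q] > fard:
                            far, fard = q, dist[q]
            frontier = nxt
        return far, prev

    a, _ = bfs(pix[0])
    b, prev = bfs(a)
    path = []
    cur = b
    while cur is not None:
        path.append(cur)
        cur = prev[cur]
    return path


def _arc_lengths(path: np.ndarray) -> np.ndarray:
    if len(path) < 2:
        return np.zeros(len(path))
    steps = np.linalg.norm(np.diff(path.astype(float), axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def _trim_and_extend(path: np.ndarray, mask: np.ndarray,
                     edt: np.ndarray) -> np.ndarray:
    """Replace skeleton end branches with tangent extensions to the rim.

    The raw skeleton of a tube forks near its ends; the longest path
    keeps one diagonal branch per end, biasing the arc length.  Each
    end is trimmed back by the local half-width and then extended along
    the local tangent until it leaves the mask.
    """
    path = path.astype(float)
    H, W = mask.shape
    for _ in range(2):       # handle one end, then flip
        r0 = min(edt[int(path[0, 0]), int(path[0, 1])], len(path) / 3.0)
        arc = _arc_lengths(path)
        k = int(np.searchsorted(arc, r0))
        path = path[k:]
        j = min(max(int(edt[int(path[0, 0]), int(path[0, 1])]), 3), len(path) - 1)
        tangent = path[0] - path[j]
        norm = np.linalg.norm(tangent)
        if norm > 0:
            tangent /= norm
            ext = []
            p = path[0].copy()
            for _i in range(int(3 * edt.max()) + 4):
                p = p + tangent
                ri, ci = int(round(p[0])), int(round(p[1]))
                if not (0 <= ri < H and 0 <= ci < W) or not mask[ri, ci]:
                    break
                ext.append(p.copy())
            if ext:
                path = np.concatenate([np.asarray(ext)[::-1], path], axis=0)
        path = path[::-1]
    return path


def _smooth_path(path: np.ndarray, window: int = 7) -> np.ndarray:
    """Box-filter the path coordinates (endpoints pinned).

    The 8-connected pixel path zigzags around the true centerline and
    overestimates the arc length of curved cords by several percent;
    a small moving average removes the stair-casing.
    """
    if len(path) <= window:
        return path
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(path, ((pad, pad), (0, 0)), mode="edge")
    sm = np.stack([np.convolve(padded[:, i], kernel, mode="valid")
                   for i in (0, 1)], axis=1)
    sm[0], sm[-1] = path[0], path[-1]
    return sm


def cord_geometry(cord_mask: np.ndarray) -> CordGeometry:
    """Central skeleton, boundary polylines and arc length of the cord."""
    mask = np.asarray(cord_mask, dtype=bool)
    lab, ncomp = cc_label(mask, connectivity=2, return_num=True)
    if ncomp == 0:
        raise ValueError("empty cord mask")
    if ncomp > 1:
        warnings.warn(f"cord mask has {ncomp} components; using the largest",
                      stacklevel=2)
        sizes = np.bincount(lab.ravel())[1:]
        mask = lab == (int(np.argmax(sizes)) + 1)
    edt = ndimage.distance_transform_edt(mask)
    if edt.max() < 1.5:
        raise ValueError("cord narrower than 3 px; skeleton unreliable")
    skel = skeletonize(mask)
    path = np.asarray(_longest_path(skel), dtype=float)
    path = _trim_and_extend(path, mask, edt)
    path = _smooth_path(path)
    length = float(_arc_lengths(path)[-1])

    # split the mask contour into the two boundary sides at the points
    # nearest to the skeleton endpoints
    contours = find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)[:-1]            # closed; drop repeat
    d0 = np.linalg.norm(contour - path[0], axis=1)
    d1 = np.linalg.norm(contour - path[-1], axis=1)
    i0, i1 = int(np.argmin(d0)), int(np.argmin(d1))
    lo, hi = min(i0, i1), max(i0, i1)
    side1 = contour[lo:hi + 1]
    side2 = np.concatenate([contour[hi:], contour[:lo + 1]], axis=0)
    # orient both sides from path[0] to path[-1]
    def oriented(side):
        if np.linalg.norm(side[0] - path[0]) > np.linalg.norm(side[-1] - path[0]):
            return side[::-1]
        return side
    side1, side2 = oriented(side1), oriented(side2)
    return CordGeometry(skeleton=path, boundary_a=side1, boundary_b=side2,
                        length_px=length)


# ---------------------------------------------------------------------------
# crevice detection


def _principal_direction(pts: np.ndarray) -> np.ndarray:
    c = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - c, full_matrices=False)
    return vt[0]


def detect_crevices(image: np.ndarray, cord_mask: np.ndarray,
                    geometry: CordGeometry, *, sigma: float = 1.2,
                    min_len_frac: float = 0.3, min_angle_deg: float = 30.0,
                    interior_margin: int = 2, link_radius: int = 2,
                    min_gradient: float = 6.0) -> list[CreviceSegment]:
    """Canny-based fold-crevice extraction with the three rejection rules.

    Edges are detected inside the cord only (the mask is eroded by
    ``interior_margin`` px so the cord silhouette itself does not
    fire).  Canny thresholds adapt to the cord: high = 90th percentile
    of gradient magnitude within the cord, floored at ``min_gradient``
    gray-levels/px so a featureless cord yields no edges; low =
    0.4 * high.  Surviving segments are ordered by entry position along
    the boundary.
    """
    mask = np.asarray(cord_mask, dtype=bool)
    gray = image.mean(axis=2) if image.ndim == 3 else image.astype(float)
    interior = ndimage.binary_erosion(mask, iterations=interior_margin)
    if not interior.any():
        return []
    gy, gx = np.gradient(gray)
    gmag = np.hypot(gx, gy)[interior]
    high = max(float(np.percentile(gmag, 90.0)), min_gradient)
    edges = canny(gray, sigma=sigma, low_threshold=0.4 * high,
                  high_threshold=high, mask=interior)
    # link nearby edge pixels into segments: the two flanks of one groove
    # must land in the same segment even when Canny leaves a small gap
    linked = ndimage.binary_dilation(edges, iterations=link_radius)
    lab, ncomp = cc_label(linked, connectivity=2, return_num=True)
    lab = np.where(edges, lab, 0)
    edt = ndimage.distance_transform_edt(mask)
    skel = geometry.skeleton
    skel_arc = _arc_lengths(skel)
    lines = {0: LineString([(r, c) for r, c in geometry.boundary_a]),
             1: LineString([(r, c) for r, c in geometry.boundary_b])}

    candidates: list[CreviceSegment] = []
    for i in range(1, ncomp + 1):
        pts = np.argwhere(lab == i).astype(float)
        if len(pts) < 2:
            continue
        # nearest skeleton point (e3) and the local tangent there
        dmat = np.linalg.norm(skel[None, :, :] - pts[:, None, :], axis=2)
        pi, si = np.unravel_index(np.argmin(dmat), dmat.shape)
        e3 = tuple(skel[si])
        j0, j1 = max(si - 4, 0), min(si + 4, len(skel) - 1)
        tangent = skel[j1] - skel[j0]
        tangent = tangent / (np.linalg.norm(tangent) + 1e-12)
        direction = _principal_direction(pts)
        cosang = abs(float(np.dot(direction, tangent)))
        angle = float(np.arccos(np.clip(cosang, 0.0, 1.0)))
        local_width = 2.0 * float(edt[int(e3[0]), int(e3[1])])
        seg_arc = _arc_lengths(pts[np.argsort(pts @ direction)])
        seg_len = float(np.linalg.norm(
            pts[np.argmax(pts @ direction)] - pts[np.argmin(pts @ direction)]))
        # filter (i): too short; filter (iii): too parallel to the skeleton
        if seg_len < min_len_frac * local_width:
            continue
        if angle < np.deg2rad(min_angle_deg):
            continue
        # near boundary and entry point e1
        d_a = lines[0].distance(Point(tuple(pts.mean(axis=0))))
        d_b = lines[1].distance(Point(tuple(pts.mean(axis=0))))
        dists_a = [lines[0].distance(Point(tuple(p))) for p in pts[:: max(len(pts)//8, 1)]]
        dists_b = [lines[1].distance(Point(tuple(p))) for p in pts[:: max(len(pts)//8, 1)]]
        side = 0 if min(dists_a) <= min(dists_b) else 1
        near, far = lines[side], lines[1 - side]
        near_d = [near.distance(Point(tuple(p))) for p in pts]
        p_entry = pts[int(np.argmin(near_d))]
        e1_pos = float(near.project(Point(tuple(p_entry))))
        e1 = near.interpolate(e1_pos)
        e1 = (float(e1.x), float(e1.y))
        # e2: far-boundary intersection, else the deepest pixel
        far_d = [far.distance(Point(tuple(p))) for p in pts]
        if min(far_d) <= 1.5:
            e2 = tuple(pts[int(np.argmin(far_d))])
        else:
            depth = [float(edt[int(p[0]), int(p[1])]) for p in pts]
            e2 = tuple(pts[int(np.argmax(depth))])
        # e4: project e2 perpendicular to the skeleton onto the near boundary
        perp = np.array([-tangent[1], tangent[0]])
        ray = LineString([tuple(np.asarray(e2) - perp * 4.0 * local_width),
                          tuple(np.asarray(e2) + perp * 4.0 * local_width)])
        hit = ray.intersection(near)
        if hit.is_empty:
            e4_pos = float(near.project(Point(e2)))
        else:
            hp = min(getattr(hit, "geoms", [hit]),
                     key=lambda g: Point(e2).distance(g.centroid))
            e4_pos = float(near.project(hp.centroid))
        e4pt = near.interpolate(e4_pos)
        span = abs(e4_pos - e1_pos)
        candidates.append(CreviceSegment(
            pixels=pts, e1=e1, e2=(float(e2[0]), float(e2[1])), e3=(float(e3[0]), float(e3[1])),
            e4=(float(e4pt.x), float(e4pt.y)), boundary_side=side,
            boundary_pos=e1_pos, boundary_span=float(span),
            position=float(skel_arc[si]),
            angle_to_skeleton=angle, length_px=seg_len))

    # order along the cord via the skeleton arc coordinate: entry points on
    # opposite boundary sides share this parametrization
    candidates.sort(key=lambda s: s.position)
    # filter (ii): drop segments that geometrically cross the previous kept one
    kept: list[CreviceSegment] = []
    for seg in candidates:
        if kept:
            prev = kept[-1]
            l1 = LineString([seg.e1, seg.e2]) if tuple(seg.e1) != tuple(seg.e2) else None
            l2 = LineString([prev.e1, prev.e2]) if tuple(prev.e1) != tuple(prev.e2) else None
            if l1 is not None and l2 is not None and l1.crosses(l2):
                continue
        kept.append(seg)
    return kept


# ---------------------------------------------------------------------------
# counting and coilness


def count_coils(segments: list[CreviceSegment],
                geometry: CordGeometry | None = None) -> CoilResult:
    """Greedy spacing rule: a segment is a new coil only when its entry
    point is more than twice the last counted segment's boundary span
    away (several edge segments from one crevice sit much closer).
    """
    counted: list[bool] = []
    last: CreviceSegment | None = None
    n = 0
    for seg in segments:
        if last is None:
            ok = True
        else:
            d = abs(seg.position - last.position)
            ok = d > 2.0 * last.boundary_span
        counted.append(ok)
        if ok:
            n += 1
            last = seg
    return CoilResult(segments=list(segments), counted=counted, n=n)


def coilness(n: int, length_cm: float) -> float:
    """Coils per ten centimeters: C = n * 10 / l."""
    if length_cm <= 0:
        raise ValueError("cord length must be positive")
    return n * 10.0 / length_cm


def classify_hypercoiled(C: float, threshold: float = HYPERCOIL_THRESHOLD) -> bool:
    """Hypercoiled iff C >= threshold (inclusive boundary)."""
    if C < 0:
        raise ValueError("coilness must be non-negative")
    return C >= threshold


def save_overlay(image: np.ndarray, geometry: CordGeometry,
                 result: CoilResult, path) -> None:
    """Debug overlay: skeleton (green), boundaries (blue/cyan), accepted
    segments (yellow), rejected segments (red)."""
    from PIL import Image, ImageDraw
    img = Image.fromarray(np.asarray(image)).convert("RGB")
    draw = ImageDraw.Draw(img)

    def poly(points, color):
        draw.line([(float(c), float(r)) for r, c in points], fill=color, width=1)

    poly(geometry.skeleton, (0, 220, 0))
    poly(geometry.boundary_a, (60, 60, 255))
    poly(geometry.boundary_b, (0, 200, 255))
    for seg, kept in zip(result.segments, result.counted):
        color = (255, 220, 0) if kept else (255, 40, 40)
        for r, c in seg.pixels:
            draw.point((float(c), float(r)), fill=color)
        draw.ellipse([seg.e1[1] - 2, seg.e1[0] - 2, seg.e1[1] + 2,
                      seg.e1[0] + 2], outline=color)
    img.save(path)


def analyze_cord(image: np.ndarray, cord_mask: np.ndarray,
                 pixels_per_cm: float, **detect_kw) -> CoilResult:
    """Full coiling analysis: geometry, crevices, count, coilness."""
    geom = cord_geometry(cord_mask)
    segs = detect_crevices(image, cord_mask, geom, **detect_kw)
    res = count_coils(segs, geom)
    res.length_cm = geom.length_px / pixels_per_cm
    res.coilness = coilness(res.n, res.length_cm)
    res.hypercoiled = classify_hypercoiled(res.coilness)
    return res
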