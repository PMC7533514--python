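"""Synthetic placenta-scene generator.

Real gross-pathology photos show a roughly elliptical placental disc, an
umbilical cord that partially occludes the disc on its way to the
insertion point, and a ruler laid beside the specimen for scale.  This
module renders simplified scenes with exactly that structure — flat
colors on a uniform background, not photo-realism — together with the
4-class pixel label map (background / disc / cord / ruler) and the full
generative ground truth, so the segmentation network and every
geometric analysis can be exercised and scored without clinical data.

Scene structure
---------------
* Disc: a filled ellipse, optionally perturbed into a star shape by a
  sinusoidal radial modulation (irregular-shape fixtures).
* Cord: a thick curved tube.  On fetal-side scenes it runs from the
  image periphery to the insertion point inside the disc and
  *over-paints* the disc along the way (class 2 wins over class 1),
  emulating the occlusion the disc-recovery step must undo.  On
  maternal-side scenes the cord lies beside the disc without touching
  it.  Coil fold-crevices are drawn as short dark wedges crossing one
  cord boundary, near-perpendicular to the cord axis.
* Ruler: a light rectangle at arbitrary orientation with dark tick
  marks every ``tick_pitch`` pixels along its long edge (one tick per
  centimeter), disjoint from disc and cord.

Class precedence at overlaps is cord > disc > ruler > background.
Rendering is deterministic given the seed, and the label map is a pure
function of :class:`SceneTruth` (``render_label_map``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "BACKGROUND", "DISC", "CORD", "RULER",
    "SceneConfig", "SceneTruth", "Scene", "SceneGenerationError",
    "generate_scene", "degrade_scene", "render_label_map",
    "write_scene", "read_scene",
]

BACKGROUND, DISC, CORD, RULER = 0, 1, 2, 3


class SceneGenerationError(RuntimeError):
    """Raised when the configured objects cannot be placed disjointly."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SceneConfig:
    """Ranges and palette for scene sampling.

    Defaults are tuned for a 768 x 1024 canvas (the working resolution
    for full-frame photos); :meth:`for_size` rescales every length
    proportionally for smaller test canvases.
    """

    height: int = 768
    width: int = 1024
    side: str = "fetal"
    # disc
    semi_axis_a: tuple[float, float] = (150.0, 210.0)
    semi_axis_b: tuple[float, float] = (110.0, 150.0)
    star_amplitude: float = 0.0
    star_points: int = 0
    # cord
    cord_halfwidth: tuple[float, float] = (11.0, 16.0)
    cord_length: tuple[float, float] = (420.0, 640.0)   # outside-disc arc, px
    coil_count: int = 0
    insertion_frac: tuple[float, float] = (0.1, 0.75)   # radial position in disc
    # ruler
    tick_pitch: tuple[float, float] = (20.0, 32.0)
    ruler_short: float = 44.0
    n_ticks: int = 9
    ruler_angle: float | None = None                    # radians; None = random
    # palette (RGB)
    background_rgb: tuple[int, int, int] = (62, 88, 152)
    disc_rgb: tuple[int, int, int] = (150, 62, 66)
    cord_rgb: tuple[int, int, int] = (222, 200, 190)
    ruler_rgb: tuple[int, int, int] = (235, 232, 225)
    tick_rgb: tuple[int, int, int] = (30, 30, 35)
    crevice_rgb: tuple[int, int, int] = (95, 70, 65)

    @classmethod
    def for_size(cls, height: int, width: int, **overrides) -> "SceneConfig":
        """Scale the default geometry to a smaller canvas."""
        if height < 256 or width < 256:
            raise ValueError("image must be at least 256 x 256")
        s = min(height / 768.0, width / 1024.0)
        cfg = cls(height=height, width=width)
        for name in ("semi_axis_a", "semi_axis_b", "cord_halfwidth",
                     "cord_length", "tick_pitch"):
            lo, hi = getattr(cfg, name)
            setattr(cfg, name, (lo * s, hi * s))
        cfg.ruler_short = max(12.0, cfg.ruler_short * s)
        for k, v in overrides.items():
            if not hasattr(cfg, k):
                raise TypeError(f"unknown config field {k!r}")
            setattr(cfg, k, v)
        return cfg

    def validate(self) -> None:
        if self.side not in ("fetal", "maternal"):
            raise ValueError("side must be 'fetal' or 'maternal'")
        if self.height < 256 or self.width < 256:
            raise ValueError("image must be at least 256 x 256")
        if min(self.semi_axis_a[0], self.semi_axis_b[0]) < 30:
            raise ValueError("disc semi-axes must be at least 30 px")
        if not (0.0 <= self.star_amplitude <= 0.5):
            raise ValueError("star_amplitude must lie in [0, 0.5]")


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class SceneTruth:
    """Full generative parameters of one scene (the test oracle)."""

    disc_center: tuple[float, float]          # (row, col)
    disc_semi_axes: tuple[float, float]       # (A, B), A >= B
    disc_inclination: float                   # radians, major axis vs +col
    star_amplitude: float
    star_points: int
    cord_path: list[tuple[float, float]]      # ordered (row, col), tip last
    cord_halfwidth: float
    coil_count: int
    insertion_point: tuple[float, float] | None
    ruler_rect: list[tuple[float, float]]     # 4 corners (row, col)
    tick_pitch: float
    pixels_per_cm_true: float
    side: str
    rng_seed: int
    crevice_anchors: list[tuple[float, float]] = field(default_factory=list)

    # -- analytic oracles ---------------------------------------------------

    def _ellipse_boundary(self, n: int = 32768) -> np.ndarray:
        A, B = self.disc_semi_axes
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        r = 1.0 + self.star_amplitude * np.cos(self.star_points * t)
        x, y = A * r * np.cos(t), B * r * np.sin(t)
        ca, sa = np.cos(self.disc_inclination), np.sin(self.disc_inclination)
        col = self.disc_center[1] + x * ca - y * sa
        row = self.disc_center[0] + x * sa + y * ca
        return np.stack([row, col], axis=1)

    def margin_distance_px(self, point: tuple[float, float] | None = None) -> float:
        """Exact distance from a point to the (unoccluded) disc boundary."""
        if point is None:
            point = self.insertion_point
        if point is None:
            raise ValueError("maternal scene has no insertion point")
        b = self._ellipse_boundary()
        return float(np.min(np.linalg.norm(b - np.asarray(point), axis=1)))

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SceneTruth":
        d = json.loads(text)
        for k in ("disc_center", "disc_semi_axes"):
            d[k] = tuple(d[k])
        if d.get("insertion_point") is not None:
            d["insertion_point"] = tuple(d["insertion_point"])
        d["cord_path"] = [tuple(p) for p in d["cord_path"]]
        d["ruler_rect"] = [tuple(p) for p in d["ruler_rect"]]
        d["crevice_anchors"] = [tuple(p) for p in d.get("crevice_anchors", [])]
        return cls(**d)


@dataclass
class Scene:
    image: np.ndarray        # H x W x 3 uint8
    label_map: np.ndarray    # H x W uint8 in {0..3}
    truth: SceneTruth

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.label_map.shape:
            raise ValueError("image and label map sizes differ")


# ---------------------------------------------------------------------------
# rasterization helpers


def _disc_mask(truth: SceneTruth, shape: tuple[int, int]) -> np.ndarray:
    H, W = shape
    rows, cols = np.mgrid[0:H, 0:W]
    dr = rows - truth.disc_center[0]
    dc = cols - truth.disc_center[1]
    ca, sa = np.cos(truth.disc_inclination), np.sin(truth.disc_inclination)
    x = dc * ca + dr * sa
    y = -dc * sa + dr * ca
    A, B = truth.disc_semi_axes
    rho = np.hypot(x / A, y / B)
    if truth.star_amplitude == 0.0:
        return rho <= 1.0
    theta = np.arctan2(y / B, x / A)
    mod = 1.0 + truth.star_amplitude * np.cos(truth.star_points * theta)
    return rho <= mod


def _polyline_mask(points: np.ndarray, halfwidth: float,
                   shape: tuple[int, int]) -> np.ndarray:
    """Pixels within ``halfwidth`` of a dense polyline (tube raster)."""
    canvas = np.ones(shape, dtype=bool)
    rr = np.clip(np.round(points[:, 0]).astype(int), 0, shape[0] - 1)
    cc = np.clip(np.round(points[:, 1]).astype(int), 0, shape[1] - 1)
    canvas[rr, cc] = False
    dist = ndimage.distance_transform_edt(canvas)
    return dist <= halfwidth


def _densify(points: np.ndarray, step: float = 1.0) -> np.ndarray:
    """Resample a polyline at roughly unit spacing."""
    seg = np.diff(points, axis=0)
    lengths = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(lengths)])
    total = s[-1]
    if total == 0:
        return points[:1]
    t = np.arange(0.0, total, step)
    rows = np.interp(t, s, points[:, 0])
    cols = np.interp(t, s, points[:, 1])
    return np.stack([rows, cols], axis=1)


def _rect_corners(center: np.ndarray, angle: float, long_len: float,
                  short_len: float) -> np.ndarray:
    u = np.array([np.sin(angle), np.cos(angle)])       # long axis (row, col)
    v = np.array([np.cos(angle), -np.sin(angle)])      # short axis
    h, w = long_len / 2.0, short_len / 2.0
    return np.array([center + h * u + w * v, center + h * u - w * v,
                     center - h * u - w * v, center - h * u + w * v])


def _polygon_mask(corners: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    from skimage.draw import polygon
    rr, cc = polygon(corners[:, 0], corners[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def render_label_map(truth: SceneTruth, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Rasterize the 4-class label map from the ground truth alone.

    Precedence at overlaps: cord > disc > ruler > background.
    """
    if shape is None:
        raise ValueError("shape is required")
    labels = np.zeros(shape, dtype=np.uint8)
    labels[_polygon_mask(np.asarray(truth.ruler_rect), shape)] = RULER
    labels[_disc_mask(truth, shape)] = DISC
    path = _densify(np.asarray(truth.cord_path, dtype=float))
    labels[_polyline_mask(path, truth.cord_halfwidth, shape)] = CORD
    return labels


# ---------------------------------------------------------------------------
# scene sampling


def _steer(psi: float, target: float, limit: float) -> float:
    delta = (target - psi) % (2.0 * np.pi)
    if delta > np.pi:
        delta -= 2.0 * np.pi
    return psi + np.clip(delta, -limit, limit)


def _sample_cord_path(rng: np.random.Generator, disc_center: np.ndarray,
                      start: np.ndarray, direction: np.ndarray,
                      length: float, shape: tuple[int, int],
                      margin: float, avoid_radius: float = 0.0) -> np.ndarray:
    """Integrate a gently curving path, avoiding the borders and the disc.

    The first stretch continues straight along ``direction`` so that a
    cord leaving the disc exits roughly radially (as a lifted-aside
    cord does in a staged photo) rather than grazing the disc rim.
    """
    H, W = shape
    pts = [start.copy()]
    psi = np.arctan2(direction[0], direction[1])
    bend_amp = rng.uniform(0.2, 0.7) * rng.choice([-1.0, 1.0])
    bend_freq = rng.uniform(1.0, 2.0)
    step = 2.0
    s_straight = min(0.25 * length, 60.0)
    p = start.copy()
    arc = 0.0
    max_iter = int(4 * length / step) + 8
    for _i in range(max_iter):
        if arc >= length:
            break
        psi_i = psi if arc < s_straight else \
            psi + bend_amp * np.sin(bend_freq * 2.0 * np.pi
                                    * (arc - s_straight) / length)
        d = np.array([np.sin(psi_i), np.cos(psi_i)])
        q = p + step * d
        # gentle anticipatory steering: cord curvature stays well above the
        # cord width so the tube never folds onto itself
        ahead = p + 40.0 * d
        steered = False
        if avoid_radius > 0.0 and (
                np.linalg.norm(p + 20.0 * d - disc_center) < avoid_radius
                or np.linalg.norm(q - disc_center) < avoid_radius):
            away = p - disc_center
            psi = _steer(psi, np.arctan2(away[0], away[1]), 0.05)
            steered = True
        if not (margin < ahead[0] < H - margin and margin < ahead[1] < W - margin) \
                or not (margin < q[0] < H - margin and margin < q[1] < W - margin):
            to_center = np.array([H / 2.0, W / 2.0]) - p
            psi = _steer(psi, np.arctan2(to_center[0], to_center[1]), 0.05)
            steered = True
        if steered:
            d = np.array([np.sin(psi), np.cos(psi)])
            q = p + step * d
            q[0] = np.clip(q[0], margin, H - margin)
            q[1] = np.clip(q[1], margin, W - margin)
        arc += np.linalg.norm(q - p)
        pts.append(q)
        p = q
    return np.asarray(pts)


def _place_ruler(rng: np.random.Generator, occupied: np.ndarray,
                 cfg: SceneConfig, long_len: float) -> np.ndarray:
    H, W = occupied.shape
    blocked = ndimage.binary_dilation(occupied, iterations=8)
    for _ in range(300):
        angle = cfg.ruler_angle if cfg.ruler_angle is not None \
            else rng.uniform(0.0, np.pi)
        center = np.array([rng.uniform(0.12 * H, 0.88 * H),
                           rng.uniform(0.12 * W, 0.88 * W)])
        corners = _rect_corners(center, angle, long_len, cfg.ruler_short)
        if (corners < 4).any() or (corners[:, 0] > H - 4).any() \
                or (corners[:, 1] > W - 4).any():
            continue
        mask = _polygon_mask(corners, (H, W))
        if not (mask & blocked).any():
            return corners
    raise SceneGenerationError(
        "cannot place the ruler disjointly from disc and cord; "
        "reduce object sizes or enlarge the canvas")


def generate_scene(config: SceneConfig | None = None, seed: int = 0) -> Scene:
    """Sample and render one synthetic placenta scene.

    Deterministic for a fixed (config, seed) pair.  Raises
    :class:`SceneGenerationError` when the configured objects cannot be
    placed disjointly.
    """
    cfg = config or SceneConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    H, W = cfg.height, cfg.width

    # --- disc ---------------------------------------------------------------
    A = rng.uniform(*cfg.semi_axis_a)
    B = rng.uniform(*cfg.semi_axis_b)
    A, B = max(A, B), min(A, B)
    incl = rng.uniform(-np.pi / 2.0, np.pi / 2.0)
    halfwidth = rng.uniform(*cfg.cord_halfwidth)
    length = rng.uniform(*cfg.cord_length)
    # keep a cord-wide corridor between the disc and every border
    corridor = 4.0 * halfwidth + 10.0 if cfg.side == "fetal" else 0.0
    margin_needed = A * (1.0 + cfg.star_amplitude) + 6 + corridor
    if 2 * margin_needed > min(H, W):
        raise SceneGenerationError("disc does not fit on the canvas")
    center = np.array([
        rng.uniform(margin_needed, H - margin_needed),
        rng.uniform(margin_needed, max(0.62 * W, margin_needed + 1)),
    ])
    if cfg.side == "fetal":
        frac = rng.uniform(*cfg.insertion_frac)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        ca, sa = np.cos(incl), np.sin(incl)
        ex = A * frac * np.cos(phi)
        ey = B * frac * np.sin(phi)
        insertion = center + np.array([ex * sa + ey * ca, ex * ca - ey * sa])
        u = insertion - center
        if np.linalg.norm(u) < 1.0:
            u = np.array([np.sin(phi), np.cos(phi)])
        u = u / np.linalg.norm(u)
        # walk from the insertion point out of the disc, then onward
        t = 1.0
        while True:
            q = insertion + t * u
            dr, dc = q - center
            x = dc * ca + dr * sa
            y = -dc * sa + dr * ca
            if np.hypot(x / A, y / B) > 1.02 or t > 2.5 * A:
                break
            t += 2.0
        exit_pt = insertion + t * u
        outer = _sample_cord_path(
            rng, center, exit_pt, u, length, (H, W), margin=halfwidth + 4,
            avoid_radius=A * (1.0 + cfg.star_amplitude) + halfwidth + 6)
        inner = _densify(np.stack([insertion, exit_pt]))
        cord_path = np.concatenate([outer[::-1], inner[::-1][1:]], axis=0)
        insertion_tuple = (float(insertion[0]), float(insertion[1]))
    else:
        # maternal: cord beside the disc, never touching it
        for _ in range(200):
            start = np.array([rng.uniform(0.1 * H, 0.9 * H),
                              rng.uniform(0.1 * W, 0.9 * W)])
            u = rng.standard_normal(2)
            u /= np.linalg.norm(u)
            path = _sample_cord_path(rng, center, start, u, length, (H, W),
                                     margin=halfwidth + 4)
            d = np.linalg.norm(path - center, axis=1)
            if d.min() > A * (1.0 + cfg.star_amplitude) + halfwidth + 10:
                cord_path = path
                break
        else:
            raise SceneGenerationError(
                "cannot place a maternal cord clear of the disc")
        insertion_tuple = None

    # --- ruler --------------------------------------------------------------
    pitch = rng.uniform(*cfg.tick_pitch)
    long_len = pitch * cfg.n_ticks + 8
    truth_stub = SceneTruth(
        disc_center=(float(center[0]), float(center[1])),
        disc_semi_axes=(float(A), float(B)), disc_inclination=float(incl),
        star_amplitude=float(cfg.star_amplitude), star_points=int(cfg.star_points),
        cord_path=[(float(r), float(c)) for r, c in cord_path],
        cord_halfwidth=float(halfwidth), coil_count=int(cfg.coil_count),
        insertion_point=insertion_tuple, ruler_rect=[(0.0, 0.0)] * 4,
        tick_pitch=float(pitch), pixels_per_cm_true=float(pitch),
        side=cfg.side, rng_seed=int(seed))
    disc = _disc_mask(truth_stub, (H, W))
    cord = _polyline_mask(_densify(cord_path), halfwidth, (H, W))
    corners = _place_ruler(rng, disc | cord, cfg, long_len)
    truth = dataclasses.replace(
        truth_stub, ruler_rect=[(float(r), float(c)) for r, c in corners])

    # --- crevice anchors (arc positions along the outside-disc cord) --------
    anchors: list[tuple[float, float]] = []
    if cfg.side == "fetal" and cfg.coil_count > 0:
        outer_rev = outer[::-1]                     # tip-to-periphery ordering
        dense = _densify(outer_rev[::-1])           # periphery -> disc entry
        arc = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(dense, axis=0), axis=1))])
        usable_lo, usable_hi = 3.0 * halfwidth, arc[-1] - 3.0 * halfwidth
        if usable_hi - usable_lo < cfg.coil_count * 3.0 * halfwidth:
            raise SceneGenerationError(
                "cord too short for the requested coil count")
        pitch_s = (usable_hi - usable_lo) / cfg.coil_count
        for i in range(cfg.coil_count):
            s = usable_lo + (i + 0.5) * pitch_s + rng.uniform(-0.08, 0.08) * pitch_s
            j = int(np.searchsorted(arc, s))
            anchors.append((float(dense[j, 0]), float(dense[j, 1])))
        truth = dataclasses.replace(truth, crevice_anchors=anchors)

    labels = render_label_map(truth, (H, W))

    # --- image --------------------------------------------------------------
    image = np.empty((H, W, 3), dtype=np.uint8)
    image[:] = cfg.background_rgb
    image[labels == RULER] = cfg.ruler_rgb
    image[labels == DISC] = cfg.disc_rgb
    image[labels == CORD] = cfg.cord_rgb
    _draw_ticks(image, corners, pitch, cfg)
    if anchors:
        _draw_crevices(image, labels, truth, rng, cfg)
    # mild shading so the image is not piecewise-constant
    shade = (8.0 * np.sin(np.linspace(0, 3 * np.pi, W)))[None, :, None]
    image = np.clip(image.astype(np.int16) + shade.astype(np.int16), 0, 255)
    return Scene(image=image.astype(np.uint8), label_map=labels, truth=truth)


def _draw_ticks(image: np.ndarray, corners: np.ndarray, pitch: float,
                cfg: SceneConfig) -> None:
    from skimage.draw import polygon
    H, W = image.shape[:2]
    c0, c1, c2, c3 = corners            # c3->c0 and c2->c1 are the long edges
    u = c0 - c3
    long_len = np.linalg.norm(u)
    u = u / long_len
    v = c2 - c3                          # short-axis direction, edge to edge
    n = int((long_len - 8) // pitch) + 1
    for i in range(n):
        base = c3 + u * (4 + i * pitch)
        tip = base + v * 0.6
        quad = np.array([base + 1.0 * np.array([u[0], u[1]]),
                         base - 1.0 * np.array([u[0], u[1]]),
                         tip - 1.0 * np.array([u[0], u[1]]),
                         tip + 1.0 * np.array([u[0], u[1]])])
        rr, cc = polygon(quad[:, 0], quad[:, 1], shape=(H, W))
        image[rr, cc] = cfg.tick_rgb


def _draw_crevices(image: np.ndarray, labels: np.ndarray, truth: SceneTruth,
                   rng: np.random.Generator, cfg: SceneConfig) -> None:
    """Dark wedges crossing one cord boundary, near-perpendicular to it."""
    from skimage.draw import polygon
    H, W = labels.shape
    path = _densify(np.asarray(truth.cord_path, dtype=float))
    hw = truth.cord_halfwidth
    for (ar, ac) in truth.crevice_anchors:
        j = int(np.argmin(np.linalg.norm(path - np.array([ar, ac]), axis=1)))
        j0, j1 = max(j - 3, 0), min(j + 3, len(path) - 1)
        t = path[j1] - path[j0]
        t = t / (np.linalg.norm(t) + 1e-9)
        nrm = np.array([-t[1], t[0]])                 # left normal
        boundary_pt = path[j] + nrm * hw
        tilt = rng.uniform(np.deg2rad(55), np.deg2rad(72)) * rng.choice([-1, 1])
        d_in = -nrm * np.sin(abs(tilt)) + t * np.cos(abs(tilt)) * np.sign(tilt)
        d_in = d_in / np.linalg.norm(d_in)
        depth = rng.uniform(1.25, 1.55) * hw
        a = boundary_pt + nrm * 1.0
        b = boundary_pt + d_in * depth
        w = 1.6     # wedge: wide mouth tapering toward the deep end
        quad = np.array([a + w * t, a - w * t, b - 0.5 * w * t, b + 0.5 * w * t])
        rr, cc = polygon(quad[:, 0], quad[:, 1], shape=(H, W))
        keep = labels[rr, cc] == CORD
        image[rr[keep], cc[keep]] = cfg.crevice_rgb


def degrade_scene(scene: Scene, noise_sd: float = 0.0, blur_sigma: float = 0.0,
                  seed: int = 0) -> Scene:
    """Add Gaussian blur and pixel noise to the image only.

    Labels and truth are untouched — degradation models camera noise,
    not annotation noise.
    """
    if noise_sd < 0 or blur_sigma < 0:
        raise ValueError("noise_sd and blur_sigma must be non-negative")
    img = scene.image.astype(float)
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=(blur_sigma, blur_sigma, 0))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return Scene(image=img, label_map=scene.label_map, truth=scene.truth)


# ---------------------------------------------------------------------------
# disk I/O


def write_scene(scene: Scene, directory, stem: str) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": directory / f"{stem}.png",
        "labels": directory / f"{stem}_labels.png",
        "truth": directory / f"{stem}_truth.json",
    }
    Image.fromarray(scene.image).save(paths["image"])
    Image.fromarray(scene.label_map, mode="L").save(paths["labels"])
    paths["truth"].write_text(scene.truth.to_json())
    return paths


def read_scene(directory, stem: str) -> Scene:
    directory = Path(directory)
    image = np.asarray(Image.open(directory / f"{stem}.png").convert("RGB"))
    labels = np.asarray(Image.open(directory / f"{stem}_labels.png"))
    truth = SceneTruth.from_json((directory / f"{stem}_truth.json").read_text())
    return Scene(image=image, label_map=labels.astype(np.uint8), truth=truth)
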