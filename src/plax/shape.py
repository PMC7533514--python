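"""Moment-based ellipse fit and shape-irregularity index for disc masks.

A regular placental disc is round or oval; irregular discs (star- or
calabash-shaped) deviate visibly from their best-fit ellipse.  The
irregularity index compares the disc mask with the ellipse fitted from
its zeroth-, first- and second-order image moments:

    I = (n2 + n3) / n1

where ``n1`` is the pixel count of the fitted ellipse, ``n2`` the disc
pixels outside it and ``n3`` the non-disc pixels inside it.  ``I`` is 0
when mask and ellipse raster coincide and grows with shape deviation; a
disc is called irregular when ``I`` exceeds a threshold (default 0.14,
fitted on labeled training data).

Coordinate convention: ``x`` is the column axis, ``y`` the row axis;
moments are evaluated at pixel centers (col + 0.5, row + 0.5); the
inclination ``alpha`` is measured from the +x axis, counterclockwise in
image coordinates, and lies in (-pi/2, pi/2].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MomentSet", "EllipseFit", "IrregularityResult",
    "raw_moments", "fit_ellipse", "rasterize_ellipse", "irregularity",
    "classify_shape", "fit_shape_threshold", "IRREGULARITY_THRESHOLD",
]

IRREGULARITY_THRESHOLD = 0.14


@dataclass(frozen=True)
class MomentSet:
    """Raw moments m_pq (p+q <= 2) and central moments mu_pq (p+q = 2)."""

    m00: float
    m10: float
    m01: float
    m20: float
    m11: float
    m02: float
    mu20: float
    mu11: float
    mu02: float

    @property
    def centroid(self) -> tuple[float, float]:
        """(x_c, y_c) = (m10/m00, m01/m00)."""
        return (self.m10 / self.m00, self.m01 / self.m00)


@dataclass(frozen=True)
class EllipseFit:
    center: tuple[float, float]     # (x_c, y_c) in px
    alpha: float                    # radians in (-pi/2, pi/2]
    semi_axes: tuple[float, float]  # (a, b), a >= b


@dataclass(frozen=True)
class IrregularityResult:
    n1: int
    n2: int
    n3: int

    @property
    def index(self) -> float:
        return (self.n2 + self.n3) / self.n1


def raw_moments(mask: np.ndarray) -> MomentSet:
    """Discrete image moments of a binary mask at pixel centers."""
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask")
    x = cols + 0.5
    y = rows + 0.5
    m00 = float(rows.size)
    m10, m01 = float(x.sum()), float(y.sum())
    m20, m11, m02 = float((x * x).sum()), float((x * y).sum()), float((y * y).sum())
    xc, yc = m10 / m00, m01 / m00
    mu20 = m20 - xc * m10
    mu02 = m02 - yc * m01
    mu11 = m11 - xc * m01
    return MomentSet(m00, m10, m01, m20, m11, m02, mu20, mu11, mu02)


def fit_ellipse(mask: np.ndarray) -> EllipseFit:
    """Best-fit ellipse from the mask's image moments.

    The inclination and axes are evaluated on *central, per-area*
    second moments (mu_pq / m00): for an ideal ellipse these give back
    the true semi-axes, since the per-area central moments of an
    ellipse with semi-axes a >= b are a^2/4 and b^2/4 along its
    principal directions.
    """
    m = raw_moments(mask)
    if m.m00 < 5:
        raise ValueError("mask too small for a second-moment ellipse fit")
    u20, u11, u02 = m.mu20 / m.m00, m.mu11 / m.m00, m.mu02 / m.m00
    disc = np.sqrt((u20 - u02) ** 2 + 4.0 * u11 ** 2)
    if disc < 1e-12:
        alpha = 0.0     # circular: inclination undefined, take 0 by convention
    else:
        alpha = 0.5 * np.arctan2(2.0 * u11, u20 - u02)
    a = np.sqrt(2.0 * (u20 + u02 + disc))
    b = np.sqrt(max(2.0 * (u20 + u02 - disc), 0.0))
    if alpha <= -np.pi / 2:
        alpha += np.pi
    elif alpha > np.pi / 2:
        alpha -= np.pi
    return EllipseFit(center=m.centroid, alpha=float(alpha),
                      semi_axes=(float(a), float(b)))


def rasterize_ellipse(fit: EllipseFit, shape: tuple[int, int]) -> np.ndarray:
    """Pixels whose centers lie inside or on the fitted ellipse."""
    H, W = shape
    x = (np.arange(W) + 0.5)[None, :] - fit.center[0]
    y = (np.arange(H) + 0.5)[:, None] - fit.center[1]
    ca, sa = np.cos(fit.alpha), np.sin(fit.alpha)
    xp = x * ca + y * sa
    yp = -x * sa + y * ca
    a, b = fit.semi_axes
    return (xp / a) ** 2 + (yp / b) ** 2 <= 1.0


def irregularity(mask: np.ndarray, fit: EllipseFit | None = None) -> IrregularityResult:
    """Count mask/ellipse disagreement pixels and form the index I."""
    mask = np.asarray(mask, dtype=bool)
    if fit is None:
        fit = fit_ellipse(mask)
    ell = rasterize_ellipse(fit, mask.shape)
    n1 = int(ell.sum())
    if n1 == 0:
        raise ValueError("fitted ellipse covers no pixels")
    n2 = int((mask & ~ell).sum())
    n3 = int((ell & ~mask).sum())
    return IrregularityResult(n1=n1, n2=n2, n3=n3)


def classify_shape(I: float, threshold: float = IRREGULARITY_THRESHOLD) -> str:
    """'irregular' iff I is strictly larger than the threshold."""
    if I < 0:
        raise ValueError("irregularity index must be non-negative")
    return "irregular" if I > threshold else "regular"


def fit_shape_threshold(labeled: list[tuple[float, str]]) -> float:
    """Accuracy-maximizing threshold over midpoints of sorted I values.

    ``labeled`` holds (I, label) pairs with labels 'regular'/'irregular'.
    Ties favor the smallest threshold.  With a single class present the
    threshold degenerates to an extreme and a warning is emitted.
    """
    if not labeled:
        raise ValueError("no labeled examples")
    values = np.array([v for v, _ in labeled], dtype=float)
    y = np.array([lab == "irregular" for _, lab in labeled])
    if y.all() or (~y).all():
        warnings.warn("only one shape class present; threshold degenerate",
                      stacklevel=2)
        return float(values.min() - 1e-6) if y.all() else float(values.max())
    uniq = np.unique(values)
    candidates = np.concatenate([[uniq[0] - 1e-6],
                                 (uniq[:-1] + uniq[1:]) / 2.0,
                                 [uniq[-1]]])
    best_t, best_acc = candidates[0], -1.0
    for t in candidates:
        acc = np.mean((values > t) == y)
        if acc > best_acc:
            best_t, best_acc = t, acc
    return float(best_t)
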