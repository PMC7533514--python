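"""Training objectives and keypoint heatmap utilities.

Segmentation is trained with a 4-class dice loss on per-pixel softmax
probabilities p(i,j,k) against one-hot ground truth g(i,j,k):

    L = 1 - sum(p * g) / sum(p^2 + g^2)

As printed this form omits the conventional factor 2 in the numerator,
so its minimum at a perfect one-hot prediction is 0.5 rather than 0.
Both behaviors are available via ``variant``: ``"as_printed"`` (default)
and ``"doubled"`` (the conventional dice loss with minimum 0).

The cord insertion point is supervised as a Gaussian heatmap regressed
with an MSE loss at two decoder depths (intermediate supervision); at
inference the point is read off with an argmax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HeatMap",
    "dice_loss_4class",
    "dice_loss_grad",
    "gaussian_heatmap",
    "ip_loss",
    "decode_peak",
    "one_hot",
]

NUM_CLASSES = 4


@dataclass(frozen=True)
class HeatMap:
    """A non-negative H x W response map with its argmax location."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("heatmap must be a non-empty 2-D array")
        object.__setattr__(self, "values", v)

    @property
    def peak_location(self) -> tuple[int, int]:
        return decode_peak(self)


def one_hot(labels: np.ndarray, k: int = NUM_CLASSES) -> np.ndarray:
    """Expand an H x W label map into H x W x k one-hot ground truth."""
    labels = np.asarray(labels)
    if labels.size and (labels.min() < 0 or labels.max() >= k):
        raise ValueError(f"labels outside [0, {k})")
    return np.eye(k, dtype=float)[labels]


def _check_probs(p: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 3:
        raise ValueError("probability map must be H x W x k")
    if (p < -atol).any():
        raise ValueError("probabilities must be non-negative")
    s = p.sum(axis=-1)
    if not np.allclose(s, 1.0, atol=atol):
        raise ValueError("per-pixel probabilities must sum to 1")
    return p


def dice_loss_4class(p: np.ndarray, g: np.ndarray, variant: str = "as_printed") -> float:
    """Multi-class dice loss between a probability map and a label map.

    Parameters
    ----------
    p
        H x W x 4 per-pixel class probabilities (softmax output).
    g
        H x W integer label map, or an H x W x 4 one-hot array.
    variant
        ``"as_printed"`` — numerator ``sum(p*g)`` (minimum 0.5 at a
        perfect prediction); ``"doubled"`` — conventional
        ``2*sum(p*g)`` numerator (minimum 0).
    """
    p = _check_probs(p)
    g = np.asarray(g)
    if g.ndim == 2:
        g = one_hot(g, p.shape[-1])
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs g {g.shape}")
    num = float((p * g).sum())
    den = float((p * p + g * g).sum())
    if variant == "as_printed":
        pass
    elif variant == "doubled":
        num *= 2.0
    else:
        raise ValueError(f"unknown dice variant: {variant!r}")
    return 1.0 - num / den


def dice_loss_grad(p: np.ndarray, g: np.ndarray, variant: str = "as_printed") -> np.ndarray:
    """Analytic gradient of :func:`dice_loss_4class` w.r.t. ``p``.

    With S = sum(p*g) and Q = sum(p^2 + g^2), the loss is 1 - c*S/Q
    (c = 1 or 2), so dL/dp = -c * (g*Q - 2*p*S) / Q^2.
    """
    p = _check_probs(p)
    g = np.asarray(g)
    if g.ndim == 2:
        g = one_hot(g, p.shape[-1])
    c = 2.0 if variant == "doubled" else 1.0
    S = (p * g).sum()
    Q = (p * p + g * g).sum()
    return -c * (g * Q - 2.0 * p * S) / (Q * Q)


def gaussian_heatmap(center: tuple[float, float], sigma: float,
                     shape: tuple[int, int]) -> HeatMap:
    """Unit-peak isotropic Gaussian centered at ``center`` (row, col)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r, c = center
    H, W = shape
    if not (0 <= r < H and 0 <= c < W):
        raise ValueError(f"center {center} outside shape {shape}")
    rows = np.arange(H, dtype=float)[:, None]
    cols = np.arange(W, dtype=float)[None, :]
    values = np.exp(-((rows - r) ** 2 + (cols - c) ** 2) / (2.0 * sigma ** 2))
    return HeatMap(values)


def ip_loss(h_hat_intermediate: HeatMap | np.ndarray,
            h_hat_final: HeatMap | np.ndarray,
            h_intermediate: HeatMap | np.ndarray,
            h_final: HeatMap | np.ndarray | None = None) -> float:
    """Two-head MSE heatmap loss with intermediate supervision.

    The total loss is the sum over the two prediction heads of the
    summed squared residual against the Gaussian ground truth.  The
    ground truth may be supplied once (same resolution for both heads)
    or per head; each prediction must match its target's shape — the
    truth is regenerated, not resized, at coarser head resolutions.
    """
    def arr(h):
        return h.values if isinstance(h, HeatMap) else np.asarray(h, dtype=float)

    g1 = arr(h_intermediate)
    g2 = arr(h_final) if h_final is not None else g1
    total = 0.0
    for pred, truth in ((arr(h_hat_intermediate), g1), (arr(h_hat_final), g2)):
        if pred.shape != truth.shape:
            raise ValueError(f"heatmap shape mismatch: {pred.shape} vs {truth.shape}")
        total += float(((pred - truth) ** 2).sum())
    return total


def decode_peak(h_hat: HeatMap | np.ndarray) -> tuple[int, int]:
    """Argmax location of a heatmap; ties go to smallest row, then col.

    A perfectly flat map is degenerate: (0, 0) is returned with a
    warning.
    """
    v = h_hat.values if isinstance(h_hat, HeatMap) else np.asarray(h_hat)
    if v.size == 0:
        raise ValueError("empty heatmap")
    if np.all(v == v.flat[0]):
        warnings.warn("degenerate heatmap: all values equal", stacklevel=2)
        return (0, 0)
    idx = int(np.argmax(v))  # C order == row-major == documented tie-break
    return (idx // v.shape[1], idx % v.shape[1])
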