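"""Per-channel segmentation: Gaussian blur + Li minimum-cross-entropy threshold.

The threshold is selected by Li's fixed-point iteration on a 256-bin
histogram of the blurred channel scaled to its own min–max range, so the
iteration operates in "gray levels" regardless of the input bit depth, and
the result is mapped back to intensity units. One global threshold is
computed per channel per stack (all z-slices pooled); a per-slice mode is
available for stacks with strong depth-dependent attenuation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

N_GRAY = 256


@dataclass
class BinaryMask:
    """Boolean occupancy of one channel after blur + thresholding."""

    mask: np.ndarray  # (Z, Y, X) bool
    channel: str
    threshold: float
    sigma: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D (Z, Y, X)")

    @property
    def occupied(self) -> int:
        return int(self.mask.sum())


def gaussian_blur(channel: np.ndarray, sigma) -> np.ndarray:
    """Separable Gaussian blur with reflective boundaries; sigma=0 is identity."""
    sigma = tuple(float(s) for s in np.atleast_1d(sigma))
    if len(sigma) == 1:
        sigma = sigma * np.asarray(channel).ndim
    if any(s < 0 for s in sigma):
        raise ValueError("sigma must be >= 0")
    channel = np.asarray(channel, np.float64)
    if all(s == 0 for s in sigma):
        return channel.copy()
    return ndimage.gaussian_filter(channel, sigma=sigma, mode="reflect")


def _gray_histogram(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Quantize to N_GRAY integer gray levels over the min–max range.

    Returns (counts over levels 0..255, vmin, scale) with
    ``intensity = vmin + gray * scale``.
    """
    vmin = float(values.min())
    vmax = float(values.max())
    scale = (vmax - vmin) / (N_GRAY - 1)
    gray = np.rint((values - vmin) / scale).astype(np.intp)
    counts = np.bincount(gray.ravel(), minlength=N_GRAY).astype(np.float64)
    return counts, vmin, scale


def _li_iterate(counts: np.ndarray, tol: float, max_iter: int) -> float:
    """Li–Tam fixed-point iteration on a gray-level histogram.

    Levels are the integers 0..len(counts)-1. Initialized at the histogram
    mean; the update is t_next = (mu_b - mu_a) / (ln mu_b - ln mu_a) with
    mu_b, mu_a the mean levels at or below / above t. Levels are offset by a
    tiny epsilon when taking logs so an all-zero background class is handled.
    """
    levels = np.arange(counts.size, dtype=np.float64)
    total = counts.sum()
    csum = np.cumsum(counts)
    cmoment = np.cumsum(counts * levels)
    eps = 1e-9

    t = float((counts * levels).sum() / total)  # mean gray level
    for _ in range(max_iter):
        idx = min(int(np.floor(t)), counts.size - 2)
        n_b = csum[idx]
        n_a = total - n_b
        if n_b == 0 or n_a == 0:
            # all mass on one side; nudge toward the interior
            t_next = t + (tol if n_b == 0 else -tol)
        else:
            mu_b = cmoment[idx] / n_b + eps
            mu_a = (cmoment[-1] - cmoment[idx]) / n_a + eps
            if abs(mu_b - mu_a) < eps:
                t_next = t
            else:
                t_next = (mu_b - mu_a) / (np.log(mu_b) - np.log(mu_a))
        if abs(t_next - t) < tol:
            t = min(t, t_next)  # tie-break toward the lower threshold
            break
        t = t_next
    return float(np.clip(t, 0.0, counts.size - 1))


def cross_entropy(counts: np.ndarray, t: float) -> float:
    """Li's minimum cross-entropy criterion for a gray-level histogram cut at t.

    ``sum_g count(g) * g * ln(g / mu_class(g))`` with ``mu_class`` the mean
    gray level of the class (below/above the cut) that g falls in. Computed
    with the per-level log ratio rather than the expanded
    ``-(S ln mu)`` form, which cancels catastrophically. Used by tests as an
    exhaustive oracle for the fixed-point iteration.
    """
    levels = np.arange(counts.size, dtype=np.float64) + 1e-9
    below = levels <= t
    out = 0.0
    for cls in (below, ~below):
        n = counts[cls].sum()
        if n == 0:
            continue
        mu = (counts[cls] * levels[cls]).sum() / n
        out += float((counts[cls] * levels[cls] * np.log(levels[cls] / mu)).sum())
    return out


def li_threshold(values, tol: float = 0.5, max_iter: int = 100) -> float:
    """Li minimum-cross-entropy threshold of a collection of intensities.

    Parameters
    ----------
    values
        Array of non-negative intensities (any shape; flattened).
    tol
        Convergence tolerance in gray levels (the histogram bin width);
        default half a gray level.

    Returns
    -------
    The threshold in the units of ``values``; voxels strictly above it are
    foreground.

    Raises
    ------
    ValueError
        If the input is constant (degenerate histogram).
    """
    values = np.asarray(values, np.float64).ravel()
    if values.size == 0:
        raise ValueError("empty input")
    if values.min() == values.max():
        raise ValueError("degenerate histogram: constant input")
    counts, vmin, scale = _gray_histogram(values)
    t_gray = _li_iterate(counts, tol=tol, max_iter=max_iter)
    return vmin + t_gray * scale


def segment_channel(
    stack,
    label: str,
    sigma: tuple[float, float, float] = (0.0, 1.0, 1.0),
    tol: float = 0.5,
    min_contrast: float = 2.0,
) -> BinaryMask:
    """Blur one channel and binarize it at its global Li threshold.

    Two degenerate situations yield an empty mask with a warning rather
    than an error, so batch runs over many species combinations survive
    conditions where one species has vanished:

    * a constant channel (no histogram to threshold);
    * a channel with no real signal, only noise around the background —
      any automatic threshold then just splits the noise in half. The guard
      requires the mean above-threshold intensity to exceed
      ``min_contrast`` times the mean below-threshold intensity; genuine
      fluorescence foreground is many-fold brighter than background, while
      a noise split achieves only a few percent of contrast.
    """
    channel = stack.channel(label)
    blurred = gaussian_blur(channel, sigma)
    empty = BinaryMask(
        mask=np.zeros(channel.shape, bool),
        channel=label,
        threshold=float(blurred.min()),
        sigma=tuple(sigma),
    )
    if blurred.min() == blurred.max():
        warnings.warn(
            f"channel {label!r} is constant; emitting an empty mask",
            RuntimeWarning,
            stacklevel=2,
        )
        return empty
    thr = li_threshold(blurred, tol=tol)
    mask = blurred > thr
    if mask.any() and not mask.all():
        fg_mean = float(blurred[mask].mean())
        bg_mean = float(blurred[~mask].mean())
        if bg_mean > 0 and fg_mean < min_contrast * bg_mean:
            warnings.warn(
                f"channel {label!r}: above/below-threshold contrast "
                f"{fg_mean / bg_mean:.2f} < {min_contrast}; treating the "
                "channel as empty (noise only)",
                RuntimeWarning,
                stacklevel=2,
            )
            return empty
    return BinaryMask(mask=mask, channel=label, threshold=float(thr), sigma=tuple(sigma))


def segment_channel_per_slice(
    stack,
    label: str,
    sigma: tuple[float, float, float] = (0.0, 1.0, 1.0),
    tol: float = 0.5,
) -> BinaryMask:
    """Variant of :func:`segment_channel` with an independent threshold per z-slice."""
    channel = stack.channel(label)
    blurred = gaussian_blur(channel, sigma)
    mask = np.zeros(channel.shape, bool)
    thresholds = []
    for z in range(channel.shape[0]):
        plane = blurred[z]
        if plane.min() == plane.max():
            continue
        thr = li_threshold(plane, tol=tol)
        thresholds.append(thr)
        mask[z] = plane > thr
    thr_repr = float(np.median(thresholds)) if thresholds else float(blurred.min())
    return BinaryMask(mask=mask, channel=label, threshold=thr_repr, sigma=tuple(sigma))
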