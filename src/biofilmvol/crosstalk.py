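"""Bleed-through (crosstalk) calibration and correction.

A fluorophore excited in its own channel also emits into neighbouring
detection channels. For every ordered dye pair the bleed-through is modelled
as a single linear coefficient ``k[source -> target]``: the fraction of the
source channel's signal that appears in the target channel. Coefficients are
calibrated from single-label control stacks — images containing only one
labelled organism — as the mode of the per-voxel ratio

    r = I_unpopulated / I_populated

over the foreground of the populated channel. Mixed-species stacks are then
corrected, by default subtractively (``I_j' = I_j - sum_i k[i->j] I_i``,
clamped at zero), optionally by solving the full linear mixing system.

Two estimator details matter in practice and are configurable:

* the ratio is formed only over voxels where the populated channel exceeds
  its Li threshold — unrestricted per-voxel division is dominated by 0/0
  background noise;
* a per-channel background estimate (the median intensity outside that
  foreground) is subtracted from both channels first; otherwise a camera
  offset ``b`` inflates the estimated coefficient by roughly ``b`` divided
  by the foreground brightness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExperimentConfig, MultiChannelStack
from .segmentation import gaussian_blur, segment_channel


@dataclass
class RatioDistribution:
    """Histogram of per-voxel target/source intensity ratios in a control."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_voxels: int
    source_channel: str  # the populated channel (denominator)
    target_channel: str  # the unpopulated channel (numerator)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, np.float64)
        self.counts = np.asarray(self.counts, np.int64)
        if self.bin_edges.ndim != 1 or self.bin_edges.size != self.counts.size + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")
        if int(self.counts.sum()) != self.n_voxels:
            raise ValueError("n_voxels must equal the summed counts")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class CrosstalkMatrix:
    """``k[i, j]``: fraction of channel-i signal detected in channel j; diag 1."""

    labels: list[str]
    k: np.ndarray
    cap: float = 1.0

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.k = np.asarray(self.k, np.float64)
        c = len(self.labels)
        if self.k.shape != (c, c):
            raise ValueError(f"k must be {c}x{c}")
        if not np.allclose(np.diag(self.k), 1.0):
            raise ValueError("diagonal must be 1")
        off = self.k[~np.eye(c, dtype=bool)]
        if np.any(off < 0) or np.any(off > self.cap):
            raise ValueError(f"off-diagonal coefficients must lie in [0, {self.cap}]")

    @classmethod
    def identity(cls, labels) -> "CrosstalkMatrix":
        return cls(labels=list(labels), k=np.eye(len(labels)))

    def coefficient(self, source: str, target: str) -> float:
        return float(self.k[self.labels.index(source), self.labels.index(target)])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.k, index=self.labels, columns=self.labels)


def ratio_distribution(
    control: MultiChannelStack,
    populated: str,
    unpopulated: str,
    config: ExperimentConfig | None = None,
) -> RatioDistribution:
    """Histogram the per-voxel bleed-through ratio in a single-label control.

    Parameters
    ----------
    control
        Stack in which only `populated` carries true signal.
    populated, unpopulated
        Source (denominator) and target (numerator) channel labels.
    config
        Supplies blur sigma, ratio clipping range, bin count and the
        background-subtraction flag; defaults are used when omitted.
    """
    if populated == unpopulated:
        raise ValueError("populated and unpopulated channels must differ")
    cfg = config or ExperimentConfig(channel_labels=control.channel_labels)
    fg_mask = segment_channel(
        control, populated, sigma=cfg.blur_sigma, tol=cfg.li_tol
    ).mask
    if not fg_mask.any():
        raise ValueError(f"no calibration signal in channel {populated!r}")

    # The ratio is taken on the blurred channels: both are blurred by the
    # same kernel, so the ratio of a noise-free linear mixture is unchanged
    # (still exactly k, even at object edges), while read noise in the
    # per-voxel ratio shrinks by the kernel's averaging.
    pop = gaussian_blur(control.channel(populated), cfg.blur_sigma)
    unpop = gaussian_blur(control.channel(unpopulated), cfg.blur_sigma)
    if cfg.background_subtract:
        bg = ~fg_mask
        if bg.any():
            pop = pop - np.median(pop[bg])
            unpop = unpop - np.median(unpop[bg])

    denom = pop[fg_mask]
    numer = unpop[fg_mask]
    valid = denom > 0
    if not valid.any():
        raise ValueError(f"no calibration signal in channel {populated!r}")
    lo, hi = cfg.ratio_clip
    ratios = np.clip(numer[valid] / denom[valid], lo, hi)
    # Bin centers sit on integer multiples of the bin width (first center at
    # `lo`), so a bleed-free control yields a coefficient of exactly `lo`.
    width = (hi - lo) / cfg.ratio_bins
    edges = lo - width / 2 + width * np.arange(cfg.ratio_bins + 2)
    counts, edges = np.histogram(ratios, bins=edges)
    return RatioDistribution(
        bin_edges=edges,
        counts=counts,
        n_voxels=int(counts.sum()),
        source_channel=populated,
        target_channel=unpopulated,
    )


def crosstalk_coefficient(dist: RatioDistribution) -> float:
    """The mode of the ratio distribution: center of the highest-count bin.

    Ties break toward the lower bin so a flat plateau gives the most
    conservative (smallest) coefficient.
    """
    if dist.n_voxels == 0:
        raise ValueError("empty ratio distribution")
    idx = int(np.argmax(dist.counts))  # argmax returns the first (lowest) max
    return float(dist.bin_centers[idx])


def build_crosstalk_matrix(
    controls: dict[str, MultiChannelStack],
    config: ExperimentConfig | None = None,
) -> CrosstalkMatrix:
    """Calibrate all ordered dye pairs from one single-label control per channel.

    ``controls[label]`` is the stack in which only `label` is populated. All
    controls must share the same channel labels.
    """
    labels = None
    for stack in controls.values():
        if labels is None:
            labels = stack.channel_labels
        elif stack.channel_labels != labels:
            raise ValueError("all control stacks must share channel labels")
    if labels is None:
        raise ValueError("no controls given")
    missing = [lab for lab in labels if lab not in controls]
    if missing:
        raise ValueError(f"missing single-label control for channel(s) {missing}")

    k = np.eye(len(labels))
    for i, src in enumerate(labels):
        for j, tgt in enumerate(labels):
            if i == j:
                continue
            dist = ratio_distribution(controls[src], src, tgt, config)
            k[i, j] = crosstalk_coefficient(dist)
    return CrosstalkMatrix(labels=list(labels), k=k)


def correct_stack(
    stack: MultiChannelStack,
    matrix: CrosstalkMatrix,
    method: str = "subtractive",
) -> MultiChannelStack:
    """Remove bleed-through from a mixed stack.

    ``subtractive`` (default) subtracts each source channel scaled by its
    pairwise coefficient and clamps at zero — consistent with how the
    coefficients were calibrated pair by pair. ``unmix`` solves the full
    linear mixing system ``observed = K^T signal`` per voxel, exact when the
    forward model is exactly linear, and clamps negatives to zero.
    """
    if stack.channel_labels != matrix.labels:
        raise ValueError(
            f"stack channels {stack.channel_labels} do not match "
            f"matrix labels {matrix.labels}"
        )
    obs = stack.intensities.astype(np.float64)
    c = stack.n_channels
    flat = obs.reshape(c, -1)
    if method == "subtractive":
        off = matrix.k.copy()
        np.fill_diagonal(off, 0.0)
        corrected = flat - off.T @ flat
    elif method == "unmix":
        if abs(np.linalg.det(matrix.k)) < 1e-12:
            raise np.linalg.LinAlgError("mixing matrix is singular")
        corrected = np.linalg.solve(matrix.k.T, flat)
    else:
        raise ValueError(f"unknown correction method {method!r}")
    corrected = np.clip(corrected, 0.0, None).reshape(obs.shape)
    return stack.with_intensities(corrected)
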