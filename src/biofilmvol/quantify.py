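"""Biovolume quantities derived from binary occupancy masks.

Segmented voxels are counted per z-slice and in total, normalized to the
slice / stack volume, converted to species composition shares ("cell ratio"
percentages), and summarized across replicates as mean +/- sample SD. A
Welch two-sample t-test compares total biovolumes between conditions, and a
layer-order descriptor summarizes the vertical arrangement of species
(bottom-first ordering, sandwich detection).

Composition shares are volume shares of segmented biovolume, not cell
counts: each channel's occupied voxels divided by the summed occupied voxels
over all channels. Channels are segmented independently, so a voxel may be
claimed by several channels; each claims it in full, and the overlap
fraction is reported for auditing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .segmentation import BinaryMask


@dataclass
class SliceProfile:
    """Occupied-volume fractions of one channel, per z-slice and in total."""

    channel: str
    fractions: np.ndarray  # f_z, occupied/total voxels per slice
    total_fraction: float  # F, occupied/total voxels of the stack
    occupied_voxels: int
    volume_um3: float  # occupied voxels x voxel volume

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, np.float64)

    @property
    def n_slices(self) -> int:
        return self.fractions.size


@dataclass
class CompositionSummary:
    """Per-channel share of the summed segmented biovolume, in percent."""

    labels: list[str]
    shares_percent: np.ndarray
    occupied_voxels: np.ndarray
    overlap_fraction: float  # voxels claimed by >1 channel / voxels claimed by >=1
    all_empty: bool = False

    def share(self, label: str) -> float:
        return float(self.shares_percent[self.labels.index(label)])


@dataclass
class ReplicateSummary:
    """Mean and sample SD of slice profiles over replicate images."""

    channel: str
    n: int
    mean_fractions: np.ndarray
    sd_fractions: np.ndarray
    mean_total: float
    sd_total: float


@dataclass
class ChannelLayerStats:
    """Vertical-placement descriptor for one channel's occupancy."""

    channel: str
    mean_z: float  # occupancy-weighted mean slice index (0 = substratum)
    bottom_share: float  # fraction of the channel's voxels in the bottom third
    mid_share: float
    top_share: float
    sandwich: bool  # bottom and top thirds each exceed the middle third


def slice_profile(
    mask: BinaryMask, voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> SliceProfile:
    """Count occupied voxels per z-slice and normalize to the slice volume."""
    arr = mask.mask
    if arr.size == 0:
        raise ValueError("empty (zero-size) mask")
    per_slice = arr.reshape(arr.shape[0], -1).sum(axis=1)
    slice_voxels = arr.shape[1] * arr.shape[2]
    occupied = int(per_slice.sum())
    dz, dy, dx = voxel_size
    return SliceProfile(
        channel=mask.channel,
        fractions=per_slice / slice_voxels,
        total_fraction=occupied / arr.size,
        occupied_voxels=occupied,
        volume_um3=occupied * dz * dy * dx,
    )


def composition(masks: list[BinaryMask]) -> CompositionSummary:
    """Species composition shares from per-channel occupied voxel counts."""
    if not masks:
        raise ValueError("no masks given")
    shape = masks[0].mask.shape
    if any(m.mask.shape != shape for m in masks):
        raise ValueError("masks must share shape")
    counts = np.array([m.occupied for m in masks], np.float64)
    total = counts.sum()
    claimed = np.sum([m.mask for m in masks], axis=0)
    any_claimed = int((claimed > 0).sum())
    overlap = int((claimed > 1).sum()) / any_claimed if any_claimed else 0.0
    if total == 0:
        shares = np.zeros_like(counts)
        return CompositionSummary(
            labels=[m.channel for m in masks],
            shares_percent=shares,
            occupied_voxels=counts.astype(np.int64),
            overlap_fraction=0.0,
            all_empty=True,
        )
    return CompositionSummary(
        labels=[m.channel for m in masks],
        shares_percent=100.0 * counts / total,
        occupied_voxels=counts.astype(np.int64),
        overlap_fraction=overlap,
    )


def average_replicates(profiles: list[SliceProfile]) -> ReplicateSummary:
    """Mean and sample SD (n-1 denominator) over replicate slice profiles."""
    if len(profiles) < 2:
        raise ValueError("need >= 2 replicates for a sample SD")
    channel = profiles[0].channel
    n_z = profiles[0].n_slices
    if any(p.channel != channel for p in profiles):
        raise ValueError("replicate profiles must be from the same channel")
    if any(p.n_slices != n_z for p in profiles):
        raise ValueError("replicate profiles must share the number of z-slices")
    frac = np.stack([p.fractions for p in profiles])
    totals = np.array([p.total_fraction for p in profiles])
    return ReplicateSummary(
        channel=channel,
        n=len(profiles),
        mean_fractions=frac.mean(axis=0),
        sd_fractions=frac.std(axis=0, ddof=1),
        mean_total=float(totals.mean()),
        sd_total=float(totals.std(ddof=1)),
    )


def compare_volumes(group_a, group_b) -> tuple[float, float]:
    """Welch two-sample t-test on total biovolumes of two conditions.

    Returns ``(t, p)`` with a two-sided p-value. Identical groups with zero
    spread carry no information and are rejected.
    """
    a = np.asarray(group_a, np.float64)
    b = np.asarray(group_b, np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def layer_order(masks: list[BinaryMask]) -> list[ChannelLayerStats]:
    """Order channels bottom-to-top and flag sandwich-like occupancies.

    Each channel gets its occupancy-weighted mean z and the fraction of its
    voxels in the bottom / middle / top thirds of the stack; channels are
    returned sorted by mean z ascending (bottom first). A channel whose
    bottom-third and top-third shares both exceed its middle-third share is
    flagged as a sandwich (it brackets another species). Empty channels are
    omitted from the ordering.
    """
    if not masks:
        raise ValueError("no masks given")
    shape = masks[0].mask.shape
    if any(m.mask.shape != shape for m in masks):
        raise ValueError("masks must share shape")
    if all(m.occupied == 0 for m in masks):
        raise ValueError("all masks are empty")
    n_z = shape[0]
    thirds = np.array_split(np.arange(n_z), 3)
    out = []
    for m in masks:
        if m.occupied == 0:
            continue
        per_slice = m.mask.reshape(n_z, -1).sum(axis=1).astype(np.float64)
        total = per_slice.sum()
        mean_z = float((per_slice * np.arange(n_z)).sum() / total)
        b, mid, t = (float(per_slice[idx].sum() / total) for idx in thirds)
        out.append(
            ChannelLayerStats(
                channel=m.channel,
                mean_z=mean_z,
                bottom_share=b,
                mid_share=mid,
                top_share=t,
                sandwich=b > mid and t > mid,
            )
        )
    out.sort(key=lambda s: s.mean_z)
    return out
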