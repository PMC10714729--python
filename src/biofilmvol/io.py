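"""Reading and writing multichannel confocal z-stacks.

Conventions fixed here and assumed by every downstream module:

* in-memory axis order is always ``(C, Z, Y, X)``;
* ``z = 0`` is the substratum (the attachment surface); z increases toward
  the top of the biofilm;
* intensities are carried as floating point but never rescaled — the raw
  detector range (8- or 16-bit counts) is preserved, because the crosstalk
  ratio is only meaningful when both channels share a scale.

Stacks live in plain multi-page TIFF files; the on-disk axis order is
declared in :class:`ExperimentConfig` (default ``CZYX``) since microscopy
exports disagree on page layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml

_AXES = "CZYX"


@dataclass
class MultiChannelStack:
    """A 4D fluorescence image: one 3D volume per channel.

    Parameters
    ----------
    intensities
        Non-negative array of shape ``(C, Z, Y, X)``.
    channel_labels
        One fluorophore/species name per channel; unique.
    voxel_size
        ``(dz, dy, dx)`` in micrometres.
    """

    intensities: np.ndarray
    channel_labels: list[str]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    z_origin: str = "substratum"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 4:
            raise ValueError(
                f"intensities must be 4D (C, Z, Y, X), got {self.intensities.ndim}D"
            )
        if not np.issubdtype(self.intensities.dtype, np.number):
            raise ValueError("intensities must be numeric")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.intensities.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.intensities.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if min(self.intensities.shape[1:]) < 1:
            raise ValueError("Z, Y, X must all be >= 1")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three strictly positive values")

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.intensities.shape

    def channel(self, label: str) -> np.ndarray:
        """Return the 3D ``(Z, Y, X)`` volume for one channel label."""
        return self.intensities[self.channel_index(label)]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown channel {label!r}; have {self.channel_labels}"
            ) from None

    def with_intensities(self, intensities: np.ndarray) -> "MultiChannelStack":
        return replace(self, intensities=intensities)


@dataclass
class ExperimentConfig:
    """Settings shared by a whole analysis run.

    ``axis_order`` declares the layout of stacks on disk as a permutation of
    ``"CZYX"``. ``blur_sigma`` is the segmentation pre-blur in voxels,
    ``(sz, sy, sx)``; the default blurs in-plane only because confocal z
    sampling is coarser than xy. ``ratio_clip``/``ratio_bins`` control the
    bleed-through ratio histogram.
    """

    channel_labels: list[str] = field(default_factory=list)
    axis_order: str = "CZYX"
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    blur_sigma: tuple[float, float, float] = (0.0, 1.0, 1.0)
    crosstalk_method: str = "subtractive"
    ratio_clip: tuple[float, float] = (0.0, 1.5)
    ratio_bins: int = 256
    background_subtract: bool = True
    li_tol: float = 0.5
    output_dir: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        order = self.axis_order.upper()
        if sorted(order) != sorted(_AXES):
            raise ValueError(f"axis_order must be a permutation of 'CZYX', got {order!r}")
        self.axis_order = order
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if any(s < 0 for s in self.blur_sigma):
            raise ValueError("blur sigma must be >= 0")
        if self.crosstalk_method not in ("subtractive", "unmix"):
            raise ValueError("crosstalk_method must be 'subtractive' or 'unmix'")
        if self.ratio_bins < 1:
            raise ValueError("ratio_bins must be >= 1")
        lo, hi = self.ratio_clip
        if not lo < hi:
            raise ValueError("ratio_clip must be (low, high) with low < high")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("voxel_size", "blur_sigma", "ratio_clip"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "channel_labels": list(self.channel_labels),
            "axis_order": self.axis_order,
            "voxel_size": list(self.voxel_size),
            "blur_sigma": list(self.blur_sigma),
            "crosstalk_method": self.crosstalk_method,
            "ratio_clip": list(self.ratio_clip),
            "ratio_bins": self.ratio_bins,
            "background_subtract": self.background_subtract,
            "li_tol": self.li_tol,
            "output_dir": str(self.output_dir),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def read_stack(path: str | Path, config: ExperimentConfig) -> MultiChannelStack:
    """Read a multi-page TIFF into a ``(C, Z, Y, X)`` stack.

    The file may store a 4D array directly or a flat page sequence; either
    way the layout must match ``config.axis_order``, and the number of
    channel pages must equal ``len(config.channel_labels)``. Axes are
    permuted (never resampled) to the in-memory ``CZYX`` convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    data = tifffile.imread(path)
    order = config.axis_order
    n_c = len(config.channel_labels)
    if n_c < 1:
        raise ValueError("config declares no channels")

    if data.ndim == 3:
        # Flat page sequence: pages iterate over the two leading declared
        # axes; the page count must factor as C * Z.
        n_pages = data.shape[0]
        if n_pages % n_c != 0:
            raise ValueError(
                f"layout mismatch: {n_pages} pages not divisible by C={n_c} "
                f"for declared order {order}"
            )
        lead = order[:2]
        n_z = n_pages // n_c
        first = n_c if lead[0] == "C" else n_z
        second = n_z if lead[0] == "C" else n_c
        data = data.reshape((first, second) + data.shape[1:])
    elif data.ndim != 4:
        raise ValueError(f"expected a 3D page sequence or 4D array, got {data.ndim}D")

    if data.shape[order.index("C")] != n_c:
        raise ValueError(
            f"layout mismatch: axis {order.index('C')} has size "
            f"{data.shape[order.index('C')]}, expected C={n_c}"
        )
    perm = [order.index(a) for a in _AXES]
    data = np.ascontiguousarray(np.transpose(data, perm))
    return MultiChannelStack(
        intensities=data.astype(np.float64, copy=False),
        channel_labels=list(config.channel_labels),
        voxel_size=config.voxel_size,
    )


def write_stack(
    stack: MultiChannelStack,
    path: str | Path,
    axis_order: str = "CZYX",
) -> None:
    """Write a stack as a multi-page TIFF in the given on-disk axis order."""
    order = axis_order.upper()
    if sorted(order) != sorted(_AXES):
        raise ValueError(f"axis_order must be a permutation of 'CZYX', got {order!r}")
    perm = [_AXES.index(a) for a in order]
    data = np.transpose(stack.intensities, perm)
    tifffile.imwrite(Path(path), np.ascontiguousarray(data), photometric="minisblack")


def write_mask_tiff(mask: np.ndarray, path: str | Path) -> None:
    """Export a boolean ``(Z, Y, X)`` mask as an 8-bit 0/255 multi-page TIFF."""
    tifffile.imwrite(
        Path(path), np.asarray(mask, bool) * np.uint8(255), photometric="minisblack"
    )


def channels_as_dict(stack: MultiChannelStack) -> dict[str, np.ndarray]:
    return {lab: stack.intensities[i] for i, lab in enumerate(stack.channel_labels)}


def stack_from_channels(
    channels: Sequence[np.ndarray],
    labels: Sequence[str],
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> MultiChannelStack:
    return MultiChannelStack(
        intensities=np.stack([np.asarray(c, np.float64) for c in channels]),
        channel_labels=list(labels),
        voxel_size=voxel_size,
    )
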