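"""Synthetic multispecies biofilm scenes with exact ground truth.

A scene is a set of per-species boolean occupancy masks on a common
``(Z, Y, X)`` grid (z = 0 at the substratum), built from simple geometric
primitives that mimic the structural phenotypes seen in mixed-species
biofilms: horizontal layers (bottom / middle / top bands at a given fill
density), spherical microcolonies, and hyphae modelled as
persistent-random-walk tubes with optional satellite cells of a second
species attached to the tube surface. With exclusivity on (the default),
species never share a voxel, as in a space-filling community.

The imaging forward model turns occupancy into a multichannel stack the way
a confocal microscope would see it: per-voxel brightness drawn lognormally
around a species mean (expression heterogeneity), a background offset,
linear channel mixing by a known crosstalk matrix, an anisotropic Gaussian
PSF blur, additive Gaussian (optionally Poisson) noise, and clipping at
zero. Mixing is applied before the blur: fluorophore emissions mix at
detection while the blur is optical. Every random draw flows from an
explicit seed, so scenes and renders reproduce bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import MultiChannelStack
from .quantify import slice_profile
from .segmentation import BinaryMask, gaussian_blur


# --------------------------------------------------------------------------
# scene geometry


@dataclass
class Layer:
    """Horizontal band: slices z_lo..z_hi inclusive, Bernoulli fill density.

    ``y_hi``/``x_hi`` (exclusive, None = full extent) restrict the band to a
    corner rectangle in-plane; this gives exact fractional slice-equivalents
    of occupancy without the sub-resolution speckle a Bernoulli density
    creates (speckle merges under the PSF and is over-segmented).
    """

    z_lo: int
    z_hi: int
    density: float = 1.0
    y_hi: int | None = None
    x_hi: int | None = None

    def __post_init__(self) -> None:
        if self.z_hi < self.z_lo:
            raise ValueError("z_hi must be >= z_lo")
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")


@dataclass
class Microcolonies:
    """Spherical colonies seeded on or near the substratum."""

    count: int
    radius_mean: float = 4.0
    radius_sd: float = 1.0
    z_max: int | None = None  # centers drawn in [0, z_max]

    def __post_init__(self) -> None:
        if self.radius_mean < 1:
            raise ValueError("radius must be >= 1 voxel")


@dataclass
class Hyphae:
    """Persistent-random-walk tubes growing from the substratum upward."""

    count: int
    length: int = 40
    radius: float = 1.5
    satellite_species: str | None = None
    attach_probability: float = 0.3

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1 voxel")


Primitive = Layer | Microcolonies | Hyphae


@dataclass
class SpeciesSpec:
    name: str
    primitives: list = field(default_factory=list)


@dataclass
class SceneSpec:
    shape: tuple[int, int, int]  # (Z, Y, X)
    species: list[SpeciesSpec] = field(default_factory=list)
    exclusive: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ValueError("shape must be (Z, Y, X) with all >= 1")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        n_z = self.shape[0]
        for s in self.species:
            for p in s.primitives:
                if isinstance(p, Layer) and not (0 <= p.z_lo and p.z_hi < n_z):
                    raise ValueError(
                        f"layer [{p.z_lo}, {p.z_hi}] outside grid of {n_z} slices"
                    )


@dataclass
class SceneGroundTruth:
    """Everything the pipeline should recover, known exactly."""

    labels: list[str]
    masks: np.ndarray  # (C, Z, Y, X) bool
    shares_percent: np.ndarray  # true composition, sums to 100 (or 0 if empty)
    profiles: list  # true per-species SliceProfile
    seed: int
    mixing: np.ndarray | None = None  # true crosstalk matrix, set by render()

    def mask(self, label: str) -> np.ndarray:
        return self.masks[self.labels.index(label)]


def _ball(shape, center, radius) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    return (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _grow_hypha(shape, rng, length, radius) -> np.ndarray:
    """Trace one tube by a persistent random walk biased toward +z."""
    n_z, n_y, n_x = shape
    pos = np.array(
        [0.0, rng.uniform(radius, n_y - radius), rng.uniform(radius, n_x - radius)]
    )
    direction = np.array([1.0, 0.0, 0.0])  # start growing straight up
    mask = np.zeros(shape, bool)
    for _ in range(length):
        mask |= _ball(shape, pos, radius)
        # persistent walk: jitter the direction, renormalize, keep +z bias
        direction = direction + rng.normal(0.0, 0.25, size=3)
        direction[0] = abs(direction[0])
        direction /= np.linalg.norm(direction)
        pos = pos + direction
        if not (0 <= pos[0] < n_z):
            break
        pos[1] = np.clip(pos[1], 0, n_y - 1)
        pos[2] = np.clip(pos[2], 0, n_x - 1)
    return mask


def _tube_shell(tube: np.ndarray) -> np.ndarray:
    """Voxels within 1 voxel of the tube surface, outside the tube."""
    from scipy import ndimage

    return ndimage.binary_dilation(tube, iterations=1) & ~tube


def make_scene(spec: SceneSpec) -> SceneGroundTruth:
    """Realize the occupancy masks and exact ground-truth quantities.

    Species are laid down in listed order; with exclusivity on, later species
    cannot claim voxels already occupied, and explicitly overlapping layers
    of different species are rejected up front.
    """
    if spec.exclusive:
        _check_layer_overlap(spec)
    rng = np.random.default_rng(spec.seed)
    n_species = len(spec.species)
    masks = np.zeros((n_species,) + tuple(spec.shape), bool)
    hypha_tubes: dict[str, np.ndarray] = {}
    satellites: list[tuple[str, np.ndarray, float]] = []

    for i, sp in enumerate(spec.species):
        m = np.zeros(spec.shape, bool)
        for prim in sp.primitives:
            if isinstance(prim, Layer):
                band = np.zeros(spec.shape, bool)
                y_hi = prim.y_hi if prim.y_hi is not None else spec.shape[1]
                x_hi = prim.x_hi if prim.x_hi is not None else spec.shape[2]
                if prim.density >= 1.0:
                    band[prim.z_lo : prim.z_hi + 1, :y_hi, :x_hi] = True
                else:
                    band[prim.z_lo : prim.z_hi + 1, :y_hi, :x_hi] = (
                        rng.random((prim.z_hi - prim.z_lo + 1, y_hi, x_hi))
                        < prim.density
                    )
                m |= band
            elif isinstance(prim, Microcolonies):
                z_max = prim.z_max if prim.z_max is not None else spec.shape[0] // 3
                for _ in range(prim.count):
                    r = max(1.0, rng.normal(prim.radius_mean, prim.radius_sd))
                    center = (
                        rng.uniform(0, z_max),
                        rng.uniform(0, spec.shape[1] - 1),
                        rng.uniform(0, spec.shape[2] - 1),
                    )
                    m |= _ball(spec.shape, center, r)
            elif isinstance(prim, Hyphae):
                for _ in range(prim.count):
                    tube = _grow_hypha(spec.shape, rng, prim.length, prim.radius)
                    m |= tube
                    if prim.satellite_species is not None:
                        satellites.append(
                            (prim.satellite_species, tube, prim.attach_probability)
                        )
                hypha_tubes[sp.name] = m.copy()
            else:
                raise TypeError(f"unknown primitive {type(prim).__name__}")
        masks[i] = m

    # satellite cells: occupy the tube shell with the attachment probability
    labels = [s.name for s in spec.species]
    for sat_name, tube, p_attach in satellites:
        if sat_name not in labels:
            raise ValueError(f"satellite species {sat_name!r} not in scene")
        shell = _tube_shell(tube)
        attach = shell & (rng.random(spec.shape) < p_attach)
        masks[labels.index(sat_name)] |= attach

    if spec.exclusive:
        claimed = np.zeros(spec.shape, bool)
        for i in range(n_species):
            masks[i] &= ~claimed
            claimed |= masks[i]

    counts = masks.reshape(n_species, -1).sum(axis=1).astype(np.float64)
    total = counts.sum()
    shares = 100.0 * counts / total if total else np.zeros(n_species)
    profiles = [
        slice_profile(BinaryMask(masks[i], labels[i], threshold=0.0, sigma=(0, 0, 0)))
        for i in range(n_species)
    ]
    return SceneGroundTruth(
        labels=labels,
        masks=masks,
        shares_percent=shares,
        profiles=profiles,
        seed=spec.seed,
    )


def _check_layer_overlap(spec: SceneSpec) -> None:
    seen: list[tuple[str, Layer]] = []
    for sp in spec.species:
        for prim in sp.primitives:
            if not isinstance(prim, Layer):
                continue
            for other_name, other in seen:
                if other_name != sp.name and not (
                    prim.z_hi < other.z_lo or other.z_hi < prim.z_lo
                ):
                    if prim.density >= 1.0 and other.density >= 1.0:
                        raise ValueError(
                            f"exclusive scene: full-density layers of "
                            f"{sp.name!r} and {other_name!r} overlap in z"
                        )
            seen.append((sp.name, prim))


# --------------------------------------------------------------------------
# imaging forward model


@dataclass
class ImagingModel:
    """Linear mixing / blur / noise model mapping occupancy to intensities.

    ``brightness`` is the per-species mean foreground intensity (detector
    counts); ``brightness_cv`` the lognormal coefficient of variation of the
    per-voxel draw (0 disables heterogeneity). ``mixing`` is the true
    crosstalk matrix with unit diagonal, applied before the PSF blur.
    ``noise_sigma`` is additive Gaussian read noise in counts.
    """

    brightness: dict[str, float]
    brightness_cv: float = 0.1
    background: float = 10.0
    mixing: np.ndarray | None = None  # (C, C); None means identity
    psf_sigma: tuple[float, float, float] = (0.0, 1.0, 1.0)
    noise_sigma: float = 0.0
    poisson: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if any(b <= self.background for b in self.brightness.values()):
            raise ValueError("brightness must exceed background")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.mixing is not None:
            self.mixing = np.asarray(self.mixing, np.float64)
            off = self.mixing[~np.eye(self.mixing.shape[0], dtype=bool)]
            if np.any(off < 0):
                raise ValueError("mixing off-diagonals must be >= 0")


def render(
    truth: SceneGroundTruth, model: ImagingModel
) -> tuple[MultiChannelStack, np.ndarray]:
    """Render a scene through the imaging model.

    Returns the observed multichannel stack and the per-channel pre-mixing
    signals (brightness + background, before crosstalk/blur/noise) so tests
    can check each forward-model stage in isolation. Also stamps the true
    mixing matrix onto ``truth.mixing``.
    """
    rng = np.random.default_rng(model.seed)
    n_c = len(truth.labels)
    mixing = np.eye(n_c) if model.mixing is None else model.mixing
    if mixing.shape != (n_c, n_c):
        raise ValueError(
            f"mixing matrix is {mixing.shape}, scene has {n_c} channels"
        )

    shape = truth.masks.shape[1:]
    signals = np.full((n_c,) + shape, float(model.background))
    for i, lab in enumerate(truth.labels):
        mean = model.brightness[lab]
        occ = truth.masks[i]
        n_occ = int(occ.sum())
        if n_occ == 0:
            continue
        if model.brightness_cv > 0:
            s = np.sqrt(np.log1p(model.brightness_cv**2))
            draws = rng.lognormal(np.log(mean) - s**2 / 2, s, size=n_occ)
        else:
            draws = np.full(n_occ, float(mean))
        signals[i][occ] += draws

    # observed_j = sum_i k[i, j] * signal_i
    mixed = np.tensordot(mixing.T, signals, axes=1)
    blurred = np.stack([gaussian_blur(c, model.psf_sigma) for c in mixed])
    noisy = blurred
    if model.poisson:
        noisy = rng.poisson(np.clip(noisy, 0, None)).astype(np.float64)
    if model.noise_sigma > 0:
        noisy = noisy + rng.normal(0.0, model.noise_sigma, size=noisy.shape)
    observed = np.clip(noisy, 0.0, None)

    truth.mixing = mixing
    stack = MultiChannelStack(
        intensities=observed, channel_labels=list(truth.labels)
    )
    return stack, signals


def single_label_control(
    truth: SceneGroundTruth, label: str, model: ImagingModel, seed: int | None = None
) -> MultiChannelStack:
    """Render a control in which only `label` is occupied (other species blanked).

    This is the calibration input: the same imaging model, but one organism.
    """
    idx = truth.labels.index(label)
    masks = np.zeros_like(truth.masks)
    masks[idx] = truth.masks[idx]
    control_truth = SceneGroundTruth(
        labels=list(truth.labels),
        masks=masks,
        shares_percent=np.where(
            np.arange(len(truth.labels)) == idx, 100.0, 0.0
        ),
        profiles=[],
        seed=truth.seed,
    )
    m = model if seed is None else _with_seed(model, seed)
    stack, _ = render(control_truth, m)
    return stack


def _with_seed(model: ImagingModel, seed: int) -> ImagingModel:
    from dataclasses import replace

    return replace(model, seed=seed)


def calibration_controls(
    labels: Sequence[str],
    model: ImagingModel,
    shape: tuple[int, int, int] = (24, 64, 64),
    seed: int = 0,
    slab: tuple[int, int] | None = None,
) -> dict[str, MultiChannelStack]:
    """Standard single-label calibration stacks: one slab per channel.

    Mimics imaging each fluorophore-tagged organism alone — the input the
    crosstalk calibration expects — under the same imaging model as the
    mixed scenes. The organism fills a bottom slab (default: the lower half
    of the grid, leaving background for the threshold to separate).
    Returns ``{label: control stack}``.
    """
    if slab is None:
        slab = (0, shape[0] // 2 - 1)
    controls: dict[str, MultiChannelStack] = {}
    for i, lab in enumerate(labels):
        spec = SceneSpec(
            shape=shape,
            species=[
                SpeciesSpec(l, [Layer(*slab)] if l == lab else [])
                for l in labels
            ],
            seed=seed + i,
        )
        truth = make_scene(spec)
        stack, _ = render(truth, _with_seed(model, seed + 101 * (i + 1)))
        controls[lab] = stack
    return controls


def two_species_share_scene(
    share_a_percent: float,
    labels: tuple[str, str] = ("A", "B"),
    shape: tuple[int, int, int] = (64, 128, 128),
    occupied_slices: int = 50,
    seed: int = 0,
) -> SceneSpec:
    """A stacked-slab scene whose true composition share is set exactly.

    Species A forms the bottom band and B sits directly above; together they
    fill ``occupied_slices`` slice-equivalents of the grid, split
    ``share_a : 100 - share_a``. Fractional slice-equivalents are realized
    as a full-density band restricted to part of the plane (``y_hi``), so
    the ground-truth voxel count is exact and there is no sub-resolution
    speckle for the PSF to smear. A share of 0 gives species A zero
    occupancy (the exclusion phenotype).
    """
    if not 0 <= share_a_percent <= 100:
        raise ValueError("share must be in [0, 100]")
    n_z, n_y, _ = shape
    units_a = share_a_percent / 100.0 * occupied_slices

    def band(z_start: int, units: float) -> tuple[list[Layer], int]:
        prims: list[Layer] = []
        full = int(np.floor(units + 1e-9))
        frac = units - full
        z = z_start
        if full > 0:
            prims.append(Layer(z, z + full - 1, 1.0))
            z += full
        y_hi = int(round(frac * n_y))
        if y_hi > 0:
            prims.append(Layer(z, z, 1.0, y_hi=y_hi))
            z += 1
        return prims, z

    prims_a, z_next = band(0, units_a)
    prims_b, z_end = band(z_next, occupied_slices - units_a)
    if z_end > n_z:
        raise ValueError("occupied_slices does not fit in the grid")
    return SceneSpec(
        shape=shape,
        species=[SpeciesSpec(labels[0], prims_a), SpeciesSpec(labels[1], prims_b)],
        seed=seed,
    )


# --------------------------------------------------------------------------
# presets: reproducible study scenes


_PRESET_SHAPE = (64, 128, 128)


def preset(name: str) -> tuple[SceneSpec, ImagingModel]:
    """Named, fully seeded scene + imaging-model combinations.

    ``dual_layered``
        Two stacked full-density slabs with a 76/24 volume split — distinct
        layer formation of two bacterial species.
    ``dual_sandwich``
        Species A occupies bottom and top bands bracketing species B — the
        triple-layer sandwich phenotype.
    ``dual_hypha``
        Species B grows hyphal tubes from a basal layer; species A forms a
        bottom layer and attaches to the tube surfaces.
    ``triple_layered``
        Three disjoint bands, bottom species first.
    ``exclusion_72h``
        Species A has zero occupancy (completely lysed / outcompeted);
        species B forms a full bottom biofilm.
    """
    shape = _PRESET_SHAPE
    k = np.array([[1.0, 0.05], [0.05, 1.0]])
    dual_model = dict(
        brightness_cv=0.1,
        background=10.0,
        mixing=k,
        psf_sigma=(0.0, 1.0, 1.0),
        noise_sigma=10.0,  # 5% of the 200-count foreground mean
    )
    if name == "dual_layered":
        spec = SceneSpec(
            shape=shape,
            species=[
                SpeciesSpec("A", [Layer(0, 37, 1.0)]),
                SpeciesSpec("B", [Layer(38, 49, 1.0)]),
            ],
            seed=11,
        )
        model = ImagingModel(brightness={"A": 200.0, "B": 200.0}, seed=11, **dual_model)
    elif name == "dual_sandwich":
        spec = SceneSpec(
            shape=shape,
            species=[
                SpeciesSpec("A", [Layer(0, 15, 1.0), Layer(40, 49, 1.0)]),
                SpeciesSpec("B", [Layer(16, 39, 1.0)]),
            ],
            seed=12,
        )
        model = ImagingModel(brightness={"A": 200.0, "B": 200.0}, seed=12, **dual_model)
    elif name == "dual_hypha":
        spec = SceneSpec(
            shape=shape,
            species=[
                SpeciesSpec("A", [Layer(0, 5, 0.6)]),
                SpeciesSpec(
                    "B",
                    [
                        Layer(0, 3, 0.4),
                        Hyphae(
                            count=6,
                            length=50,
                            radius=2.0,
                            satellite_species="A",
                            attach_probability=0.3,
                        ),
                    ],
                ),
            ],
            seed=13,
        )
        model = ImagingModel(brightness={"A": 200.0, "B": 200.0}, seed=13, **dual_model)
    elif name == "triple_layered":
        k3 = np.eye(3)
        k3[k3 == 0] = 0.05
        spec = SceneSpec(
            shape=shape,
            species=[
                SpeciesSpec("A", [Layer(0, 15, 1.0)]),
                SpeciesSpec("B", [Layer(16, 31, 1.0)]),
                SpeciesSpec("C", [Layer(32, 47, 1.0)]),
            ],
            seed=14,
        )
        model = ImagingModel(
            brightness={"A": 200.0, "B": 200.0, "C": 200.0},
            brightness_cv=0.1,
            background=10.0,
            mixing=k3,
            psf_sigma=(0.0, 1.0, 1.0),
            noise_sigma=10.0,
            seed=14,
        )
    elif name == "exclusion_72h":
        spec = SceneSpec(
            shape=shape,
            species=[
                SpeciesSpec("A", []),  # lysed: zero occupancy
                SpeciesSpec("B", [Layer(0, 49, 1.0)]),
            ],
            seed=15,
        )
        model = ImagingModel(brightness={"A": 200.0, "B": 200.0}, seed=15, **dual_model)
    else:
        raise ValueError(f"unknown preset {name!r}")
    return spec, model
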