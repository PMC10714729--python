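import numpy as np
import pytest

from biofilmvol import (
    ImagingModel,
    SceneSpec,
    SpeciesSpec,
    composition,
    layer_order,
    make_scene,
    preset,
    render,
)
from biofilmvol.segmentation import BinaryMask
from biofilmvol.synthetic import (
    Hyphae,
    Layer,
    Microcolonies,
    calibration_controls,
)


def masks_of(truth):
    return [
        BinaryMask(truth.masks[i], lab, threshold=0.0, sigma=(0, 0, 0))
        for i, lab in enumerate(truth.labels)
    ]


class TestMakeScene:
    def test_full_bottom_layer_profile(self):
        spec = SceneSpec(
            shape=(10, 8, 8), species=[SpeciesSpec("A", [Layer(0, 3, 1.0)])]
        )
        truth = make_scene(spec)
        expected = np.array([1.0] * 4 + [0.0] * 6)
        assert np.array_equal(truth.profiles[0].fractions, expected)

    def test_equal_layers_split_50_50(self):
        spec = SceneSpec(
            shape=(10, 8, 8),
            species=[
                SpeciesSpec("A", [Layer(0, 4, 1.0)]),
                SpeciesSpec("B", [Layer(5, 9, 1.0)]),
            ],
        )
        truth = make_scene(spec)
        assert truth.shares_percent == pytest.approx([50.0, 50.0])

    def test_sandwich_spec_flagged_by_layer_order(self):
        spec = SceneSpec(
            shape=(8, 8, 8),
            species=[
                SpeciesSpec("A", [Layer(0, 1, 1.0), Layer(6, 7, 1.0)]),
                SpeciesSpec("B", [Layer(2, 5, 1.0)]),
            ],
        )
        truth = make_scene(spec)
        stats = {s.channel: s for s in layer_order(masks_of(truth))}
        assert stats["A"].sandwich and not stats["B"].sandwich

    def test_truth_shares_equal_composition_of_truth_masks(self, rng):
        spec = SceneSpec(
            shape=(12, 16, 16),
            species=[
                SpeciesSpec("A", [Layer(0, 5, 0.7)]),
                SpeciesSpec("B", [Layer(6, 9, 0.4), Microcolonies(3, 2.0, 0.5)]),
            ],
            seed=9,
        )
        truth = make_scene(spec)
        comp = composition(masks_of(truth))
        assert np.array_equal(truth.shares_percent, comp.shares_percent)

    def test_exclusive_species_are_disjoint(self):
        spec = SceneSpec(
            shape=(12, 16, 16),
            species=[
                SpeciesSpec("A", [Layer(0, 8, 0.8)]),
                SpeciesSpec("B", [Microcolonies(5, 3.0, 0.5)]),
            ],
            seed=1,
        )
        truth = make_scene(spec)
        assert not np.any(truth.masks[0] & truth.masks[1])

    def test_overlapping_exclusive_full_layers_rejected(self):
        spec = SceneSpec(
            shape=(10, 8, 8),
            species=[
                SpeciesSpec("A", [Layer(0, 5, 1.0)]),
                SpeciesSpec("B", [Layer(3, 8, 1.0)]),
            ],
        )
        with pytest.raises(ValueError, match="overlap"):
            make_scene(spec)

    def test_layer_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SceneSpec(shape=(4, 8, 8), species=[SpeciesSpec("A", [Layer(0, 7)])])

    def test_determinism(self):
        spec = SceneSpec(
            shape=(10, 12, 12),
            species=[SpeciesSpec("A", [Layer(0, 6, 0.5)])],
            seed=123,
        )
        assert np.array_equal(make_scene(spec).masks, make_scene(spec).masks)

    def test_subrectangle_layer_gives_exact_partial_occupancy(self):
        spec = SceneSpec(
            shape=(4, 8, 8),
            species=[SpeciesSpec("A", [Layer(0, 1, 1.0, y_hi=4)])],
        )
        truth = make_scene(spec)
        assert truth.masks[0].sum() == 2 * 4 * 8  # two half-slices

    def test_hyphae_grow_from_substratum_with_satellites(self):
        spec = SceneSpec(
            shape=(20, 24, 24),
            species=[
                SpeciesSpec(
                    "fungus",
                    [Hyphae(2, length=15, radius=1.5, satellite_species="bact",
                            attach_probability=0.5)],
                ),
                SpeciesSpec("bact", []),
            ],
            seed=3,
        )
        truth = make_scene(spec)
        tube = truth.mask("fungus")
        sat = truth.mask("bact")
        assert tube[0].any()  # anchored at the substratum
        assert tube.sum() > 0 and sat.sum() > 0
        # satellites sit within one voxel of the tube surface
        from scipy import ndimage

        shell = ndimage.binary_dilation(tube, iterations=1) & ~tube
        assert np.all(shell[sat])


class TestRender:
    @staticmethod
    def _simple_truth():
        spec = SceneSpec(
            shape=(6, 12, 12),
            species=[
                SpeciesSpec("A", [Layer(0, 2, 1.0)]),
                SpeciesSpec("B", [Layer(3, 4, 1.0)]),
            ],
            seed=5,
        )
        return make_scene(spec)

    def test_identity_mixing_no_noise_no_psf_equals_signal(self):
        truth = self._simple_truth()
        model = ImagingModel(
            brightness={"A": 200.0, "B": 150.0},
            brightness_cv=0.0,
            background=5.0,
            psf_sigma=(0, 0, 0),
        )
        stack, signals = render(truth, model)
        assert np.array_equal(stack.intensities, signals)

    def test_linear_mixing_oracle(self):
        """k[A->B]=0.10: channel B = own signal + 0.10 x channel-A signal."""
        truth = self._simple_truth()
        k = np.array([[1.0, 0.10], [0.0, 1.0]])
        model = ImagingModel(
            brightness={"A": 200.0, "B": 150.0},
            brightness_cv=0.0,
            background=5.0,
            mixing=k,
            psf_sigma=(0, 0, 0),
        )
        stack, signals = render(truth, model)
        assert np.allclose(stack.intensities[1], signals[1] + 0.10 * signals[0])
        assert np.allclose(stack.intensities[0], signals[0])
        assert np.array_equal(truth.mixing, k)

    def test_rendering_is_deterministic(self):
        truth = self._simple_truth()
        model = ImagingModel(
            brightness={"A": 200.0, "B": 150.0}, noise_sigma=10.0, seed=77
        )
        s1, _ = render(self._simple_truth(), model)
        s2, _ = render(truth, model)
        assert np.array_equal(s1.intensities, s2.intensities)

    def test_mixing_shape_mismatch_rejected(self):
        truth = self._simple_truth()
        model = ImagingModel(
            brightness={"A": 200.0, "B": 150.0}, mixing=np.eye(3)
        )
        with pytest.raises(ValueError, match="mixing"):
            render(truth, model)

    def test_brightness_must_exceed_background(self):
        with pytest.raises(ValueError, match="background"):
            ImagingModel(brightness={"A": 5.0}, background=10.0)

    def test_noise_free_render_segments_back_to_truth(self):
        """Identity mixing, no PSF, no noise, 40x brightness/background
        separation: segmentation recovers the truth masks exactly."""
        from biofilmvol import segment_channel

        truth = self._simple_truth()
        model = ImagingModel(
            brightness={"A": 200.0, "B": 200.0},
            brightness_cv=0.1,
            background=5.0,
            psf_sigma=(0, 0, 0),
            seed=8,
        )
        stack, _ = render(truth, model)
        for lab in truth.labels:
            mask = segment_channel(stack, lab)
            assert np.array_equal(mask.mask, truth.mask(lab))


class TestPresets:
    def test_exclusion_preset_has_one_empty_species(self):
        spec, model = preset("exclusion_72h")
        truth = make_scene(spec)
        assert truth.masks[0].sum() == 0
        assert truth.masks[1].sum() > 0
        assert truth.shares_percent == pytest.approx([0.0, 100.0])

    def test_sandwich_preset_three_band_geometry(self):
        spec, _ = preset("dual_sandwich")
        truth = make_scene(spec)
        stats = {s.channel: s for s in layer_order(masks_of(truth))}
        assert stats["A"].sandwich

    def test_triple_layered_order(self):
        spec, _ = preset("triple_layered")
        truth = make_scene(spec)
        order = [s.channel for s in layer_order(masks_of(truth))]
        assert order == ["A", "B", "C"]

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            preset("no_such_scene")

    def test_preset_scene_is_reproducible(self):
        spec1, _ = preset("dual_hypha")
        spec2, _ = preset("dual_hypha")
        assert np.array_equal(make_scene(spec1).masks, make_scene(spec2).masks)


class TestCalibrationControls:
    def test_each_control_is_single_label(self):
        model = ImagingModel(
            brightness={"A": 200.0, "B": 200.0},
            brightness_cv=0.0,
            background=0.0,
            psf_sigma=(0, 0, 0),
        )
        controls = calibration_controls(["A", "B"], model, shape=(8, 16, 16), seed=2)
        assert set(controls) == {"A", "B"}
        # only the labelled channel carries signal when mixing is identity
        assert controls["A"].channel("A").max() > 0
        assert controls["A"].channel("B").max() == 0
        assert controls["B"].channel("A").max() == 0
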