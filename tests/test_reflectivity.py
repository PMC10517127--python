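import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from perivasc import (
    EmptyMaskError,
    EnFaceImage,
    InputError,
    Modality,
    ParameterError,
    Quadrant,
    binarize,
    compute_threshold,
    corrected_reflectivity,
    filter_particles,
    mean_reflectivity_on_mask,
    particle_width_um,
    quality_gate,
)

from .oracles import filter_particles_bruteforce, flood_fill_components


class TestComputeThreshold:
    @pytest.mark.parametrize(
        "pixels,expected",
        [
            (np.full((4, 4), 100.0), 100.0),  # SD = 0
            (np.array([0.0, 0.0, 0.0, 200.0]), 250.0),  # mean 50, sample SD 100
            (np.array([10.0, 10.0, 30.0, 30.0]), 43.09401076758503),
        ],
    )
    def test_hand_computed_values(self, pixels, expected):
        assert compute_threshold(pixels) == pytest.approx(expected, abs=1e-9)

    def test_population_sd_option(self):
        # population SD of {0,0,0,200} is 86.6025...; mean 50
        pixels = np.array([0.0, 0.0, 0.0, 200.0])
        expected = 50.0 + 2.0 * np.sqrt(((pixels - 50.0) ** 2).mean())
        assert compute_threshold(pixels, sd_ddof=0) == pytest.approx(expected)

    def test_empty_input_errors(self):
        with pytest.raises(InputError):
            compute_threshold(np.empty((0,)))


class TestBinarize:
    def test_strict_inequality_on_constant(self):
        q = np.full((4, 4), 120.0)
        assert not binarize(q, 120.0).any()

    def test_threshold_above_max_gives_empty(self):
        assert not binarize(np.array([0.0, 0.0, 0.0, 200.0]), 250.0).any()

    def test_checkerboard_split(self):
        q = np.indices((6, 6)).sum(axis=0) % 2 * 255.0
        mask = binarize(q, 127.5)
        assert np.array_equal(mask, q == 255.0)

    def test_nonfinite_threshold_rejected(self):
        with pytest.raises(ParameterError):
            binarize(np.zeros((2, 2)), np.nan)


class TestFilterParticles:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        hss = filter_particles(mask, min_particle_px=3)
        assert hss.particle_count == 0
        assert hss.hss_area_px == 0
        assert not hss.mask.any()

    def test_l_shaped_three_pixel_blob_retained(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1, 1] = mask[2, 1] = mask[2, 2] = True  # 4-connected L
        hss = filter_particles(mask, min_particle_px=3, connectivity=4)
        assert hss.particle_count == 1
        assert hss.hss_area_px == 3
        assert np.array_equal(hss.mask, mask)

    def test_diagonal_pair_is_one_component_under_8conn(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        hss = filter_particles(mask, min_particle_px=3, connectivity=8)
        assert hss.particle_count == 0  # area 2 < 3, removed as one blob
        # under 4-connectivity they are two area-1 components, also removed
        assert filter_particles(mask, 3, connectivity=4).hss_area_px == 0

    def test_min_particle_below_one_rejected(self):
        with pytest.raises(ParameterError):
            filter_particles(np.zeros((2, 2), dtype=bool), min_particle_px=0)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        mask=hnp.arrays(bool, hnp.array_shapes(min_dims=2, max_dims=2, max_side=32)),
        connectivity=st.sampled_from([4, 8]),
        min_px=st.integers(1, 6),
    )
    def test_matches_flood_fill_oracle(self, mask, connectivity, min_px):
        """Size filtering agrees with an explicit BFS flood-fill oracle."""
        hss = filter_particles(mask, min_px, connectivity)
        ref_mask, ref_count = filter_particles_bruteforce(mask, min_px, connectivity)
        assert np.array_equal(hss.mask, ref_mask)
        assert hss.particle_count == ref_count
        assert hss.hss_area_px == ref_mask.sum()


class TestMeanReflectivityOnMask:
    def test_constant_structural(self):
        hss = filter_particles(np.ones((4, 4), dtype=bool))
        assert mean_reflectivity_on_mask(np.full((4, 4), 140.0), hss) == 140.0

    def test_on_off_mask_values(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, :3] = True
        hss = filter_particles(mask)
        struct = np.where(mask, 200.0, 100.0)
        assert mean_reflectivity_on_mask(struct, hss) == 200.0

    def test_random_mask_equals_bruteforce_sum_over_count(self, rng):
        struct = rng.uniform(0, 255, (8, 8))
        mask = rng.random((8, 8)) < 0.5
        hss = filter_particles(mask, min_particle_px=1)
        total = sum(
            struct[y, x] for y in range(8) for x in range(8) if mask[y, x]
        )
        assert mean_reflectivity_on_mask(struct, hss) == pytest.approx(
            total / mask.sum()
        )

    def test_empty_mask_raises_not_nan(self):
        hss = filter_particles(np.zeros((4, 4), dtype=bool))
        with pytest.raises(EmptyMaskError):
            mean_reflectivity_on_mask(np.zeros((4, 4)), hss)


def _mixture_pair(side=40, block=(slice(2, 10), slice(0, 20))):
    """Structural 200 on a Q1 block covering 10% of the image, 100 elsewhere;
    OCTA bright exactly on that block (binarizes to it under image-scope
    threshold statistics)."""
    octa = np.zeros((side, side))
    octa[block] = 255.0
    struct = np.full((side, side), 100.0)
    struct[block] = 200.0
    return (
        EnFaceImage(struct, Modality.STRUCTURAL),
        EnFaceImage(octa, Modality.ANGIOGRAPHY),
    )


class TestCorrectedReflectivity:
    def test_constant_structural_gives_exactly_one(self):
        _, octa = _mixture_pair()
        struct = EnFaceImage(np.full((40, 40), 137.0), Modality.STRUCTURAL)
        res = corrected_reflectivity(struct, octa, Quadrant.Q1, threshold_scope="image")
        assert res.corrected == 1.0

    def test_two_level_mixture_closed_form(self):
        struct, octa = _mixture_pair()
        res = corrected_reflectivity(struct, octa, Quadrant.Q1, threshold_scope="image")
        assert res.hss_area_px == 160  # 10% of 40x40
        assert res.corrected == pytest.approx(200.0 / 110.0, abs=1e-12)

    def test_invariant_under_uniform_structural_gain(self):
        struct, octa = _mixture_pair()
        base = corrected_reflectivity(
            struct, octa, Quadrant.Q1, threshold_scope="image"
        ).corrected
        for k in (0.25, 0.5, 1.275):
            scaled = EnFaceImage(struct.pixels * k, Modality.STRUCTURAL)
            res = corrected_reflectivity(
                scaled, octa, Quadrant.Q1, threshold_scope="image"
            )
            assert abs(res.corrected - base) < 1e-12

    def test_delta_inside_hss_strictly_increases_metric(self):
        struct, octa = _mixture_pair()
        base = corrected_reflectivity(
            struct, octa, Quadrant.Q1, threshold_scope="image"
        )
        bumped_px = struct.pixels.copy()
        bumped_px[octa.pixels == 255.0] += 5.0
        bumped = corrected_reflectivity(
            EnFaceImage(bumped_px, Modality.STRUCTURAL),
            octa,
            Quadrant.Q1,
            threshold_scope="image",
        )
        assert bumped.corrected > base.corrected

    def test_mask_soundness_on_synthetic_pair(self, small_config, rng):
        """Every HSS pixel exceeds the stored threshold and every component
        has at least the minimum particle area (flood-fill recount)."""
        from perivasc.synthetic import generate_vessel_tree, render_pair
        from perivasc.reflectivity import (
            binarize as _bin,
            compute_threshold as _thr,
            filter_particles as _filt,
        )

        vessels = generate_vessel_tree(small_config, rng)
        _, octa, _ = render_pair(vessels, small_config, 0.0, None, rng)
        q = octa.quadrant(Quadrant.Q2).astype(float)
        threshold = _thr(q)
        hss = _filt(_bin(q, threshold), min_particle_px=3, connectivity=8)
        assert np.all(q[hss.mask] > threshold)
        for comp in flood_fill_components(hss.mask, 8):
            assert len(comp) >= 3

    def test_empty_hss_raises(self):
        struct = EnFaceImage(np.full((8, 8), 100.0), Modality.STRUCTURAL)
        octa = EnFaceImage(np.full((8, 8), 50.0), Modality.ANGIOGRAPHY)
        with pytest.raises(EmptyMaskError):
            corrected_reflectivity(struct, octa, Quadrant.Q1)

    def test_modality_mixup_rejected(self):
        struct, octa = _mixture_pair()
        with pytest.raises(InputError):
            corrected_reflectivity(octa, struct, Quadrant.Q1)


class TestQualityGate:
    def test_boundary_and_extremes(self, make_enface):
        img = lambda q: make_enface(np.zeros((4, 4)), quality=q)
        assert quality_gate(img(65.0)) is True
        assert quality_gate(img(64.9)) is False
        assert quality_gate(img(100.0)) is True

    def test_missing_quality_errors(self, make_enface):
        with pytest.raises(InputError):
            quality_gate(make_enface(np.zeros((4, 4))))


class TestParticleWidth:
    @pytest.mark.parametrize(
        "n_px,expected",
        [(3, 28.125), (0, 0.0), (320, 3000.0)],
    )
    def test_nominal_geometry(self, n_px, expected):
        assert particle_width_um(n_px, 3.0, 320) == pytest.approx(expected)

    def test_zero_side_rejected(self):
        with pytest.raises(ParameterError):
            particle_width_um(3, 3.0, 0)
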