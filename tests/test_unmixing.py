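import dataclasses

import numpy as np
import pytest

from qdki67 import (
    EndmemberLibrary,
    drop_autofluorescence,
    simulate_field,
    unmix_cube,
    unmix_pixel,
)
from qdki67.errors import IllConditionedLibraryError, ValidationError
from qdki67.spectral import SpectralCube


def refine_grid_search(y, E, lo=0.0, hi=1.5, levels=(0.1, 0.01, 1e-3)):
    """Independent NNLS oracle: multi-stage grid refinement to 1e-3 resolution.

    Valid because the least-squares objective is convex, so the global
    minimum over [lo, hi]^3 is found by refining around the coarse optimum.
    """
    center = np.full(3, (lo + hi) / 2.0)
    half = (hi - lo) / 2.0
    best = None
    for step in levels:
        axes = [
            np.clip(np.arange(c - half, c + half + step / 2, step), lo, hi)
            for c in center
        ]
        A = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        residuals = np.linalg.norm(A @ E.T - y, axis=1)
        best = A[np.argmin(residuals)]
        center, half = best, 1.5 * step
    return best


class TestUnmixPixel:
    def test_pure_endmember_recovered_exactly(self, library):
        E = library.as_matrix
        abundance, residual = unmix_pixel(E @ np.array([1.0, 0.0, 0.0]), E)
        np.testing.assert_allclose(abundance, [1.0, 0.0, 0.0], atol=1e-12)
        assert residual == pytest.approx(0.0, abs=1e-12)

    def test_zero_spectrum_gives_zero_abundance(self, library):
        abundance, residual = unmix_pixel(np.zeros(21), library.as_matrix)
        np.testing.assert_array_equal(abundance, 0.0)
        assert residual == 0.0

    def test_noise_free_mixture_recovered(self, library):
        E = library.as_matrix
        true = np.array([0.3, 0.5, 0.2])
        abundance, residual = unmix_pixel(E @ true, E)
        np.testing.assert_allclose(abundance, true, atol=1e-6)
        assert residual < 1e-6

    def test_matches_grid_search_oracle_on_random_pixels(self, library, rng):
        E = library.as_matrix
        for _ in range(100):
            true = rng.uniform(0.0, 1.0, 3)
            y = E @ true + rng.normal(0.0, 0.01, 21)
            abundance, _ = unmix_pixel(y, E)
            oracle = refine_grid_search(y, E)
            np.testing.assert_allclose(abundance, oracle, atol=2e-3)

    def test_rank_deficient_library_rejected(self):
        E = np.ones((21, 3))
        with pytest.raises(IllConditionedLibraryError):
            unmix_pixel(np.ones(21), E)

    def test_residual_never_exceeds_input_norm(self, library, rng):
        E = library.as_matrix
        for _ in range(50):
            y = rng.uniform(0, 10, 21)
            _, residual = unmix_pixel(y, E)
            assert residual <= np.linalg.norm(y) + 1e-9


class TestUnmixCube:
    def test_noise_free_field_recovered_everywhere(self, library, small_scene):
        cube, truth = simulate_field(small_scene, library)
        maps = unmix_cube(cube, library)
        np.testing.assert_allclose(maps.ck_map, truth.ck_map, atol=1e-6)
        np.testing.assert_allclose(maps.ki67_map, truth.ki67_map, atol=1e-6)
        np.testing.assert_allclose(maps.residual_map, 0.0, atol=1e-6)

    def test_pure_autofluorescence_yields_no_marker_signal(self, library):
        af = 50.0 * library.autofluorescence.values
        cube = SpectralCube(np.tile(af, (8, 8, 1)), library.grid)
        maps = unmix_cube(cube, library)
        np.testing.assert_allclose(maps.ck_map, 0.0, atol=1e-9)
        np.testing.assert_allclose(maps.ki67_map, 0.0, atol=1e-9)
        np.testing.assert_allclose(maps.af_map, 50.0, atol=1e-9)

    def test_agrees_with_per_pixel_scipy_solver(self, library, rng):
        intensities = rng.uniform(0, 100, size=(6, 7, 21))
        cube = SpectralCube(intensities, library.grid)
        maps = unmix_cube(cube, library)
        E = library.as_matrix
        for row in range(6):
            for col in range(7):
                abundance, residual = unmix_pixel(intensities[row, col], E)
                got = [
                    maps.ck_map[row, col],
                    maps.ki67_map[row, col],
                    maps.af_map[row, col],
                ]
                np.testing.assert_allclose(got, abundance, atol=1e-8)
                assert maps.residual_map[row, col] == pytest.approx(residual, abs=1e-8)

    def test_grid_mismatch_rejected(self, library):
        from qdki67 import WavelengthGrid

        other = SpectralCube(np.zeros((4, 4, 11)), WavelengthGrid(450, 550, 10))
        with pytest.raises(ValidationError):
            unmix_cube(other, library)

    def test_noisy_field_abundance_error_bounded(self, library, small_scene):
        noise_sd = 0.05 * small_scene.ck_amplitude
        params = dataclasses.replace(small_scene, noise_sd=noise_sd)
        cube, truth = simulate_field(params, library)
        maps = unmix_cube(cube, library)
        errors = np.concatenate(
            [
                np.abs(maps.ck_map - truth.ck_map).ravel(),
                np.abs(maps.ki67_map - truth.ki67_map).ravel(),
            ]
        )
        assert errors.mean() < 3 * noise_sd

    def test_permuting_library_columns_permutes_maps(self, library, rng):
        intensities = rng.uniform(0, 50, size=(5, 5, 21))
        cube = SpectralCube(intensities, library.grid)
        maps = unmix_cube(cube, library)
        swapped = EndmemberLibrary(
            ck_525=library.ki67_605,
            ki67_605=library.ck_525,
            autofluorescence=library.autofluorescence,
        )
        maps_swapped = unmix_cube(cube, swapped)
        np.testing.assert_allclose(maps_swapped.ck_map, maps.ki67_map, atol=1e-9)
        np.testing.assert_allclose(maps_swapped.ki67_map, maps.ck_map, atol=1e-9)
        np.testing.assert_allclose(maps_swapped.af_map, maps.af_map, atol=1e-9)


class TestDropAutofluorescence:
    def test_marker_maps_untouched_and_af_zeroed(self, library, small_scene):
        cube, _ = simulate_field(small_scene, library)
        maps = unmix_cube(cube, library)
        dropped = drop_autofluorescence(maps)
        np.testing.assert_array_equal(dropped.ck_map, maps.ck_map)
        np.testing.assert_array_equal(dropped.ki67_map, maps.ki67_map)
        assert np.all(dropped.af_map == 0.0)

    def test_idempotent(self, library, small_scene):
        cube, _ = simulate_field(small_scene, library)
        once = drop_autofluorescence(unmix_cube(cube, library))
        twice = drop_autofluorescence(once)
        np.testing.assert_array_equal(once.af_map, twice.af_map)
        np.testing.assert_array_equal(once.ck_map, twice.ck_map)

    def test_af_only_scene_quantifies_to_zero(self, library):
        from qdki67 import quantify_field

        af = 30.0 * library.autofluorescence.values
        cube = SpectralCube(np.tile(af, (8, 8, 1)), library.grid)
        quant = quantify_field(drop_autofluorescence(unmix_cube(cube, library)))
        assert quant.ki67_signal == pytest.approx(0.0, abs=1e-6)
        assert quant.ck_signal == pytest.approx(0.0, abs=1e-6)
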