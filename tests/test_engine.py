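"""Single-pixel acquisition, four-step assembly, and reconstruction."""

import numpy as np
import pytest

from fsisfdi import (
    ReconConfig,
    SFDISpec,
    acquire_spectrum,
    circular_mask,
    four_step_coefficient,
    full_mask,
    make_smooth_tissue_scene,
    measure,
    reconstruct_cs_tv,
    reconstruct_ifft,
)
from fsisfdi.engine import Spectrum, load_spectrum, save_spectrum
from fsisfdi.patterns import PatternSpec, SamplingMask, fourier_basis_pattern


class TestMeasure:
    def test_uniform_pattern_sums_the_object(self, rng):
        obj = rng.random((8, 8))
        assert measure(obj, np.ones((8, 8))).value == pytest.approx(obj.sum())

    def test_delta_object_samples_the_pattern(self, rng):
        pat = rng.random((8, 8))
        obj = np.zeros((8, 8))
        obj[3, 5] = 1.0
        assert measure(obj, pat).value == pytest.approx(pat[3, 5])

    def test_linearity_in_the_pattern(self, rng):
        obj, p1, p2 = rng.random((3, 8, 8))
        lhs = measure(obj, p1 + p2).value
        rhs = measure(obj, p1).value + measure(obj, p2).value
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            measure(np.ones((4, 4)), np.ones((4, 5)))


class TestFourStepCoefficient:
    def test_equal_readings_cancel(self):
        assert four_step_coefficient(3.3, 3.3, 3.3, 3.3) == 0

    def test_delta_object_gives_phase_ramp(self):
        # brute-force four-step on a point scatterer matches 2b*exp(-j*theta)
        M = N = 8
        a, b = 0.5, 0.5
        x0, y0 = 2, 5
        obj = np.zeros((M, N))
        obj[x0, y0] = 1.0
        for fx, fy in [(1, 0), (2, 3), (0, 1)]:
            readings = [
                measure(obj, fourier_basis_pattern(PatternSpec(a, b, fx, fy, ph, M, N))).value
                for ph in (0, np.pi / 2, np.pi, 3 * np.pi / 2)
            ]
            coeff = four_step_coefficient(*readings)
            theta = 2 * np.pi * (fx * x0 / M + fy * y0 / N)
            assert coeff == pytest.approx(2 * b * np.exp(-1j * theta), abs=1e-12)

    def test_constant_object_dc_coefficient(self, rng):
        obj = np.full((8, 8), 0.7)
        a, b = 0.5, 0.4
        readings = [
            measure(obj, fourier_basis_pattern(PatternSpec(a, b, 0, 0, ph, 8, 8))).value
            for ph in (0, np.pi / 2, np.pi, 3 * np.pi / 2)
        ]
        coeff = four_step_coefficient(*readings)
        assert coeff == pytest.approx(2 * b * obj.sum(), abs=1e-9)


class TestAcquireSpectrum:
    def test_four_step_assembly_equals_fft_oracle(self, rng):
        mask = full_mask((16, 16))
        for _ in range(5):
            obj = rng.random((16, 16))
            spec = acquire_spectrum(obj, mask)
            oracle = 2 * 0.5 * np.fft.fft2(obj)
            err = np.abs(spec.grid - oracle).max() / np.abs(oracle).max()
            assert err <= 1e-6

    def test_bucket_path_matches_fft_path(self, rng):
        obj = rng.random((8, 8))
        mask = circular_mask((8, 8), 48)
        sfdi = SFDISpec(0.2, 0.5, 0.5)
        for illum in (None, sfdi):
            fast = acquire_spectrum(obj, mask, sfdi=illum, method="fft")
            slow = acquire_spectrum(obj, mask, sfdi=illum, method="bucket")
            assert np.allclose(fast.grid, slow.grid, rtol=1e-9, atol=1e-9)

    def test_pattern_mean_does_not_affect_the_spectrum(self, rng):
        # the a term cancels in the four-step differences
        obj = rng.random((16, 16))
        mask = circular_mask((16, 16), 120)
        s1 = acquire_spectrum(obj, mask, a=0.5, b=0.4, method="bucket")
        s2 = acquire_spectrum(obj, mask, a=0.3, b=0.4, method="bucket")
        scale = np.abs(s1.grid).max()
        assert np.allclose(s1.grid, s2.grid, atol=1e-9 * scale)

    def test_conjugate_symmetry_exact(self, rng):
        obj = rng.random((12, 10))
        spec = acquire_spectrum(obj, circular_mask((12, 10), 160))
        M, N = 12, 10
        for i in range(M):
            for j in range(N):
                assert spec.grid[i, j] == np.conj(spec.grid[(-i) % M, (-j) % N])

    def test_constant_object_off_dc_coefficients_vanish(self):
        obj = np.full((16, 16), 2.0)
        spec = acquire_spectrum(obj, circular_mask((16, 16), 80))
        dc = abs(spec.grid[0, 0])
        off = spec.grid.copy()
        off[0, 0] = 0
        assert np.abs(off).max() <= 1e-9 * dc

    def test_sfdi_argument_equals_premodulated_object(self, rng):
        # Acquiring a scene through modulated patterns is the same as
        # acquiring the illuminated scene through plain basis patterns.
        obj = rng.random((16, 16))
        sfdi = SFDISpec(0.2, 2 * np.pi / 3, 0.5)
        mask = circular_mask((16, 16), 200)
        via_patterns = acquire_spectrum(obj, mask, sfdi=sfdi)
        from fsisfdi import sfdi_illumination

        premod = acquire_spectrum(sfdi_illumination(sfdi, (16, 16)) * obj, mask)
        assert np.allclose(via_patterns.grid, premod.grid, rtol=1e-12, atol=1e-12)

    def test_negative_object_rejected(self):
        with pytest.raises(ValueError):
            acquire_spectrum(np.full((8, 8), -1.0), circular_mask((8, 8), 8))


class TestReconstructIfft:
    def test_full_sampling_round_trip(self, rng):
        obj = rng.random((32, 32))
        rec = reconstruct_ifft(acquire_spectrum(obj, full_mask((32, 32))))
        assert np.abs(rec - obj).max() <= 1e-6 * obj.max()

    def test_dc_only_returns_the_mean(self, rng):
        obj = rng.random((16, 16))
        rec = reconstruct_ifft(acquire_spectrum(obj, circular_mask((16, 16), 4)))
        assert np.allclose(rec, obj.mean(), atol=1e-12)

    def test_empty_mask_gives_zero_image(self):
        empty = SamplingMask((8, 8), frozenset(), "circular", 4)
        spec = acquire_spectrum(np.ones((8, 8)), empty)
        assert np.all(reconstruct_ifft(spec) == 0)

    def test_unfilled_spectrum_rejected(self):
        spec = Spectrum(np.zeros((4, 4), complex), circular_mask((4, 4), 4), 0.5)
        with pytest.raises(RuntimeError):
            reconstruct_ifft(spec)


class TestReconstructCsTv:
    def test_unregularized_full_sampling_matches_ifft(self, rng):
        obj = rng.random((16, 16))
        spec = acquire_spectrum(obj, full_mask((16, 16)))
        cfg = ReconConfig(lambda1=0.0, lambda2=0.0, max_iter=50)
        res = reconstruct_cs_tv(spec, cfg)
        ref = reconstruct_ifft(spec)
        assert np.abs(res.image - ref).max() <= 1e-4 * ref.max()

    def test_objective_history_is_nonincreasing(self, rng):
        obj = rng.random((32, 32))
        spec = acquire_spectrum(obj, circular_mask((32, 32), 800))
        res = reconstruct_cs_tv(spec, ReconConfig(lambda1=1e-4, lambda2=1e-3, max_iter=40))
        J = np.array(res.objective)
        assert np.all(np.diff(J) <= 1e-10 * np.abs(J[:-1]) + 1e-30)

    def test_tv_beats_zero_filling_on_piecewise_constant_scene(self):
        img = np.full((64, 64), 0.3)
        img[10:30, 12:40] = 0.9
        img[40:58, 20:34] = 0.6
        mask = circular_mask((64, 64), int(0.2 * 64 * 64))  # 20% sampling rate
        spec = acquire_spectrum(img, mask)
        zf = reconstruct_ifft(spec)
        tv = reconstruct_cs_tv(spec, ReconConfig(max_iter=200)).image
        rmse = lambda a: np.sqrt(np.mean((a - img) ** 2))
        assert rmse(tv) <= rmse(zf)

    def test_non_convergence_flags_instead_of_raising(self, rng):
        obj = rng.random((16, 16))
        spec = acquire_spectrum(obj, circular_mask((16, 16), 100))
        res = reconstruct_cs_tv(spec, ReconConfig(lambda2=1e-2, max_iter=2, tol=1e-16))
        assert res.converged is False
        assert res.n_iter <= 2


def test_monotone_fidelity_with_growing_budget():
    """Mean reconstruction error is nonincreasing as the circular budget
    grows through 2%, 8%, 20%, 40% of the pixel count."""
    shape = (128, 128)
    budgets = [int(f * 128 * 128) for f in (0.02, 0.08, 0.20, 0.40)]
    errors = np.zeros(len(budgets))
    for seed in range(5):
        scene = make_smooth_tissue_scene(shape, correlation_px=8, seed=seed)
        img = scene.mua / scene.mua.max()
        for k, budget in enumerate(budgets):
            rec = reconstruct_ifft(acquire_spectrum(img, circular_mask(shape, budget)))
            errors[k] += np.sqrt(np.mean((rec - img) ** 2)) / 5
    assert np.all(np.diff(errors) <= 1e-12)


def test_spectrum_serialization_round_trip(tmp_path, rng):
    obj = rng.random((16, 16))
    mask = circular_mask((16, 16), 100)
    spec = acquire_spectrum(obj, mask, b=0.4)
    save_spectrum(spec, tmp_path / "spec.tiff")
    back = load_spectrum(tmp_path / "spec.tiff", mask, b=0.4)
    assert np.allclose(back.grid, spec.grid, rtol=1e-6, atol=1e-6 * np.abs(spec.grid).max())
    assert np.allclose(reconstruct_ifft(back), reconstruct_ifft(spec), atol=1e-4)
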