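import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nirmix import (
    SmoothingParams,
    Spectrum,
    build_library,
    solve_concentrations,
    unmix,
    window_stability,
)
from nirmix.errors import ConditioningWarning, RangeError, SolveError, WindowError
from nirmix.synthetic import MixtureSpec, make_mixture

WINDOWS = [(4000.0, 5400.0), (5400.0, 6600.0), (6600.0, 7600.0), (7600.0, 9000.0)]


def pinv_oracle(E, b):
    """Independent normal-equations pseudoinverse solution."""
    return np.linalg.pinv(E.T @ E) @ (E.T @ b)


class TestBuildLibrary:
    def test_identifiable_default_design(self, library):
        assert np.isfinite(library.condition_number)
        assert library.d2_matrix.shape[0] >= 3
        C = np.corrcoef(library.d2_matrix.T)
        off = C[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.95

    def test_reproducible(self, grid, components):
        a = build_library(components, grid)
        b = build_library(components, grid)
        np.testing.assert_array_equal(a.d2_matrix, b.d2_matrix)
        assert a.condition_number == b.condition_number

    def test_duplicate_component_warns_collinear(self, grid, components):
        with pytest.warns(ConditioningWarning):
            build_library([components[0], components[0], components[2]], grid)

    def test_component_not_spanning_grid_raises(self, grid, components):
        short = Spectrum(
            components[0].axis[:400], components[0].absorbance[:400], "short"
        )
        with pytest.raises(RangeError):
            build_library([short, components[1], components[2]], grid)

    def test_wrong_component_count_rejected(self, grid, components):
        with pytest.raises(ValueError, match="exactly 3"):
            build_library(components[:2], grid)


class TestSolveConcentrations:
    def test_pure_component_column(self, library):
        fv = solve_concentrations(library.d2_matrix[:, 0], library)
        np.testing.assert_allclose(fv.values, [1, 0, 0], atol=1e-10)

    def test_zero_input(self, library):
        fv = solve_concentrations(np.zeros(library.d2_matrix.shape[0]), library)
        np.testing.assert_allclose(fv.values, 0, atol=1e-14)
        assert fv.residual_norm == 0

    def test_known_combination_matches_pinv_oracle(self, library):
        E = library.d2_matrix
        b = E @ np.array([0.2, 0.5, 0.3])
        fv = solve_concentrations(b, library)
        np.testing.assert_allclose(fv.values, [0.2, 0.5, 0.3], atol=1e-8)
        np.testing.assert_allclose(fv.values, pinv_oracle(E, b), atol=1e-8)

    def test_residual_orthogonal_to_columns(self, library, rng):
        E = library.d2_matrix
        b = rng.normal(0, 1e-4, E.shape[0])
        fv = solve_concentrations(b, library)
        r = b - E @ fv.values
        assert np.abs(E.T @ r).max() < 1e-8 * np.linalg.norm(b)

    def test_exact_collinearity_names_columns(self, grid, components):
        with pytest.warns(ConditioningWarning):
            lib = build_library([components[0], components[1], components[1]], grid)
        with pytest.raises(SolveError, match="collinear"):
            solve_concentrations(lib.d2_matrix[:, 0], lib)

    @given(st.integers(0, 2**32 - 1))
    def test_qr_equals_pinv_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        E = rng.normal(size=(60, 3))
        if np.linalg.cond(E) > 1e6:
            return
        b = rng.normal(size=60)
        Q, R = np.linalg.qr(E)
        from scipy.linalg import solve_triangular

        c_qr = solve_triangular(R, Q.T @ b)
        c_pinv = pinv_oracle(E, b)
        assert np.abs(c_qr - c_pinv).max() < 1e-8 * max(1.0, np.abs(c_pinv).max())


class TestUnmix:
    def test_noiseless_ground_truth_recovery(self, grid, components, library):
        s, truth = make_mixture(components, MixtureSpec((0.3, 0.5, 0.4)), grid)
        fv = unmix(s, library)
        true = np.array([truth["c_w"], truth["c_c"], truth["c_p"]])
        assert np.abs(fv.values - true).max() / np.abs(true).min() < 1e-6

    def test_baseline_offset_barely_perturbs(self, grid, components, library):
        clean, _ = make_mixture(components, MixtureSpec((0.3, 0.5, 0.4)), grid)
        offset, _ = make_mixture(
            components, MixtureSpec((0.3, 0.5, 0.4), baseline=(0.5, 0.0)), grid
        )
        fv0, fv1 = unmix(clean, library), unmix(offset, library)
        assert np.all(np.abs(fv1.values - fv0.values) / np.abs(fv0.values) < 0.01)

    def test_scale_equivariance(self, grid, components, library):
        s, _ = make_mixture(components, MixtureSpec((0.3, 0.5, 0.4)), grid)
        fv = unmix(s, library)
        for ell in (0.5, 1.0, 1.66, 3.0):
            scaled = Spectrum(s.axis, ell * s.absorbance, sample_id="scaled")
            fv_s = unmix(scaled, library)
            assert np.abs(fv_s.values - ell * fv.values).max() < 1e-10

    def test_superposition(self, grid, components, library):
        s1, _ = make_mixture(components, MixtureSpec((0.8, 0.1, 0.2)), grid)
        s2, _ = make_mixture(components, MixtureSpec((0.1, 0.6, 0.5)), grid)
        a, b = 0.4, 0.6
        combo = Spectrum(s1.axis, a * s1.absorbance + b * s2.absorbance, "combo")
        fv = unmix(combo, library)
        expected = a * unmix(s1, library).values + b * unmix(s2, library).values
        assert np.abs(fv.values - expected).max() < 1e-8

    def test_nonneg_option_clips_nothing_when_positive(self, grid, components, library):
        s, _ = make_mixture(components, MixtureSpec((0.3, 0.5, 0.4)), grid)
        fv = unmix(s, library, nonneg=True)
        np.testing.assert_allclose(fv.values, [0.3, 0.5, 0.4], atol=1e-6)

    def test_exact_recovery_over_random_concentrations(self, grid, components, library):
        rng = np.random.default_rng(101)
        for _ in range(20):
            c = rng.uniform(0.05, 1.0, 3)
            s, _ = make_mixture(components, MixtureSpec(tuple(c)), grid)
            fv = unmix(s, library)
            assert np.abs(fv.values - c).max() / np.abs(c).min() < 1e-6


class TestWindowStability:
    def test_single_full_window_equals_unmix(self, grid, components, library):
        s, _ = make_mixture(components, MixtureSpec((0.3, 0.5, 0.4)), grid)
        vecs, summary = window_stability(s, library, windows=[(grid.lo, grid.hi)])
        assert summary["n_windows"] == 1
        np.testing.assert_allclose(vecs[0].values, unmix(s, library).values, atol=1e-12)

    def test_noiseless_windows_agree_with_truth(self, grid, components, library):
        s, _ = make_mixture(components, MixtureSpec((0.3, 0.5, 0.4)), grid)
        vecs, summary = window_stability(s, library, windows=WINDOWS)
        for fv in vecs:
            assert np.abs(fv.values - [0.3, 0.5, 0.4]).max() < 1e-6
        assert summary["max"] < 1e-6

    def test_noise_increases_dispersion(self, grid, components, library):
        clean, _ = make_mixture(components, MixtureSpec((0.3, 0.5, 0.4)), grid)
        noisy, _ = make_mixture(
            components, MixtureSpec((0.3, 0.5, 0.4), noise_sd=0.005, seed=2), grid
        )
        _, s0 = window_stability(clean, library, windows=WINDOWS)
        _, s1 = window_stability(noisy, library, windows=WINDOWS)
        assert np.isfinite(s1["max"])
        assert s1["max"] > s0["max"]

    def test_tiny_window_rejected(self, grid, components, library):
        s, _ = make_mixture(components, MixtureSpec((0.3, 0.5, 0.4)), grid)
        with pytest.raises(WindowError, match="grid points"):
            window_stability(s, library, windows=[(5000.0, 5100.0)])


class TestNoiseMonotonicity:
    def test_error_nondecreasing_in_noise(self, grid, components, library):
        rng = np.random.default_rng(55)
        draws = [tuple(rng.uniform(0.05, 1.0, 3)) for _ in range(30)]
        means = []
        for sd in (0.0, 0.002, 0.005, 0.01):
            errs = [
                np.abs(
                    unmix(
                        make_mixture(
                            components, MixtureSpec(c, noise_sd=sd, seed=900 + i), grid
                        )[0],
                        library,
                    ).values
                    - c
                ).mean()
                for i, c in enumerate(draws)
            ]
            means.append(np.mean(errs))
        assert all(a <= b for a, b in zip(means[:-1], means[1:]))
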