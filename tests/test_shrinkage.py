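import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tendos as td
from tendos.shrinkage import ShrinkageConfig, neighbor_order

FS = 250.0


def oracle_shrink(S, sigma):
    """Literal reimplementation of the optimal-shrinkage recipe:
    orient rows <= columns, SVD, normalize by sigma*sqrt(m), apply the
    closed-form operator-norm shrinker value by value, reconstruct."""
    S = np.asarray(S, float)
    trans = S.shape[0] > S.shape[1]
    X = S.T if trans else S
    p, m = X.shape
    beta = p / m
    U, s, Vt = np.linalg.svd(X)
    out = np.zeros_like(X)
    for i in range(len(s)):
        y = s[i] / (sigma * np.sqrt(m))
        if y >= 1 + np.sqrt(beta):
            t = y * y - beta - 1
            eta = np.sqrt((t + np.sqrt(t * t - 4 * beta)) / 2)
        else:
            eta = 0.0
        out += sigma * np.sqrt(m) * eta * np.outer(U[:, i], Vt[i])
    return out.T if trans else out


class TestEtaStar:
    def test_closed_forms(self):
        assert td.eta_star(1.0, 1.0) == 0.0
        assert td.eta_star(2.0, 1.0) == pytest.approx(1.0)
        assert td.eta_star(2.5, 1.0) == pytest.approx(2.0)

    @given(st.floats(0.0, 50.0), st.floats(0.01, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_properties(self, y, beta):
        v = td.eta_star(y, beta)
        assert v >= 0.0
        if y < 1 + np.sqrt(beta):
            assert v == 0.0
        else:
            assert v <= y + 1e-12

    def test_asymptote(self):
        y = np.array([10.0, 100.0, 1000.0])
        ratio = td.eta_star(y, 0.5) / y
        assert np.all(np.diff(ratio) > 0) and ratio[-1] > 0.999

    def test_continuity_at_threshold(self):
        beta = 0.4
        thr = 1 + np.sqrt(beta)
        assert td.eta_star(thr, beta) == pytest.approx(
            np.sqrt((thr ** 2 - beta - 1) / 2))
        assert td.eta_star(thr + 1e-9, beta) == pytest.approx(
            td.eta_star(thr, beta), abs=1e-4)

    def test_beta_validation(self):
        with pytest.raises(ValueError):
            td.eta_star(1.0, 0.0)
        with pytest.raises(ValueError):
            td.eta_star(1.0, 1.5)


class TestShrinkMatrix:
    def test_sigma_zero_is_noop(self):
        S = np.random.default_rng(0).standard_normal((6, 9))
        out, _ = td.shrink_matrix(S, 0.0)
        np.testing.assert_array_equal(out, S)

    @pytest.mark.parametrize("shape", [(5, 8), (8, 5), (7, 7)])
    def test_matches_brute_force_oracle(self, shape):
        rng = np.random.default_rng(42)
        for _ in range(20):
            S = rng.standard_normal(shape) * rng.uniform(0.5, 3)
            sigma = rng.uniform(0.05, 2.0)
            out, _ = td.shrink_matrix(S, sigma)
            np.testing.assert_allclose(out, oracle_shrink(S, sigma), atol=1e-10)

    def test_transpose_consistency(self):
        rng = np.random.default_rng(1)
        S = rng.standard_normal((5, 12))
        a, _ = td.shrink_matrix(S, 0.3)
        b, _ = td.shrink_matrix(S.T, 0.3)
        np.testing.assert_allclose(a, b.T, atol=1e-10)

    def test_operator_norm_non_expansion(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            S = rng.standard_normal((6, 10))
            out, _ = td.shrink_matrix(S, rng.uniform(0.1, 1.0))
            assert np.linalg.norm(out, 2) <= np.linalg.norm(S, 2) + 1e-12

    def test_strong_signal_nearly_preserved(self):
        """Rank-1 matrix far above the noise floor passes almost unchanged
        (eta*(y) -> y for y >> threshold)."""
        u = np.sin(np.linspace(0, 3, 40))
        v = np.ones(20)
        S = 50.0 * np.outer(u / np.linalg.norm(u), v / np.linalg.norm(v))
        out, kept = td.shrink_matrix(S, 1e-3)
        assert kept == 1
        assert np.linalg.norm(out - S) < 0.01 * np.linalg.norm(S)

    def test_nonfinite_rejected(self):
        S = np.ones((4, 5))
        S[0, 0] = np.nan
        with pytest.raises(ValueError):
            td.shrink_matrix(S, 1.0)


class TestLibrary:
    def test_constant_rr_geometry(self):
        z = np.zeros(4000)
        rp = td.RPeakSeries(np.arange(200, 3800, 200), FS)
        lib = td.build_library(td.EcgRecord(z, FS), rp)
        assert lib.w == 200 and lib.Lw == lib.Rw == 100 and lib.p == 201

    def test_boundary_cycle_excluded(self):
        z = np.zeros(4000)
        rp = td.RPeakSeries(np.r_[30, np.arange(230, 3800, 200)], FS)
        lib = td.build_library(td.EcgRecord(z, FS), rp)
        assert 0 not in lib.cycle_index_map

    def test_constant_signal_identical_segments(self):
        z = np.full(4000, 2.5)
        rp = td.RPeakSeries(np.arange(200, 3800, 200), FS)
        lib = td.build_library(td.EcgRecord(z, FS), rp)
        assert np.ptp(lib.segments) == 0

    def test_distances(self, library):
        lib = library
        assert td.cycle_distance(lib, 3, 3, "rri") == 0.0
        assert td.cycle_distance(lib, 3, 3, "l2") == 0.0

    def test_rri_distance_value(self):
        z = np.zeros(4000)
        rp = td.RPeakSeries(np.array([300, 500, 730, 1000, 1300]), FS)
        lib = td.build_library(td.EcgRecord(z, FS), rp)
        a = int(np.flatnonzero(lib.cycle_index_map == 0)[0])
        b = int(np.flatnonzero(lib.cycle_index_map == 1)[0])
        assert td.cycle_distance(lib, a, b, "rri") == 30.0

    def test_l2_constant_offset(self, library):
        lib = library
        c = 0.7
        shifted = lib.segments[0] + c
        d = np.linalg.norm(lib.segments[0] - shifted)
        assert d == pytest.approx(c * np.sqrt(lib.p))


class TestNeighbors:
    def _toy_lib(self, rr):
        n, p = len(rr), 5
        segs = np.arange(n)[:, None] * np.ones(p)
        return td.TemplateLibrary(segs, 10, 2, 2, np.arange(n),
                                  np.asarray(rr), FS)

    def test_xi_one_picks_nearest(self):
        lib = self._toy_lib([200, 201, 300])
        S = td.select_neighbors(lib, 0, ShrinkageConfig(xi=1))
        assert S.shape == (5, 2)
        np.testing.assert_array_equal(S[:, 0], lib.segments[0])
        np.testing.assert_array_equal(S[:, 1], lib.segments[1])

    def test_tie_break_by_cycle_index(self):
        lib = self._toy_lib([200, 200, 200, 200])
        order = neighbor_order(lib, 2, ShrinkageConfig(xi=2))
        np.testing.assert_array_equal(order, [0, 1, 3])

    def test_full_shape_and_first_column(self, library):
        S = td.select_neighbors(library, 7, ShrinkageConfig(xi=19))
        assert S.shape == (library.p, 20)
        np.testing.assert_array_equal(S[:, 0], library.segments[7])

    def test_library_too_small(self):
        lib = self._toy_lib([200, 210])
        with pytest.raises(ValueError, match=">= 20"):
            td.select_neighbors(lib, 0, ShrinkageConfig(xi=19))


class TestEstimateSigma:
    def test_identical_cycles_zero(self):
        segs = np.tile(np.sin(np.linspace(0, 5, 50)), (8, 1))
        lib = td.TemplateLibrary(segs, 10, 2, 2, np.arange(8),
                                 np.full(8, 200), FS)
        assert td.estimate_sigma(lib) == 0.0

    def test_hand_computed_two_by_two(self):
        segs = np.array([[0.0, 0.0], [2.0, 2.0]])
        lib = td.TemplateLibrary(segs, 2, 1, 0, np.arange(2),
                                 np.full(2, 100), FS)
        assert td.estimate_sigma(lib) == pytest.approx(1.0)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(8)
        template = np.sin(np.linspace(0, 2 * np.pi, 120))
        segs = template + 0.1 * rng.standard_normal((500, 120))
        lib = td.TemplateLibrary(segs, 119, 60, 59, np.arange(500),
                                 np.full(500, 200), FS)
        assert td.estimate_sigma(lib) == pytest.approx(0.1, rel=0.1)


class TestDenoise:
    def test_rank_one_input_direction_preserved(self):
        seg = np.sin(np.linspace(0, 2 * np.pi, 80))
        segs = np.tile(seg, (25, 1))
        lib = td.TemplateLibrary(segs, 79, 40, 39, np.arange(25),
                                 np.full(25, 200), FS)
        out = td.denoise_cycle(lib, 0, 0.01, ShrinkageConfig(xi=19))
        cos = np.dot(out.denoised_segment, seg) / (
            np.linalg.norm(out.denoised_segment) * np.linalg.norm(seg))
        assert cos == pytest.approx(1.0, abs=1e-9)
        assert out.kept_rank == 1

    def test_noisy_cycles_move_toward_clean_template(self):
        """At 5 dB, shrinkage reduces per-cycle RMSE to the clean template
        for >= 90% of cycles."""
        rng = np.random.default_rng(13)
        spec = td.SynthEcgSpec(duration_s=120.0, seed=14)
        rec, r_idx, _ = td.gen_synth_ecg(spec)
        clean_prep = td.preprocess(rec)
        rp = td.load_rpeaks(
            td.AnnotationSeries("rpeak", r_idx, rec.fs, "t"), clean_prep)
        clean_lib = td.build_library(clean_prep, rp)

        noisy = td.add_noise(rec, td.NoiseSpec("gaussian", 5.0, seed=15))
        noisy_lib = td.build_library(td.preprocess(noisy), rp)
        assert noisy_lib.p == clean_lib.p
        sigma = td.estimate_sigma(noisy_lib)
        improved = 0
        rows = range(0, noisy_lib.n, 2)
        for row in rows:
            den = td.denoise_cycle(noisy_lib, row, sigma).denoised_segment
            ref = clean_lib.segments[row]
            before = np.sqrt(((noisy_lib.segments[row] - ref) ** 2).mean())
            after = np.sqrt(((den - ref) ** 2).mean())
            improved += after < before
        assert improved / len(list(rows)) >= 0.9

    def test_denoise_library_flag_semantics(self, prepared, library):
        prep, rp, _ = prepared
        lib = library
        none = td.denoise_library(lib, rp, np.zeros(rp.n, bool))
        np.testing.assert_array_equal(none.segments, lib.segments)

        every = td.denoise_library(lib, rp, np.ones(rp.n, bool))
        changed = np.any(every.segments != lib.segments, axis=1)
        assert changed.all()

        flags = np.zeros(rp.n, bool)
        flags[lib.cycle_index_map[5]] = True
        flags[lib.cycle_index_map[9]] = True
        mixed = td.denoise_library(lib, rp, flags)
        diff_rows = np.flatnonzero(np.any(mixed.segments != lib.segments, axis=1))
        np.testing.assert_array_equal(diff_rows, [5, 9])
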