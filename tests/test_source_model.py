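"""TMP template, dominant T-wave, forward ECG, noise injection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgi.source_model import (
    BodySurfaceECG,
    add_noise,
    build_template,
    dominant_t_wave,
    forward_ecg,
    read_ecg_csv,
    rms_curve,
    tmp_at,
    tmp_matrix,
    write_ecg_csv,
)


def _bump_template(width=60.0, onset=0.0, center=260.0):
    """Template built from a synthetic symmetric dominant-T bump."""
    t = np.arange(center - 2 * width, center + 2 * width)
    w = np.exp(-0.5 * ((t - center) / (width / 2.0)) ** 2)
    return build_template(w, t, onset)


class TestRms:
    def test_single_electrode_is_absolute_value(self):
        sig = np.sin(np.linspace(0, 3, 40))[None, :]
        assert np.allclose(rms_curve(BodySurfaceECG(sig)), np.abs(sig[0]))

    def test_opposite_pair_gives_magnitude(self):
        v = np.linspace(-1, 2, 25)
        ecg = BodySurfaceECG(np.vstack([v, -v]))
        assert np.allclose(rms_curve(ecg), np.abs(v))

    def test_matches_brute_force(self, rng):
        x = rng.normal(size=(7, 31))
        brute = np.array([np.sqrt(np.mean(x[:, k] ** 2)) for k in range(31)])
        assert np.allclose(rms_curve(BodySurfaceECG(x)), brute)


class TestDominantT:
    @pytest.mark.parametrize("method", ["svd", "rms"])
    def test_rank_one_shape_recovered(self, method, rng):
        t = np.arange(500.0)
        shape = np.exp(-0.5 * ((t - 300) / 25.0) ** 2)
        gains = rng.uniform(0.5, 2.0, size=12)
        ecg = BodySurfaceECG(gains[:, None] * shape[None, :])
        w, tw = dominant_t_wave(ecg, (200, 420), method=method)
        ref = shape[(t >= 200) & (t <= 420)]
        c = np.corrcoef(w, ref)[0, 1]
        assert c > 0.999

    def test_invariant_to_global_scaling(self, rng):
        t = np.arange(500.0)
        shape = np.exp(-0.5 * ((t - 300) / 25.0) ** 2)
        gains = rng.uniform(0.5, 2.0, size=6)
        ecg = BodySurfaceECG(gains[:, None] * shape[None, :])
        ecg10 = BodySurfaceECG(10.0 * ecg.data)
        w1, _ = dominant_t_wave(ecg, (200, 420))
        w2, _ = dominant_t_wave(ecg10, (200, 420))
        assert np.allclose(w1, w2, atol=1e-9)

    def test_empty_window_rejected(self):
        ecg = BodySurfaceECG(np.zeros((4, 500)))
        with pytest.raises(ValueError):
            dominant_t_wave(ecg, (200, 400))


class TestTemplate:
    def test_flipped_integral_is_monotone_sigmoid(self):
        tpl = _bump_template()
        assert tpl.r[0] == 1.0
        assert np.all(np.diff(tpl.r) <= 1e-12)
        assert tpl.r[-1] < 0.05

    def test_integral_accounts_for_total_drop(self):
        t = np.arange(200.0, 400.0)
        w = np.exp(-0.5 * ((t - 300) / 20.0) ** 2)
        tpl = build_template(w, t, 0.0)
        # fundamental theorem: the limb falls from 1 to r(end) = 0
        assert tpl.r_at(tpl.s[-1]) == pytest.approx(0.0, abs=1e-12)

    def test_non_finite_input_rejected(self):
        t = np.arange(100.0)
        w = np.ones(100)
        w[3] = np.nan
        with pytest.raises(ValueError):
            build_template(w, t, 0.0)


class TestTmpWaveform:
    def test_twenty_percent_at_rho(self):
        tpl = _bump_template()
        t = np.arange(0.0, 600.0, 0.25)
        for tau, rho in [(15.0, 280.0), (40.0, 210.0), (5.0, 400.0)]:
            w = tmp_at(tpl, tau, rho, t)
            val = np.interp(rho, t, w)
            assert val == pytest.approx(0.2 * tpl.amplitude, rel=0.02)

    def test_heaviside_contract(self):
        tpl = _bump_template()
        t = np.arange(0.0, 500.0)
        w = tmp_at(tpl, 50.0, 300.0, t)
        assert np.all(w[t < 50.0] == 0.0)
        assert w[int(50 + tpl.upstroke_ms)] == pytest.approx(tpl.amplitude, rel=1e-6)

    def test_time_shift_equivariance(self):
        tpl = _bump_template()
        t = np.arange(0.0, 500.0)
        w1 = tmp_at(tpl, 40.0, 260.0, t)
        w2 = tmp_at(tpl, 60.0, 280.0, t)
        assert np.allclose(w1[:-20], w2[20:], atol=1e-9)

    def test_rho_before_tau_rejected(self):
        tpl = _bump_template()
        with pytest.raises(ValueError):
            tmp_at(tpl, 100.0, 90.0, np.arange(200.0))

    @settings(deadline=None, max_examples=25)
    @given(
        tau=st.floats(0.0, 80.0),
        apd=st.floats(120.0, 350.0),
        width=st.floats(30.0, 90.0),
    )
    def test_recovery_level_property(self, tau, apd, width):
        """r crosses 20% of the plateau at rho for arbitrary stretches."""
        tpl = _bump_template(width=width)
        t = np.arange(0.0, 700.0, 0.25)
        w = tmp_at(tpl, tau, tau + apd, t)
        assert np.interp(tau + apd, t, w) == pytest.approx(0.2 * tpl.amplitude, rel=0.03)

    def test_analytic_derivatives_match_finite_differences(self):
        tpl = _bump_template()
        t = np.arange(0.0, 500.0)
        tau = np.array([30.0, 55.0])
        rho = np.array([260.0, 310.0])
        M, dMt, dMr = tmp_matrix(tpl, tau, rho, t, derivatives=True)
        eps = 1e-3
        fd_t = (tmp_matrix(tpl, tau + eps, rho, t) - tmp_matrix(tpl, tau - eps, rho, t)) / (2 * eps)
        fd_r = (tmp_matrix(tpl, tau, rho + eps, t) - tmp_matrix(tpl, tau, rho - eps, t)) / (2 * eps)
        scale = np.abs(fd_t).max()
        assert np.abs(dMt - fd_t).max() < 0.05 * scale
        assert np.abs(dMr - fd_r).max() < 0.05 * np.abs(fd_r).max()


class TestForwardEcg:
    def test_matches_brute_force_loop(self, rng):
        tpl = _bump_template()
        A = rng.normal(size=(5, 10))
        tau = rng.uniform(10, 60, size=10)
        rho = rng.uniform(220, 320, size=10)
        t = np.arange(0.0, 450.0)
        ecg = forward_ecg(A, tau, rho, tpl, t)
        brute = np.zeros((5, len(t)))
        for j in range(10):
            w = tmp_at(tpl, tau[j], rho[j], t)
            for i in range(5):
                brute[i] += A[i, j] * w
        assert np.allclose(ecg.data, brute, atol=1e-9)

    def test_uniform_timing_nulls_with_zero_row_sum(self, rng):
        tpl = _bump_template()
        A = rng.normal(size=(6, 12))
        A -= A.mean(axis=1, keepdims=True)  # closed-layer property surrogate
        t = np.arange(0.0, 450.0)
        ecg = forward_ecg(A, np.full(12, 30.0), np.full(12, 280.0), tpl, t)
        assert np.abs(ecg.data).max() < 1e-10 * np.abs(A).max() * tpl.amplitude

    def test_single_vertex_perturbation_is_column_response(self, rng):
        tpl = _bump_template()
        A = rng.normal(size=(4, 8))
        tau = np.full(8, 30.0)
        rho = np.full(8, 280.0)
        t = np.arange(0.0, 450.0)
        base = forward_ecg(A, tau, rho, tpl, t).data
        tau2 = tau.copy()
        tau2[3] += 15.0
        mod = forward_ecg(A, tau2, rho, tpl, t).data
        dw = tmp_at(tpl, tau2[3], rho[3], t) - tmp_at(tpl, tau[3], rho[3], t)
        assert np.allclose(mod - base, np.outer(A[:, 3], dw), atol=1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        tpl = _bump_template()
        with pytest.raises(ValueError):
            forward_ecg(rng.normal(size=(4, 8)), np.zeros(7), np.full(7, 250.0), tpl, np.arange(100.0))


class TestNoise:
    def test_zero_sigma_identity(self):
        ecg = BodySurfaceECG(np.ones((3, 50)))
        out = add_noise(ecg, 0.0, seed=5)
        assert np.array_equal(out.data, ecg.data)

    def test_seed_reproducibility(self):
        ecg = BodySurfaceECG(np.zeros((3, 50)))
        a = add_noise(ecg, 40.0, seed=9)
        b = add_noise(ecg, 40.0, seed=9)
        c = add_noise(ecg, 40.0, seed=10)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_empirical_sigma(self):
        ecg = BodySurfaceECG(np.zeros((40, 4000)))
        out = add_noise(ecg, 60.0, seed=3)
        assert out.data.std() * 1000 == pytest.approx(60.0, rel=0.05)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            add_noise(BodySurfaceECG(np.zeros((2, 10))), -1.0, seed=0)


def test_ecg_csv_roundtrip(tmp_path, rng):
    ecg = BodySurfaceECG(rng.normal(size=(5, 60)), dt=2.0, t0=4.0)
    path = tmp_path / "beat.csv"
    write_ecg_csv(path, ecg)
    back = read_ecg_csv(path)
    assert np.allclose(back.data, ecg.data)
    assert back.dt == ecg.dt
    assert back.t0 == ecg.t0
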