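"""Forward-model unit and property tests.

The independent oracle for the matrix exponential is a plain Taylor
series with term-wise convergence, kept deliberately separate from the
closed-form eigendecomposition used by the package.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm as expm_pade

import sirqmt as sq
from sirqmt.model import _expm2, signal_grid
from tests.conftest import random_valid_params


def expm_taylor(A, t, terms=30):
    """Series-expansion matrix exponential: independent oracle.

    The argument is halved until its norm is below 1/2 so the series
    converges to machine precision, then the result is squared back up.
    """
    M = A * t
    s = 0
    while np.max(np.abs(M)) > 0.5:
        M = M / 2.0
        s += 1
    out = np.eye(2)
    term = np.eye(2)
    for k in range(1, terms):
        term = term @ M / k
        out = out + term
    for _ in range(s):
        out = out @ out
    return out


def scalar_ir(params, ti, td):
    """Decoupled-pool (PSR = 0) closed form for the free-pool signal."""
    e_i = math.exp(-params.r1f * ti)
    e_d = math.exp(-params.r1f * td)
    return params.m0f * (e_i * params.sf * (1 - e_d) + 1 - e_i)


class TestTissueParams:
    def test_derived_rates(self):
        p = sq.TissueParams(psr=0.1, r1f=1.0, kmf=12.5, m0f=2.0)
        assert p.kfm == pytest.approx(1.25)
        assert p.m0m == pytest.approx(0.2)
        assert p.r1m == p.r1f  # default tie

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(psr=-0.1, r1f=1.0), "psr"),
            (dict(psr=0.1, r1f=0.0), "r1f"),
            (dict(psr=0.1, r1f=1.0, r1m=-1.0), "r1m"),
            (dict(psr=0.1, r1f=1.0, m0f=0.0), "m0f"),
            (dict(psr=0.1, r1f=1.0, kmf=-5.0), "kmf"),
        ],
    )
    def test_domain_errors_name_offending_field(self, kwargs, field):
        with pytest.raises(sq.ParameterDomainError, match=field):
            sq.TissueParams(**kwargs)


class TestScheme:
    def test_default_matches_protocol_ms(self):
        s = sq.AcquisitionScheme.default()
        assert s.ti == (0.015, 0.015, 0.278, 1.007)
        assert s.td == (0.648, 4.171, 2.730, 0.010)

    def test_from_ms(self):
        s = sq.AcquisitionScheme.from_ms([15, 15, 278, 1007], [648, 4171, 2730, 10])
        assert s == sq.AcquisitionScheme.default()

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            sq.AcquisitionScheme(ti=(0.1, 0.2, 0.3, 0.4), td=(0.1, 0.2, 0.3))

    def test_nonpositive_times(self):
        with pytest.raises(ValueError, match="> 0"):
            sq.AcquisitionScheme(ti=(0.1, 0.2, 0.3, 0.0), td=(0.1, 0.2, 0.3, 0.4))


class TestRateMatrix:
    def test_direct_substitution(self):
        p = sq.TissueParams(psr=0.1, r1f=1.0, r1m=1.0, kmf=12.5)
        np.testing.assert_allclose(
            sq.rate_matrix(p), [[-2.25, 12.5], [1.25, -13.5]]
        )

    def test_psr_zero_decouples_free_pool(self):
        p = sq.TissueParams(psr=0.0, r1f=1.0, r1m=1.0, kmf=12.5)
        A = sq.rate_matrix(p)
        np.testing.assert_allclose(A, [[-1.0, 12.5], [0.0, -13.5]])

    def test_eigenvalues_real_negative_over_sweep(self):
        rng = np.random.default_rng(42)
        for p in random_valid_params(rng, 200):
            eig = np.linalg.eigvals(sq.rate_matrix(p))
            assert np.all(np.isreal(eig))
            assert np.all(eig.real < 0)


class TestMatrixExponential:
    def test_closed_form_matches_pade_sweep(self):
        rng = np.random.default_rng(3)
        for p in random_valid_params(rng, 300):
            A = sq.rate_matrix(p)
            for t in (0.01, 0.278, 1.007, 4.171):
                E = np.array(_expm2(A[0, 0], A[0, 1], A[1, 0], A[1, 1], t))
                np.testing.assert_allclose(
                    E.reshape(2, 2), expm_pade(A * t), atol=1e-10, rtol=0
                )

    def test_closed_form_matches_taylor_oracle(self, wm_params):
        A = sq.rate_matrix(wm_params)
        for t in (0.015, 0.278, 1.007):
            E = np.array(_expm2(A[0, 0], A[0, 1], A[1, 0], A[1, 1], t))
            np.testing.assert_allclose(
                E.reshape(2, 2), expm_taylor(A, t), atol=1e-12, rtol=0
            )


class TestLongitudinalMagnetization:
    def test_full_recovery_limit(self, wm_params):
        mz = sq.longitudinal_magnetization(wm_params, ti=1e6, td=0.5)
        np.testing.assert_allclose(mz, [wm_params.m0f, wm_params.m0m], rtol=1e-12)

    def test_equilibrium_invariant(self):
        rng = np.random.default_rng(11)
        for p in random_valid_params(rng, 50):
            mzf = sq.longitudinal_magnetization(p, ti=50.0 / p.r1f, td=0.3)[0]
            assert abs(mzf - p.m0f) < 1e-8 * p.m0f

    def test_decoupled_long_delay_is_textbook_ir(self):
        p = sq.TissueParams(psr=0.0, r1f=1.2, sf=-1.0, m0f=1.0, kmf=12.5)
        for ti in (0.015, 0.278, 1.007):
            mzf = sq.longitudinal_magnetization(p, ti=ti, td=1e3)[0]
            expected = p.m0f * (1 - 2 * math.exp(-p.r1f * ti))
            assert mzf == pytest.approx(expected, abs=1e-12)

    def test_vanishing_predelay_is_saturation_recovery(self, wm_params):
        # td -> 0+: both pools saturated, Mz -> (I - e^{A ti}) M0
        A = sq.rate_matrix(wm_params)
        m0 = np.array([wm_params.m0f, wm_params.m0m])
        ti = 0.278
        expected = (np.eye(2) - expm_pade(A * ti)) @ m0
        mz = sq.longitudinal_magnetization(wm_params, ti=ti, td=1e-12)
        np.testing.assert_allclose(mz, expected, atol=1e-10)

    def test_recovery_exceeds_early_inversion_point(self, wm_params):
        early = sq.longitudinal_magnetization(wm_params, ti=0.015, td=0.648)[0]
        late = sq.longitudinal_magnetization(wm_params, ti=1e3, td=0.648)[0]
        assert late > early

    def test_nonpositive_times_rejected(self, wm_params):
        with pytest.raises(ValueError):
            sq.longitudinal_magnetization(wm_params, ti=-0.1, td=0.5)


class TestSirSignal:
    def test_taylor_oracle_full_model(self, wm_params, scheme):
        signal = sq.sir_signal(wm_params, scheme, magnitude=False)
        m0 = np.array([wm_params.m0f, wm_params.m0m])
        S = np.diag([wm_params.sf, wm_params.sm])
        A = sq.rate_matrix(wm_params)
        for k, (ti, td) in enumerate(zip(scheme.ti, scheme.td)):
            mz = (
                expm_taylor(A, ti) @ S @ (np.eye(2) - expm_taylor(A, td))
                + (np.eye(2) - expm_taylor(A, ti))
            ) @ m0
            assert signal[k] == pytest.approx(mz[0], abs=1e-12)

    def test_short_predelay_point_below_recovered_fraction(self, wm_params, scheme):
        # With td = 10 ms both pools start saturated, so even at
        # ti = 1.007 s the signal stays strictly below the fraction of
        # M0f that the td = 2.730 s pre-delay lets recover.
        signal = sq.sir_signal(wm_params, scheme, magnitude=True)
        recovered_fraction = 1 - math.exp(-wm_params.r1f * scheme.td[2])
        assert signal[3] < recovered_fraction * wm_params.m0f
        assert signal[3] < wm_params.m0f

    def test_decoupled_matches_scalar_closed_form(self, scheme):
        p = sq.TissueParams(psr=0.0, r1f=0.8, sf=-0.9, m0f=1.7, kmf=12.5)
        signal = sq.sir_signal(p, scheme, magnitude=False)
        expected = [scalar_ir(p, ti, td) for ti, td in zip(scheme.ti, scheme.td)]
        np.testing.assert_allclose(signal, expected, atol=1e-12, rtol=0)

    def test_magnitude_flag_rectifies(self, wm_params, scheme):
        signed = sq.sir_signal(wm_params, scheme, magnitude=False)
        mag = sq.sir_signal(wm_params, scheme, magnitude=True)
        assert signed[0] < 0  # short-ti inverted point
        np.testing.assert_allclose(mag, np.abs(signed))
        assert np.all(mag >= 0)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(c=st.floats(min_value=0.01, max_value=100.0))
    def test_m0f_scaling_property(self, c, scheme):
        base = sq.TissueParams(psr=0.12, r1f=1.1, sf=-1.0, m0f=1.0, kmf=12.5)
        scaled = sq.TissueParams(psr=0.12, r1f=1.1, sf=-1.0, m0f=c, kmf=12.5)
        np.testing.assert_allclose(
            sq.sir_signal(scaled, scheme, magnitude=False),
            c * sq.sir_signal(base, scheme, magnitude=False),
            rtol=1e-12,
        )

    def test_continuity_bounded_finite_differences(self, scheme):
        # central differences over the simulation box stay bounded
        rng = np.random.default_rng(5)
        h = 1e-6
        for _ in range(20):
            psr = rng.uniform(0.05, 0.25)
            r1f = rng.uniform(0.5, 1.5)
            for name, val in (("psr", psr), ("r1f", r1f)):
                lo = dict(psr=psr, r1f=r1f)
                hi = dict(psr=psr, r1f=r1f)
                lo[name] = val - h
                hi[name] = val + h
                s_lo = sq.sir_signal(sq.TissueParams(**lo), scheme, magnitude=False)
                s_hi = sq.sir_signal(sq.TissueParams(**hi), scheme, magnitude=False)
                assert np.all(np.abs(s_hi - s_lo) / (2 * h) < 50.0)


class TestBiexponentialComponents:
    def test_triangular_case(self):
        p = sq.TissueParams(psr=0.0, r1f=1.0, r1m=1.0, kmf=12.5)
        fast, slow = sq.biexponential_components(p)
        assert (fast, slow) == pytest.approx((13.5, 1.0))

    def test_matches_general_eigensolver(self):
        p = sq.TissueParams(psr=0.1, r1f=1.0, r1m=1.0, kmf=12.5)
        fast, slow = sq.biexponential_components(p)
        eig = np.sort(np.abs(np.linalg.eigvals(sq.rate_matrix(p))))
        assert (slow, fast) == pytest.approx((eig[0], eig[1]))

    def test_rates_reconstruct_exponential(self):
        rng = np.random.default_rng(9)
        for p in random_valid_params(rng, 50):
            fast, slow = sq.biexponential_components(p)
            assert fast >= slow > 0
            A = sq.rate_matrix(p)
            eig = np.sort(np.abs(np.linalg.eigvals(A)))
            np.testing.assert_allclose([slow, fast], eig, rtol=1e-10)


class TestSignalGrid:
    def test_matches_scalar_path(self, scheme):
        rng = np.random.default_rng(21)
        params = random_valid_params(rng, 40)
        psr = np.array([p.psr for p in params])
        r1f = np.array([p.r1f for p in params])
        r1m = np.array([p.r1m for p in params])
        sf = np.array([p.sf for p in params])
        sm = np.array([p.sm for p in params])
        m0f = np.array([p.m0f for p in params])
        kmf = np.array([p.kmf for p in params])
        grid = signal_grid(psr, r1f, r1m, sf, sm, m0f, kmf, scheme.ti, scheme.td)
        for i, p in enumerate(params):
            np.testing.assert_allclose(
                grid[i], sq.sir_signal(p, scheme, magnitude=False), atol=1e-12
            )

    def test_degenerate_gap_falls_back(self, scheme):
        # psr = 0 with r1f == r1m + kmf makes the eigenvalue gap vanish
        grid = signal_grid(0.0, 12.6, 0.1, -1.0, 0.83, 1.0, 12.5,
                           scheme.ti, scheme.td)
        assert np.all(np.isfinite(grid))
        p = sq.TissueParams(psr=0.0, r1f=12.6, r1m=0.1, kmf=12.5)
        expected = [scalar_ir(p, ti, td) for ti, td in zip(scheme.ti, scheme.td)]
        np.testing.assert_allclose(grid, expected, atol=1e-9)
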