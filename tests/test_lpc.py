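import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cmprof.coevolution import CoevolutionConfig, cm_signal_stack, corrected_joint, count_pairs
from cmprof.errors import InputError
from cmprof.fixtures import simulate_msa
from cmprof.lpc import (CmProfile, LpcConfig, autocorrelation, build_cm_profile,
                        levinson_durbin, lpc_to_cepstrum,
                        _batch_autocorrelation, _batch_cepstrum, _batch_levinson)
from cmprof.msa_io import Msa


def toeplitz_solve(r):
    """Dense normal-equation solve: the independent oracle for Levinson-Durbin."""
    p = len(r) - 1
    T = np.array([[r[abs(i - k)] for k in range(p)] for i in range(p)])
    return np.linalg.solve(T, r[1:])


def random_autocorrelation(rng, p, n=64):
    s = rng.standard_normal(n)
    return autocorrelation(s, p)


def fft_cepstrum(a, L, nfft=8192):
    """Complex cepstrum of the all-pole filter 1/A(z) via the log spectrum.

    1/A(z) is minimum phase for stable a, so its complex cepstrum at m >= 1
    is twice the real (magnitude-only) cepstrum — no phase unwrapping needed.
    """
    A = np.fft.fft(np.concatenate([[1.0], -np.asarray(a)]), nfft)
    c = np.fft.ifft(-np.log(np.abs(A))).real
    return 2.0 * c[1 : L + 1]


def stable_lpc_coefficients(rng, p=6, rmax=0.9):
    """Random stable predictor via poles drawn inside the unit disk."""
    n_cplx = p // 2
    roots = []
    for _ in range(n_cplx):
        r = rmax * np.sqrt(rng.random())
        th = np.pi * rng.random()
        roots += [r * np.exp(1j * th), r * np.exp(-1j * th)]
    for _ in range(p - 2 * n_cplx):
        roots.append((2 * rng.random() - 1) * rmax)
    poly = np.real(np.poly(roots))
    return -poly[1:]


class TestAutocorrelation:
    def test_zero_vector(self):
        assert np.array_equal(autocorrelation(np.zeros(10), 3), np.zeros(4))

    def test_unit_impulse(self):
        r = autocorrelation(np.eye(8)[0], 4)
        assert r[0] == 1.0 and np.all(r[1:] == 0.0)

    def test_matches_double_loop(self, rng):
        s = rng.standard_normal(40)
        r = autocorrelation(s, 6)
        for k in range(7):
            assert r[k] == pytest.approx(sum(s[t] * s[t + k] for t in range(40 - k)), abs=1e-12)

    def test_r0_dominates(self, rng):
        r = random_autocorrelation(rng, 10)
        assert np.all(r[0] >= np.abs(r[1:]) - 1e-12)

    def test_short_signal_rejected(self):
        with pytest.raises(InputError):
            autocorrelation(np.ones(5), 5)


class TestLevinsonDurbin:
    def test_white_signal(self):
        fit = levinson_durbin(np.array([1.0, 0, 0, 0]))
        assert np.all(fit.a == 0.0) and fit.E == 1.0 and not fit.degenerate

    def test_degenerate_zero_signal(self):
        fit = levinson_durbin(np.zeros(5))
        assert fit.degenerate and fit.E == 0.0 and np.all(fit.a == 0.0)

    def test_matches_dense_solve(self, rng):
        for _ in range(50):
            p = int(rng.integers(1, 21))
            r = random_autocorrelation(rng, p)
            fit = levinson_durbin(r)
            expected = toeplitz_solve(r)
            resid = np.linalg.norm(fit.a - expected) / max(np.linalg.norm(expected), 1e-30)
            assert resid < 1e-8
            assert fit.E >= 0.0
            assert fit.E == pytest.approx(r[0] - np.dot(fit.a, r[1:]), rel=1e-6, abs=1e-9)

    def test_ar2_recovery(self):
        rng = np.random.default_rng(5)
        a_true = np.array([0.5, -0.3])
        s = np.zeros(10000)
        noise = rng.standard_normal(10000) * 0.01
        for t in range(2, 10000):
            s[t] = a_true[0] * s[t - 1] + a_true[1] * s[t - 2] + noise[t]
        fit = levinson_durbin(autocorrelation(s[100:], 2))
        assert np.allclose(fit.a, a_true, atol=0.05)


class TestCepstrum:
    def test_zero_coefficients_give_zero_cepstrum(self):
        assert np.array_equal(lpc_to_cepstrum(np.zeros(6), 9), np.zeros(9))

    def test_output_longer_than_order(self, rng):
        a = stable_lpc_coefficients(rng, p=6)
        c = lpc_to_cepstrum(a, 9)
        assert c.shape == (9,)  # m > p branch exercised

    def test_single_pole_closed_form(self):
        # 1/(1 - a z^-1) has cepstrum a^m / m
        a = 0.6
        c = lpc_to_cepstrum(np.array([a]), 6)
        assert np.allclose(c, [a**m / m for m in range(1, 7)], atol=1e-12)

    def test_matches_fft_complex_cepstrum(self, rng):
        for _ in range(20):
            a = stable_lpc_coefficients(rng, p=6)
            assert np.allclose(lpc_to_cepstrum(a, 9), fft_cepstrum(a, 9), atol=1e-6)


class TestBatchEqualsScalar:
    def test_batch_pipeline_matches_scalar_loop(self, rng):
        S = rng.standard_normal((30, 25))
        S[4] = 0.0  # degenerate row
        R = _batch_autocorrelation(S, 6)
        A, _ = _batch_levinson(R)
        C = _batch_cepstrum(A, 9)
        for b in range(30):
            r = autocorrelation(S[b], 6)
            fit = levinson_durbin(r)
            assert np.allclose(R[b], r, atol=1e-10)
            assert np.allclose(A[b], fit.a, atol=1e-10)
            assert np.allclose(C[b], lpc_to_cepstrum(fit, 9), atol=1e-10)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_scale_invariance_of_coefficients(self, seed):
        # scaling s by a power of two scales r exactly, leaving a unchanged
        rng = np.random.default_rng(seed)
        s = rng.standard_normal(32)
        a1 = levinson_durbin(autocorrelation(s, 6)).a
        a2 = levinson_durbin(autocorrelation(4.0 * s, 6)).a
        assert np.array_equal(a1, a2)


@pytest.fixture(scope="module")
def planted_msa():
    msa, _ = simulate_msa(30, 60, [(3, 12, 0.9)], seed=3)
    return msa


class TestBuildCmProfile:
    def test_shape_and_normalization(self, planted_msa):
        prof = build_cm_profile(planted_msa)
        assert prof.coeffs.shape == (30, 400, 9)
        assert np.all(np.abs(prof.coeffs.mean(axis=(0, 1))) <= 1e-9)
        assert np.allclose(prof.coeffs.var(axis=(0, 1)), 1.0, atol=1e-6)

    def test_deterministic(self, planted_msa):
        p1 = build_cm_profile(planted_msa)
        p2 = build_cm_profile(planted_msa)
        assert np.array_equal(p1.coeffs, p2.coeffs)

    def test_matches_straight_line_oracle(self, planted_msa):
        """End-to-end naive recomputation: dense Toeplitz solve instead of
        Levinson-Durbin, scalar recursion per signal."""
        cfg_c, cfg_l = CoevolutionConfig(0.05), LpcConfig(6, 9)
        prof = build_cm_profile(planted_msa, cfg_c, cfg_l)
        freqs = corrected_joint(count_pairs(planted_msa), cfg_c)
        signals = cm_signal_stack(freqs)
        n = planted_msa.n
        raw = np.zeros((n, 400, 9))
        for i in range(n):
            for pair in range(400):
                s = signals[i, pair]
                r = np.array([np.dot(s[: n - k], s[k:]) for k in range(7)])
                if r[0] <= 1e-12:
                    continue
                a = toeplitz_solve(r)
                raw[i, pair] = lpc_to_cepstrum(a, 9)
        mean = raw.mean(axis=(0, 1))
        std = raw.std(axis=(0, 1))
        expected = (raw - mean) / std
        assert np.allclose(prof.coeffs, expected, atol=1e-9)

    def test_conserved_alignment_profile_is_finite(self):
        # a fully conserved MSA carries no covariation signal but must still
        # produce finite coefficients (never NaN)
        msa = Msa("s", [f"s{k}" for k in range(10)], ["ACDEFGHIKL"] * 10)
        prof = build_cm_profile(msa)
        assert np.all(np.isfinite(prof.coeffs))

    def test_zero_signals_short_circuit_to_zero_cepstra(self, rng):
        S = rng.standard_normal((8, 20))
        S[[1, 5]] = 0.0
        R = _batch_autocorrelation(S, 6)
        A, _ = _batch_levinson(R)
        C = _batch_cepstrum(A, 9)
        C[R[:, 0] <= 1e-12] = 0.0
        assert np.all(C[[1, 5]] == 0.0)
        assert np.any(C[0] != 0.0)

    def test_too_short_for_model_order(self):
        msa = Msa("s", ["s"], ["ACDEF"])
        with pytest.raises(InputError):
            build_cm_profile(msa)

    @pytest.mark.parametrize("mode", ["tsv", "npz"])
    def test_serialization_round_trip(self, planted_msa, tmp_path, mode):
        prof = build_cm_profile(planted_msa)
        path = tmp_path / f"p.{mode}"
        getattr(prof, f"to_{mode}")(path)
        back = getattr(CmProfile, f"from_{mode}")(path)
        assert np.array_equal(back.coeffs, prof.coeffs)
        assert back.meta == prof.meta
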