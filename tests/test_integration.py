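import numpy as np
import pytest

from stimvarx import random_stable_mvarx
from stimvarx.core import MVARXModel
from stimvarx import integration as ig


def scalar_ar1(a=0.7, q=2.0):
    return MVARXModel(A=np.array([[[a]]]), B=np.zeros((1, 1)),
                      Q=np.array([[q]]))


def block_model(seed=1, coupling=0.0, d_block=2, p=2):
    """Two independent sub-systems with optional cross-block coupling."""
    m1 = random_stable_mvarx(d_block, p, 0, spectral_radius_target=0.7,
                             seed=seed)
    m2 = random_stable_mvarx(d_block, p, 0, spectral_radius_target=0.6,
                             seed=seed + 1)
    d = 2 * d_block
    A = np.zeros((p, d, d))
    A[:, :d_block, :d_block] = m1.A
    A[:, d_block:, d_block:] = m2.A
    if coupling:
        rng = np.random.default_rng(seed + 2)
        A[:, :d_block, d_block:] += coupling * rng.standard_normal(
            (p, d_block, d_block))
    Q = np.zeros((d, d))
    Q[:d_block, :d_block] = m1.Q
    Q[d_block:, d_block:] = m2.Q
    return MVARXModel(A=A, B=np.zeros((d, 1)), Q=Q)


def kron_moments_2ch(A1, Q, tau):
    """Independent closed-form moments for a 2-channel AR(1) system:
    vec(Sigma) = (I - A kron A)^{-1} vec(Q), Gamma_t = Gamma_{t-1} A^T."""
    sig = np.linalg.solve(np.eye(4) - np.kron(A1, A1), Q.ravel()).reshape(2, 2)
    gam = sig
    for _ in range(tau):
        gam = gam @ A1.T
    return sig, gam


class TestStationaryMoments:
    def test_scalar_closed_form(self):
        m = scalar_ar1(a=0.7, q=2.0)
        mom = ig.stationary_moments(m, rho=5)
        sig = 2.0 / (1 - 0.49)
        assert mom.sigma[0, 0] == pytest.approx(sig)
        for t in range(1, 6):
            assert mom.lagged(t)[0, 0] == pytest.approx(0.7**t * sig)

    def test_block_diagonal_structure(self):
        m = block_model(seed=3)
        mom = ig.stationary_moments(m, rho=4)
        for M in [mom.sigma] + mom.gamma:
            assert np.allclose(M[:2, 2:], 0.0, atol=1e-12)
            assert np.allclose(M[2:, :2], 0.0, atol=1e-12)

    def test_matches_monte_carlo(self):
        from stimvarx import StimulusTrain, simulate_session

        m = random_stable_mvarx(3, 2, 0, spectral_radius_target=0.8, seed=5)
        mom = ig.stationary_moments(m, rho=2)
        tr = StimulusTrain(pulse_times=[10**9], isi=1)
        s = simulate_session(m, tr, n_samples=200000, seed=6)
        emp_sig = s.y @ s.y.T / s.n_samples
        assert np.linalg.norm(emp_sig - mom.sigma) / np.linalg.norm(
            mom.sigma) < 0.05
        emp_g1 = s.y[:, :-1] @ s.y[:, 1:].T / (s.n_samples - 1)
        assert np.linalg.norm(emp_g1 - mom.gamma[0]) / np.linalg.norm(
            mom.gamma[0]) < 0.05

    def test_lagged_convention(self):
        # Gamma_1 = Sigma A^T for AR(1): E{y[n-1] y[n]^T}
        m = random_stable_mvarx(3, 1, 0, spectral_radius_target=0.6, seed=7)
        mom = ig.stationary_moments(m, rho=3)
        assert np.allclose(mom.gamma[0], mom.sigma @ m.A[0].T, atol=1e-10)

    def test_unstable_rejected(self):
        m = scalar_ar1(a=1.01)
        with pytest.raises(ValueError, match="unstable"):
            ig.stationary_moments(m)


class TestConditionalCov:
    def test_no_dependence_returns_sigma(self):
        m = MVARXModel(A=np.zeros((1, 3, 3)), B=np.zeros((3, 1)),
                       Q=np.diag([1.0, 2.0, 3.0]))
        mom = ig.stationary_moments(m, rho=2)
        assert np.allclose(ig.conditional_cov(mom, 1), mom.sigma)

    def test_scalar_closed_form(self):
        m = scalar_ar1(a=0.6, q=1.5)
        mom = ig.stationary_moments(m, rho=8)
        sig = 1.5 / (1 - 0.36)
        for t in [1, 3, 8]:
            assert ig.conditional_cov(mom, t)[0, 0] == pytest.approx(
                sig * (1 - 0.6 ** (2 * t))
            )

    def test_determinant_never_increases(self):
        m = random_stable_mvarx(4, 2, 0, spectral_radius_target=0.85, seed=9)
        mom = ig.stationary_moments(m, rho=6)
        det_sig = np.linalg.det(mom.sigma)
        for t in range(1, 7):
            assert np.linalg.det(ig.conditional_cov(mom, t)) <= det_sig + 1e-12

    def test_subset_uses_marginal_blocks(self):
        m = random_stable_mvarx(4, 2, 0, spectral_radius_target=0.8, seed=10)
        mom = ig.stationary_moments(m, rho=3)
        idx = [1, 3]
        sub = ig.conditional_cov(mom, 2, subset=idx)
        sig = mom.sigma[np.ix_(idx, idx)]
        gam = mom.lagged(2)[np.ix_(idx, idx)]
        manual = sig - gam @ np.linalg.solve(sig, gam.T)
        assert np.allclose(sub, manual)


class TestEffectiveInformation:
    def test_block_independent_zero(self):
        m = block_model(seed=11)
        phi = ig.effective_information(m, 2, ig.Bipartition((0, 1), (2, 3)))
        assert phi == pytest.approx(0.0, abs=1e-9)

    def test_no_dynamics_zero_any_partition(self):
        m = MVARXModel(A=np.zeros((1, 4, 4)), B=np.zeros((4, 1)),
                       Q=np.diag([1.0, 0.5, 2.0, 1.5]))
        for part in ig.enumerate_bipartitions(4):
            assert ig.effective_information(m, 1, part) == pytest.approx(
                0.0, abs=1e-12)

    def test_swap_symmetry(self):
        m = random_stable_mvarx(4, 2, 0, spectral_radius_target=0.8, seed=12)
        p1 = ig.Bipartition((0, 2), (1, 3))
        p2 = ig.Bipartition((1, 3), (0, 2))
        assert ig.effective_information(m, 3, p1) == pytest.approx(
            ig.effective_information(m, 3, p2))

    def test_coupled_2ch_vs_independent_oracle(self):
        # independently coded closed-form moments + direct assembly
        a, c, q = 0.5, 0.3, 1.0
        A1 = np.array([[a, c], [c, a]])
        Q = q * np.eye(2)
        m = MVARXModel(A=A1[None, :, :], B=np.zeros((2, 1)), Q=Q)
        tau = 1
        phi = ig.effective_information(m, tau, ig.Bipartition((0,), (1,)))
        sig, gam = kron_moments_2ch(A1, Q, tau)
        cond = sig - gam @ np.linalg.solve(sig, gam.T)
        val = -np.log2(np.linalg.det(cond))
        for i in range(2):
            s, g = sig[i, i], gam[i, i]
            val += np.log2(s - g * g / s)
        assert phi == pytest.approx(0.5 * val, rel=1e-10)
        assert phi > 0

    def test_positivity_sweep(self):
        rng = np.random.default_rng(13)
        worst = 0.0
        for _ in range(300):
            d = int(rng.integers(2, 5))
            p = int(rng.integers(1, 4))
            m = random_stable_mvarx(
                d, p, 0, spectral_radius_target=float(rng.uniform(0.2, 0.95)),
                seed=int(rng.integers(10**6)),
            )
            tau = int(rng.integers(1, 12))
            parts = ig.enumerate_bipartitions(d)
            part = parts[int(rng.integers(len(parts)))]
            worst = min(worst, ig.effective_information(m, tau, part))
        assert worst >= -1e-9

    def test_channel_permutation_equivariance(self):
        m = random_stable_mvarx(4, 2, 0, spectral_radius_target=0.8, seed=14)
        perm = [2, 0, 3, 1]
        mp = MVARXModel(
            A=np.stack([Ai[np.ix_(perm, perm)] for Ai in m.A]),
            B=m.B[perm, :], Q=m.Q[np.ix_(perm, perm)],
        )
        part = ig.Bipartition((0, 1), (2, 3))
        inv = np.argsort(perm)
        part_p = ig.Bipartition(tuple(sorted(inv[list(part.M1)])),
                                tuple(sorted(inv[list(part.M2)])))
        assert ig.effective_information(m, 2, part) == pytest.approx(
            ig.effective_information(mp, 2, part_p), rel=1e-9)


class TestMIB:
    def test_block_aligned_mib(self):
        m = block_model(seed=15)
        mib, phi, table = ig.minimum_information_bipartition(m, 2)
        assert set(mib.M1) == {0, 1} or set(mib.M1) == {2, 3}
        assert phi == pytest.approx(0.0, abs=1e-9)
        assert len(table) == 7  # 2^(4-1) - 1 canonical bipartitions

    def test_d2_single_candidate(self):
        m = random_stable_mvarx(2, 1, 0, spectral_radius_target=0.7, seed=16)
        mib, phi, table = ig.minimum_information_bipartition(m, 1)
        assert len(table) == 1
        assert mib.M1 == (0,) and mib.M2 == (1,)

    def test_matches_bruteforce_reimplementation(self):
        # second, naive implementation built from raw formulas
        m = random_stable_mvarx(4, 2, 0, spectral_radius_target=0.85, seed=17)
        tau = 3
        mom = ig.stationary_moments(m, rho=tau)
        sig, gam = mom.sigma, mom.lagged(tau)

        def cond(idx):
            s = sig[np.ix_(idx, idx)]
            g = gam[np.ix_(idx, idx)]
            return s - g @ np.linalg.inv(s) @ g.T

        def ent(idx):
            k = len(idx)
            s = sig[np.ix_(idx, idx)]
            return 0.5 * np.log2((2 * np.pi * np.e) ** k * np.linalg.det(s))

        best = None
        from itertools import combinations

        channels = list(range(4))
        for r in range(1, 4):
            for m1 in combinations(channels, r):
                if 0 not in m1:
                    continue
                m2 = tuple(c for c in channels if c not in m1)
                phi = 0.5 * (
                    -np.log2(np.linalg.det(cond(list(range(4)))))
                    + np.log2(np.linalg.det(cond(list(m1))))
                    + np.log2(np.linalg.det(cond(list(m2))))
                )
                k2 = min(ent(list(m1)), ent(list(m2)))
                score = phi / k2
                if best is None or score < best[0]:
                    best = (score, m1, m2, phi)

        mib, phi, _ = ig.minimum_information_bipartition(m, tau)
        assert set(mib.M1) == set(best[1])
        assert set(mib.M2) == set(best[2])
        assert phi == pytest.approx(best[3], rel=1e-9)

    def test_d1_rejected(self):
        m = scalar_ar1()
        with pytest.raises(ValueError, match="at least 2"):
            ig.minimum_information_bipartition(m, 1)

    def test_channel_cap(self):
        m = random_stable_mvarx(5, 1, 0, spectral_radius_target=0.5, seed=18)
        with pytest.raises(ValueError, match="cap"):
            ig.minimum_information_bipartition(m, 1, max_channels=4)


class TestPhiProfile:
    def test_zero_dynamics_flat_zero(self):
        m = MVARXModel(A=np.zeros((1, 3, 3)), B=np.zeros((3, 1)), Q=np.eye(3))
        prof = ig.phi_profile(m, tau_grid=range(1, 6))
        assert np.allclose(prof.phi, 0.0, atol=1e-12)

    def test_finite_and_bounded(self):
        m = random_stable_mvarx(4, 3, 0, spectral_radius_target=0.9, seed=19)
        prof = ig.phi_profile(m, tau_grid=range(1, 31))
        assert np.all(np.isfinite(prof.phi))
        assert prof.phi_max >= prof.phi.min()
        assert prof.tau_argmax in prof.taus

    def test_superset_grid_never_decreases_max(self):
        m = random_stable_mvarx(4, 2, 0, spectral_radius_target=0.85, seed=20)
        coarse = ig.phi_profile(m, tau_grid=[2, 6, 10])
        fine = ig.phi_profile(m, tau_grid=[1, 2, 3, 4, 5, 6, 8, 10, 12])
        assert fine.phi_max >= coarse.phi_max - 1e-12

    def test_decoupling_continuity(self):
        part_vals = []
        for c in [0.2, 0.1, 0.05, 0.02, 0.0]:
            m = block_model(seed=21, coupling=c)
            phi = ig.effective_information(m, 2,
                                           ig.Bipartition((0, 1), (2, 3)))
            part_vals.append(phi)
        assert all(np.diff(part_vals) <= 1e-12)
        assert part_vals[-1] == pytest.approx(0.0, abs=1e-9)


class TestCompareConditions:
    def test_identical_samples(self):
        assert ig.compare_conditions([1.0, 1.0, 1.0],
                                     [1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_full_separation_exact_p(self):
        # fully separated 7 vs 7: two-sided exact p = 2 / C(14, 7)
        from math import comb

        a = list(range(1, 8))
        b = [x + 100 for x in a]
        assert ig.compare_conditions(a, b) == pytest.approx(2 / comb(14, 7))

    def test_argument_symmetry(self):
        rng = np.random.default_rng(22)
        a = list(rng.normal(0, 1, 9))
        b = list(rng.normal(0.5, 1, 7))
        assert ig.compare_conditions(a, b) == pytest.approx(
            ig.compare_conditions(b, a))

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            ig.compare_conditions([1.0], [2.0, 3.0])
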