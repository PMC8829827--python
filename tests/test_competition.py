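import numpy as np
import pytest
from scipy.optimize import brentq

from iondiff import (CompetitionSystem, ExchangeParameters, NoiseModel,
                     apparent_D, apparent_D_competition, bound_sodium, fit_Q)
from iondiff.simulate import gen_competition_series

from conftest import A_IONS, D_B, D_F, NA_BUFFER, NA_TOTAL, Q_TRUE, T_CAPACITY


def bisection_bound_sodium(Q, Na_total, K_total, T):
    """Independent oracle: root of the primitive equilibrium
    Q [Na_f][K_b] = [Na_b][K_f] under the three mass balances."""
    if T == 0:
        return 0.0

    def f(nb):
        kb = T - nb
        kf = K_total - kb
        nf = Na_total - nb
        return Q * nf * kb - nb * kf

    lo = max(0.0, T - K_total)
    hi = min(T, Na_total)
    if f(lo) == 0:
        return lo
    return brentq(f, lo, hi, xtol=1e-18, rtol=1e-14)


class TestBoundSodium:
    def _sys(self, Q, K, Na=NA_TOTAL, T=T_CAPACITY):
        return CompetitionSystem(Na, K, T, Q, D_F, D_B)

    def test_no_competitor_fills_capacity(self):
        # K = 0: every atmosphere site holds Na+, independent of Q
        for Q in [0.1, 0.58, 1.0, 3.0]:
            assert bound_sodium(self._sys(Q, 0.0)) == pytest.approx(
                T_CAPACITY, rel=1e-12)

    def test_no_preference_closed_form(self):
        # Q = 1: N_b = Na_total T / (Na_total + K_total)
        nb = bound_sodium(self._sys(1.0, 0.100))
        assert nb * 1e3 == pytest.approx(64.37 * 44.37 / 164.37, rel=1e-10)

    def test_reference_composition(self):
        nb = bound_sodium(self._sys(Q_TRUE, 0.100))
        assert nb * 1e3 == pytest.approx(13.33, abs=0.01)

    def test_continuity_through_Q_equal_1(self):
        eps = 1e-10
        below = bound_sodium(self._sys(1.0 - eps, 0.080))
        above = bound_sodium(self._sys(1.0 + eps, 0.080))
        assert below == pytest.approx(above, rel=1e-8)

    def test_bisection_oracle_grid(self):
        # 10 x 10 x 10 grid of (Q, K_total, T_capacity)
        for Q in np.geomspace(0.05, 20.0, 10):
            for K in np.linspace(0.0, 0.150, 10):
                for T in np.linspace(0.005, 0.044, 10):
                    sys_ = CompetitionSystem(NA_TOTAL, K, T, Q, D_F, D_B)
                    ours = bound_sodium(sys_)
                    oracle = bisection_bound_sodium(Q, NA_TOTAL, K, T)
                    assert ours == pytest.approx(oracle, rel=1e-9, abs=1e-15)

    def test_conservation(self):
        for Q in [0.3, 1.0, 2.5]:
            for K in [0.01, 0.08, 0.15]:
                nb = bound_sodium(self._sys(Q, K))
                kb = T_CAPACITY - nb
                assert 0.0 <= nb <= min(T_CAPACITY, NA_TOTAL)
                assert 0.0 <= kb <= K

    def test_overfull_atmosphere_rejected(self):
        with pytest.raises(ValueError, match="cannot hold"):
            CompetitionSystem(0.010, 0.0, 0.020, 1.0, D_F, D_B)


class TestApparentDCompetition:
    def test_zero_KCl_matches_two_state_model(self, competition_template,
                                              exchange_params):
        # the competition model must reduce to the plain exchange model
        d_comp = apparent_D_competition(competition_template)
        d_two_state = apparent_D(exchange_params, 1.74e-3)
        assert d_comp == pytest.approx(d_two_state, rel=1e-10)

    def test_high_KCl_approaches_free_diffusion(self):
        sys_ = CompetitionSystem(NA_TOTAL, 1e3, T_CAPACITY, Q_TRUE, D_F, D_B)
        assert apparent_D_competition(sys_) == pytest.approx(D_F, rel=1e-3)

    def test_reference_value_at_100mM(self):
        sys_ = CompetitionSystem(NA_TOTAL, 0.100, T_CAPACITY, Q_TRUE, D_F, D_B)
        assert apparent_D_competition(sys_) == pytest.approx(1.14e-9, abs=0.005e-9)

    def test_monotone_in_KCl_and_capacity(self):
        ks = np.linspace(0.0, 0.150, 12)
        ds = [apparent_D_competition(
            CompetitionSystem(NA_TOTAL, k, T_CAPACITY, Q_TRUE, D_F, D_B))
            for k in ks]
        assert np.all(np.diff(ds) >= 0)
        ts = np.linspace(0.0, 0.044, 12)
        dts = [apparent_D_competition(
            CompetitionSystem(NA_TOTAL, 0.05, t, Q_TRUE, D_F, D_B))
            for t in ts]
        assert np.all(np.diff(dts) <= 0)


class TestFitQ:
    def test_noiseless_round_trip(self, competition_template, noiseless):
        ts = gen_competition_series(competition_template, noiseless)
        fit = fit_Q(ts.x, ts.y, NA_TOTAL, T_CAPACITY, D_F, D_B)
        assert fit.estimate == pytest.approx(Q_TRUE, rel=1e-6)

    def test_monte_carlo_mean_within_envelope(self, competition_template):
        estimates = []
        for s in range(200):
            ts = gen_competition_series(
                competition_template,
                NoiseModel(sigma=0.01, seed=s, n_replicates=1))
            estimates.append(fit_Q(ts.x, ts.y, NA_TOTAL, T_CAPACITY,
                                   D_F, D_B).estimate)
        assert abs(np.mean(estimates) - Q_TRUE) <= 0.09

    def test_species_relabeling_inverts_Q(self, noiseless):
        # swapping which cation is observed maps Q to 1/Q; the printed
        # ammonium/potassium pair 1/0.53 = 1.89 is the field convention
        assert 1.0 / 0.53 == pytest.approx(1.89, abs=0.005)
        template = CompetitionSystem(NA_TOTAL, 0.0, T_CAPACITY, 2.0, D_F, D_B)
        ts = gen_competition_series(template, noiseless)
        fit = fit_Q(ts.x, ts.y, NA_TOTAL, T_CAPACITY, D_F, D_B)
        assert 1.0 / fit.estimate == pytest.approx(0.5, rel=1e-5)
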