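"""Association constants by three titration routes, and free energies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluorbind.binding import (
    AnisotropyTitration,
    TitrationSeries,
    fit_anisotropy_binding,
    fit_benesi_hildebrand,
    fit_stern_volmer,
    free_energy,
)
from fluorbind.exceptions import DomainError, FitError
from fluorbind.simulate import (
    QuenchingConfig,
    TitrationConfig,
    gen_quenching,
    gen_titration,
)


def make_anisotropy_titration(K, r_f=0.01, r_b=0.30, R=6.0, n=10, p_max_uM=60.0):
    """Exact single-site anisotropy series: (r-r_f)/(R(r_b-r)) = K [P]."""
    P_uM = np.linspace(0.0, p_max_uM, n)
    x = K * P_uM * 1e-6 * R
    r = (r_f + x * r_b) / (1.0 + x)
    return AnisotropyTitration(
        protein_conc_uM=P_uM, r_obs=r, r_f=r_f, r_b=r_b, quantum_yield_ratio=R
    )


class TestBenesiHildebrand:
    def test_noisefree_recovery_nonlinear(self):
        series = gen_titration(TitrationConfig(noise_frac=0.0), seed=0)
        fit = fit_benesi_hildebrand(series, f_inf_mode="fit")
        assert fit.k_assoc == pytest.approx(4.72e4, rel=0.01)
        assert fit.f_inf == pytest.approx(2.9, rel=0.01)

    def test_noisefree_recovery_linear_with_true_finf(self):
        series = gen_titration(TitrationConfig(noise_frac=0.0), seed=0)
        fit = fit_benesi_hildebrand(series, f_inf_mode="fixed", f_inf=2.9)
        assert fit.k_assoc == pytest.approx(4.72e4, rel=0.01)
        assert fit.intercept == pytest.approx(1.0, abs=0.01)

    def test_linear_and_nonlinear_agree_noisefree(self):
        series = gen_titration(TitrationConfig(noise_frac=0.0), seed=0)
        k_lin = fit_benesi_hildebrand(series, "fixed", f_inf=2.9).k_assoc
        k_nl = fit_benesi_hildebrand(series, "fit").k_assoc
        assert k_lin == pytest.approx(k_nl, rel=0.01)

    def test_flat_series_fails(self):
        series = TitrationSeries(np.linspace(0, 50, 8), np.full(8, 1.7))
        with pytest.raises(FitError):
            fit_benesi_hildebrand(series, f_inf_mode="fit")

    def test_noisy_median_recovery(self):
        """2% multiplicative noise, 20 seeds: median |K error| <= 10%."""
        errs = []
        for seed in range(20):
            series = gen_titration(TitrationConfig(noise_frac=0.02), seed)
            k = fit_benesi_hildebrand(series, "fit").k_assoc
            errs.append(abs(k - 4.72e4) / 4.72e4)
        assert np.median(errs) <= 0.10

    def test_mass_balance_round_trip(self):
        """Data generated with explicit 1:1 mass balance is recovered by the
        mass-balance fit, not by the excess-protein hyperbola."""
        series = gen_titration(
            TitrationConfig(noise_frac=0.0, mass_balance=True), seed=0
        )
        from fluorbind.binding import BenesiHildebrandModel

        k_mb = BenesiHildebrandModel(series).fit_nonlinear(mass_balance=True).k_assoc
        assert k_mb == pytest.approx(4.72e4, rel=0.01)


class TestAnisotropyBinding:
    def test_noisefree_recovery(self):
        a = make_anisotropy_titration(K=5.97e4)
        fit = fit_anisotropy_binding(a)
        assert fit.k_assoc == pytest.approx(5.97e4, rel=0.01)
        assert fit.method == "anisotropy"

    def test_flat_at_rf_fails(self):
        P = np.linspace(0, 60, 8)
        a = AnisotropyTitration(P, np.full(8, 0.01), 0.01, 0.30, 6.0)
        with pytest.raises(FitError):
            fit_anisotropy_binding(a)

    def test_yield_ratio_scaling(self):
        """Doubling R halves every y-value, hence halves the slope exactly."""
        a1 = make_anisotropy_titration(K=5e4, R=6.0)
        a2 = AnisotropyTitration(
            a1.protein_conc_uM, a1.r_obs, a1.r_f, a1.r_b, quantum_yield_ratio=12.0
        )
        k1 = fit_anisotropy_binding(a1).k_assoc
        k2 = fit_anisotropy_binding(a2).k_assoc
        assert k2 == pytest.approx(k1 / 2.0, rel=1e-9)


class TestSternVolmer:
    def test_noisefree_recovery_both_constants(self):
        q = gen_quenching(QuenchingConfig(k_sv=1e4, k_static=5e3, noise_frac=0.0), 0)
        fit = fit_stern_volmer(q)
        assert fit.k_sv == pytest.approx(1e4, rel=0.02)
        assert fit.k_static == pytest.approx(5e3, rel=0.02)

    def test_null_static_term_has_wide_ci(self):
        q = gen_quenching(QuenchingConfig(k_sv=1e4, k_static=0.0, noise_frac=0.002), 3)
        with pytest.warns(UserWarning):
            fit = fit_stern_volmer(q, static_term=True)
        assert fit.static_unresolved
        # 95% confidence interval includes zero
        assert fit.k_static - 1.96 * fit.stderr_static <= 0.0

    def test_linear_data_exact_ols_slope(self):
        L = np.linspace(0, 1e-4, 9)
        y = 1.0 + 1e4 * L
        from fluorbind.binding import QuenchingSeries

        fit = fit_stern_volmer(QuenchingSeries(L, y), static_term=False)
        assert fit.k_sv == pytest.approx(1e4, rel=1e-9)
        assert fit.k_static == 0.0

    def test_noisy_median_recovery(self):
        """1% noise over 20 replicates on a well-sampled (21-point)
        quenching curve: median dynamic-constant error <= 5%."""
        grid = tuple(np.linspace(0.0, 1e-4, 21))
        errs = []
        for seed in range(20):
            q = gen_quenching(QuenchingConfig(noise_frac=0.01, conc_M=grid), seed)
            errs.append(abs(fit_stern_volmer(q).k_sv - 1e4) / 1e4)
        assert np.median(errs) <= 0.05


class TestFreeEnergy:
    @pytest.mark.parametrize(
        "k, t, expected",
        [
            (1.0, 298.0, 0.0),
            (3.14e4, 298.0, -6.13),
            (6.2e4, 298.0, -6.53),
        ],
    )
    def test_values(self, k, t, expected):
        assert free_energy(k, t) == pytest.approx(expected, abs=0.005)

    @given(st.floats(1.0, 1e8), st.floats(1.1, 1e8))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_strictly_decreasing_in_k(self, k, factor):
        assert free_energy(k * factor) < free_energy(k)

    def test_domain(self):
        with pytest.raises(DomainError):
            free_energy(0.0)


class TestThreeMethodConsistency:
    def test_common_constant_recovered_by_all_methods(self):
        """One synthetic 1:1 system, K = 5e4 M^-1, analysed by all three
        routes: the estimates agree with each other and the truth."""
        K = 5e4
        tit = gen_titration(TitrationConfig(k_assoc=K, noise_frac=0.0), 0)
        k_bh = fit_benesi_hildebrand(tit, "fit").k_assoc
        k_an = fit_anisotropy_binding(make_anisotropy_titration(K)).k_assoc
        q = gen_quenching(QuenchingConfig(k_sv=0.0, k_static=K,
                                          conc_M=tuple(np.linspace(0, 6e-5, 10)),
                                          noise_frac=0.0), 0)
        k_sv = fit_stern_volmer(q).k_static
        for k in (k_bh, k_an, k_sv):
            assert k == pytest.approx(K, rel=0.02)
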