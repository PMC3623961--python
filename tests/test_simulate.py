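"""Synthetic-data generators: determinism, limits and round trips."""

import numpy as np
import pytest

from fluorbind.binding import fit_benesi_hildebrand, fit_stern_volmer
from fluorbind.decay import construct_anisotropy, fit_decay
from fluorbind.energy_transfer import PhosphorescenceAreas, efficiency_phosphorescence
from fluorbind.exceptions import DomainError
from fluorbind.simulate import (
    AnisotropyConfig,
    DecayConfig,
    PhosBandConfig,
    QuenchingConfig,
    TitrationConfig,
    gen_anisotropy_pair,
    gen_decay,
    gen_phos_spectrum,
    gen_quenching,
    gen_titration,
)


class TestDeterminism:
    def test_same_seed_identical_different_seed_same_expectation(self):
        cfg = DecayConfig()
        a = gen_decay(cfg, 7)
        b = gen_decay(cfg, 7)
        c = gen_decay(cfg, 8)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert not np.array_equal(a.counts, c.counts)
        # noise-free expectation is seed independent
        nf = DecayConfig(poisson=False)
        np.testing.assert_array_equal(gen_decay(nf, 7).counts, gen_decay(nf, 8).counts)

    def test_seed_mandatory(self):
        with pytest.raises(DomainError):
            gen_titration(TitrationConfig(), None)


class TestTitrationGenerator:
    def test_zero_k_gives_flat_series(self):
        s = gen_titration(TitrationConfig(k_assoc=0.0, noise_frac=0.0), 0)
        np.testing.assert_allclose(s.observable, 0.26)

    def test_saturation_limit(self):
        cfg = TitrationConfig(
            protein_grid_uM=(0.0, 5.0, 10.0, 20.0, 40.0, 1e6),
            noise_frac=0.0,
            f_inf=2.9,
        )
        s = gen_titration(cfg, 0)
        assert s.observable[-1] == pytest.approx(2.9, rel=1e-4)

    def test_round_trip(self):
        s = gen_titration(TitrationConfig(noise_frac=0.0), 0)
        assert fit_benesi_hildebrand(s, "fit").k_assoc == pytest.approx(
            4.72e4, rel=0.01
        )


class TestDecayGenerator:
    def test_zero_noise_counts_equal_model(self):
        c = gen_decay(DecayConfig(poisson=False), 0)
        assert c.peak_count == pytest.approx(1e4)
        # smooth: neighbouring channels differ by far less than shot noise
        inner = c.counts[c.counts > 100]
        assert np.max(np.abs(np.diff(inner))) < 5 * np.sqrt(1e4)

    def test_round_trip_mean_lifetime(self):
        """Study-condition biexponential round-trips <tau> ~ 1.45 ns."""
        fit = fit_decay(gen_decay(DecayConfig(), 2), n_components=2)
        assert fit.tau_mean_amplitude == pytest.approx(1.454, rel=0.03)

    def test_channel_width_halving_leaves_tau_unchanged(self):
        fine = DecayConfig(n_channels=2048, channel_width_ns=0.0125)
        f1 = fit_decay(gen_decay(DecayConfig(), 5), 2)
        f2 = fit_decay(gen_decay(fine, 5), 2)
        t1 = sorted(f1.taus, reverse=True)
        t2 = sorted(f2.taus, reverse=True)
        assert t1[0] == pytest.approx(t2[0], rel=0.02)
        assert t1[1] == pytest.approx(t2[1], rel=0.02)


class TestAnisotropyGenerator:
    def test_zero_r0_gives_equal_scaled_channels(self):
        cfg = AnisotropyConfig(r0=0.0, g_factor=1.3, decay=DecayConfig(poisson=False))
        p = gen_anisotropy_pair(cfg, 0)
        np.testing.assert_allclose(p.ivv, p.g_factor * p.ivh, rtol=1e-9)

    def test_construct_inverts_generation(self):
        """Noise-free narrow-IRF pair returns r(t) = r0 exp(-t/theta_c)."""
        cfg = AnisotropyConfig(
            r0=0.3,
            theta_c_ns=5.0,
            decay=DecayConfig(
                poisson=False, irf_fwhm_ns=0.01, irf_center_ns=0.3, n_channels=2048
            ),
        )
        p = gen_anisotropy_pair(cfg, 0)
        t, r = construct_anisotropy(p, min_total=1e-9)
        sel = (t > 1.0) & (t < 15.0)
        expected = 0.3 * np.exp(-(t[sel] - 0.3) / 5.0)
        np.testing.assert_allclose(r[sel], expected, rtol=0.02)


class TestQuenchingGenerator:
    def test_pure_dynamic_is_linear(self):
        q = gen_quenching(QuenchingConfig(k_sv=1e4, k_static=0.0, noise_frac=0.0), 0)
        slopes = np.diff(q.f0_over_f) / np.diff(q.quencher_conc_M)
        np.testing.assert_allclose(slopes, 1e4, rtol=1e-9)

    def test_round_trip(self):
        q = gen_quenching(QuenchingConfig(noise_frac=0.0), 0)
        fit = fit_stern_volmer(q)
        assert fit.k_sv == pytest.approx(1e4, rel=0.02)
        assert fit.k_static == pytest.approx(5e3, rel=0.02)

    def test_degenerate_grid(self):
        with pytest.raises(DomainError):
            gen_quenching(QuenchingConfig(conc_M=(0.0, 0.0, 0.0, 0.0, 0.0)), 0)


class TestPhosBandGenerator:
    def test_area_ratio_maps_to_efficiency(self):
        free = gen_phos_spectrum(PhosBandConfig(area=1.0))
        complexed = gen_phos_spectrum(PhosBandConfig(area=0.67))
        e = efficiency_phosphorescence(
            PhosphorescenceAreas(free.area(), complexed.area())
        )
        assert e == pytest.approx(0.33, abs=1e-6)

    def test_pure_gaussian_shape(self):
        """Without a vibronic shoulder the band is Gaussian in wavenumber:
        the analytic amplitude * sigma * sqrt(2 pi) area matches."""
        cfg = PhosBandConfig(vibronic_weight=0.0, area=2.0)
        s = gen_phos_spectrum(cfg)
        nu = 1e7 / s.wavelength
        sigma_nu = cfg.fwhm_cm1 / (2 * np.sqrt(2 * np.log(2)))
        peak = s.intensity.max()
        area_nu = -np.trapezoid(s.intensity, nu)  # nu decreasing with lambda
        assert area_nu == pytest.approx(peak * sigma_nu * np.sqrt(2 * np.pi), rel=1e-3)

    def test_vibronic_shoulder_does_not_move_origin(self):
        from fluorbind.steady_state import band_metrics

        s = gen_phos_spectrum(
            PhosBandConfig(vibronic_weight=0.3, grid_nm=(395.0, 470.0, 0.05))
        )
        m = band_metrics(s)
        assert m.lambda_max_nm == pytest.approx(412.8, abs=0.1)
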