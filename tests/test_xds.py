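import math

import numpy as np
import pytest
from scipy.integrate import simpson
from scipy.special import j0

from memkappa.simulate import NoiseModel, simulate_diffuse_map
from memkappa.units import mn_per_m_to_kbt_per_ang2
from memkappa.xds import (
    CailleModel,
    DiffuseMap,
    DiffuseSlice,
    DomainSizeModel,
    FitError,
    SmecticStackParams,
    TiltStackParams,
    caille_eta,
    correlation_xi,
    delta_u,
    emulate_slices,
    extract_slices,
    finite_size_factor,
    fit_kappa_B,
    scan_domain_size,
    structure_factor,
    tilt_emulation_scan,
    tilt_roughness,
    tilt_sigma_w2,
)
from oracles import oracle_delta_u, oracle_finite_size, oracle_tilt_roughness


class TestCailleParameters:
    def test_eta_published_stack(self, rbc_stack):
        assert caille_eta(rbc_stack) == pytest.approx(0.4439, abs=1e-4)

    def test_eta_scales_with_root_kappa(self):
        stiff = SmecticStackParams(kappa=20.0, B=2e-7, q1=0.084)
        assert caille_eta(stiff) == pytest.approx(0.4439 / math.sqrt(10), abs=2e-4)

    def test_xi_values(self, rbc_stack):
        assert correlation_xi(rbc_stack) == pytest.approx(56.23, abs=0.01)
        assert correlation_xi(
            SmecticStackParams(kappa=6.0, B=2e-7, q1=0.084)
        ) == pytest.approx(74.0, abs=0.05)
        assert correlation_xi(
            SmecticStackParams(kappa=3e-5, B=3e-5, d=74.8)
        ) == pytest.approx(1.0)

    def test_rigid_stack_limit(self):
        assert caille_eta(
            SmecticStackParams(kappa=2.0, B=1e6, q1=0.084)
        ) == pytest.approx(0.0, abs=1e-6)

    def test_monotonic_dependence_on_moduli(self, rbc_stack):
        softer = SmecticStackParams(kappa=4.0, B=2e-7, q1=0.084)
        stiffer_B = SmecticStackParams(kappa=2.0, B=4e-7, q1=0.084)
        assert caille_eta(softer) < caille_eta(rbc_stack)
        assert caille_eta(stiffer_B) < caille_eta(rbc_stack)
        assert correlation_xi(softer) > correlation_xi(rbc_stack)
        assert correlation_xi(stiffer_B) < correlation_xi(rbc_stack)

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="inconsistent"):
            SmecticStackParams(kappa=2, B=2e-7, d=74.8, q1=0.09)
        with pytest.raises(ValueError):
            SmecticStackParams(kappa=-1, B=2e-7, d=74.8)
        with pytest.raises(ValueError):
            SmecticStackParams(kappa=2, B=2e-7)
        st = SmecticStackParams(kappa=2, B=2e-7, q1=0.084)
        assert st.d == pytest.approx(2 * math.pi / 0.084)


class TestDeltaU:
    def test_zero_separation_same_membrane(self, rbc_stack):
        assert delta_u(0.0, 0, rbc_stack) == 0.0

    def test_frozen_oracle_values(self, rbc_stack):
        # adaptive x-space quadrature references, computed independently
        assert delta_u(rbc_stack.xi, 0, rbc_stack) == pytest.approx(
            147.5228, rel=2e-5
        )
        assert delta_u(200.0, 3, rbc_stack) == pytest.approx(489.9595, rel=2e-5)

    def test_matches_oracle_route(self, rbc_stack):
        for r, n in [(10.0, 0), (56.2, 1), (300.0, 0), (700.0, 5)]:
            ref = oracle_delta_u(r, n, rbc_stack.eta_c, rbc_stack.xi, rbc_stack.q1)
            assert delta_u(r, n, rbc_stack) == pytest.approx(ref, rel=1e-5)

    def test_symmetric_in_layer_index(self, rbc_stack):
        assert delta_u(123.0, -4, rbc_stack) == delta_u(123.0, 4, rbc_stack)

    def test_rigid_limit_vanishes(self):
        rigid = SmecticStackParams(kappa=1e8, B=1.0, d=74.8)
        assert delta_u(100.0, 0, rigid) == pytest.approx(0.0, abs=1e-4)
        assert delta_u(100.0, 3, rigid) == pytest.approx(0.0, abs=1e-4)

    def test_monotone_in_r_and_n(self, rbc_stack):
        rs = [1.0, 10.0, 56.0, 200.0, 800.0]
        v = [delta_u(r, 0, rbc_stack) for r in rs]
        assert all(a < b for a, b in zip(v, v[1:]))
        ns = [0, 1, 3, 8]
        vn = [delta_u(56.0, n, rbc_stack) for n in ns]
        assert all(a < b for a, b in zip(vn, vn[1:]))
        assert all(x >= 0 for x in v + vn)

    def test_log_slope_far_beyond_xi(self, rbc_stack):
        # for r >> ξ, δu_0 grows as (4η_c/q1²)·ln r (two uncorrelated points
        # each carrying the 2η_c/q1² log variance); verified against the
        # adaptive quadrature oracle
        slope = (
            delta_u(4000.0, 0, rbc_stack) - delta_u(2000.0, 0, rbc_stack)
        ) / math.log(2.0)
        expected = 4.0 * rbc_stack.eta_c / rbc_stack.q1**2
        assert slope == pytest.approx(expected, rel=0.02)

    def test_negative_r_rejected(self, rbc_stack):
        with pytest.raises(ValueError):
            delta_u(-1.0, 0, rbc_stack)


class TestFiniteSizeFactor:
    def test_normalization_at_zero_separation(self):
        assert finite_size_factor(0.0, 500.0, 125.0) == pytest.approx(1.0)
        assert finite_size_factor(0.0, 500.0, 0.0) == 1.0

    def test_sharp_triangle_when_sigma_zero(self):
        assert finite_size_factor(250.0, 500.0, 0.0) == pytest.approx(0.5)
        assert finite_size_factor(600.0, 500.0, 0.0) == 0.0

    def test_frozen_oracle_value(self):
        assert finite_size_factor(250.0, 500.0, 125.0) == pytest.approx(
            0.46665, abs=2e-5
        )

    def test_matches_oracle_route(self):
        for s in (50.0, 400.0, 700.0):
            assert finite_size_factor(s, 500.0, 125.0) == pytest.approx(
                oracle_finite_size(s, 500.0, 125.0), abs=1e-5
            )

    def test_monotone_decreasing(self):
        s = np.linspace(0, 900, 50)
        vals = finite_size_factor(s, 500.0, 125.0)
        assert np.all(np.diff(vals) <= 1e-12)
        assert np.all((vals >= 0) & (vals <= 1))


class TestStructureFactor:
    def test_even_in_qpar(self, rbc_stack, rbc_domains):
        model = CailleModel(rbc_stack.d, rbc_domains)
        assert model.structure_factor(rbc_stack, 0.168, -0.04) == pytest.approx(
            model.structure_factor(rbc_stack, 0.168, 0.04)
        )

    def test_rigid_limit_collapses_to_interference_sum(self, rbc_domains):
        # η_c → 0: the exp(-qz²δu/2) factor becomes 1 and S reduces to the
        # finite-size interference sum, reconstructed here directly
        rigid = SmecticStackParams(kappa=1e6, B=1e-2, d=74.8)
        qz, qpar = 2.0 * rigid.q1, 0.03
        S = structure_factor(qz, qpar, rigid, rbc_domains)
        r = np.linspace(0, 900, 4001)
        Hr = finite_size_factor(r, rbc_domains.Lr, rbc_domains.sigma_r)
        radial = simpson(r * Hr * j0(qpar * r), x=r)
        total = 0.0
        for n in range(40):
            Hz = finite_size_factor(n * rigid.d, rbc_domains.Lz, rbc_domains.sigma_z)
            if Hz <= 0:
                break
            total += (1 if n == 0 else 2) * Hz * math.cos(qz * n * rigid.d) * radial
        assert S == pytest.approx(total, rel=5e-3)

    def test_frozen_oracle_ratio(self, rbc_stack, rbc_domains):
        # brute-force oracle reference for the 2q₁ slice decay
        model = CailleModel(rbc_stack.d, rbc_domains)
        s = model.structure_factor(rbc_stack, 2 * rbc_stack.q1, [0.01, 0.02])
        assert s[1] / s[0] == pytest.approx(0.67811, rel=1e-3)

    def test_positive_on_fitted_range(self, rbc_stack, rbc_domains):
        model = CailleModel(rbc_stack.d, rbc_domains)
        for f in (2.0, 2.5):
            S = model.structure_factor(
                rbc_stack, f * rbc_stack.q1, np.linspace(0.01, 0.1, 19)
            )
            assert np.all(S > 0)

    def test_rejects_nonpositive_qz(self, rbc_stack, rbc_domains):
        model = CailleModel(rbc_stack.d, rbc_domains)
        with pytest.raises(ValueError):
            model.structure_factor(rbc_stack, 0.0, 0.05)


class TestTiltRoughness:
    def tilt(self, Kt=4.0):
        stack = SmecticStackParams(kappa=2.0, B=2e-7, d=74.8)
        return TiltStackParams.with_default_band(stack, Kt=Kt, Lr=500.0)

    def test_zero_at_contact(self):
        assert tilt_roughness(0.0, self.tilt()) == pytest.approx(0.0, abs=1e-12)

    def test_stiff_limit_vanishes(self):
        assert tilt_roughness(100.0, self.tilt(Kt=1e9)) == pytest.approx(
            0.0, abs=1e-6
        )
        assert tilt_sigma_w2(self.tilt(Kt=1e9)) == pytest.approx(0.0, abs=1e-6)

    def test_frozen_oracle_value(self):
        # K_t = 4 mN/m, band 2π/500 .. 2π/10, r = 100 Å, T = 310.15 K
        assert tilt_roughness(100.0, self.tilt()) == pytest.approx(130.77, rel=1e-3)

    def test_matches_oracle_route(self):
        t = self.tilt()
        kt_int = mn_per_m_to_kbt_per_ang2(4.0, t.stack.T)
        ref = oracle_tilt_roughness(55.0, kt_int, t.Qmin, t.Qmax)
        assert tilt_roughness(55.0, t) == pytest.approx(ref, rel=1e-6)

    def test_cross_membrane_constant_is_twice_variance(self):
        t = self.tilt()
        assert tilt_roughness(300.0, t, same_membrane=False) == pytest.approx(
            2 * tilt_sigma_w2(t)
        )
        # same-membrane roughness saturates towards the cross-membrane level
        assert tilt_roughness(5000.0, t) < 2 * tilt_sigma_w2(t)


class TestExtractSlices:
    def make_map(self, rows=None):
        qz = np.array([0.15, 0.168, 0.21])
        qpar = np.linspace(0.005, 0.105, 21)
        inten = np.ones((3, 21)) if rows is None else rows
        return DiffuseMap(qz=qz, qpar=qpar, intensity=inten,
                          sigma=0.1 * np.ones((3, 21)))

    def test_all_ones_map_gives_unit_slice(self):
        (sl,) = extract_slices(self.make_map(), [0.168], q_norm=0.01)
        assert np.allclose(sl.intensity, 1.0)

    def test_normalization_point_is_exactly_one(self):
        rows = np.outer([1, 2, 3], np.linspace(2.0, 1.0, 21))
        (sl,) = extract_slices(self.make_map(rows), [0.168], q_norm=0.055)
        assert np.interp(0.055, sl.qpar, sl.intensity) == pytest.approx(1.0)

    def test_row_interpolation(self):
        rows = np.vstack([np.full(21, 1.0), np.full(21, 2.0), np.full(21, 4.0)])
        (sl,) = extract_slices(self.make_map(rows), [0.189], q_norm=0.01)
        # halfway between the 0.168 and 0.21 rows: values (2+4)/2 = 3,
        # normalized to 1; uncertainties propagated by the same division
        assert np.allclose(sl.intensity, 1.0)
        assert np.allclose(sl.sigma, 0.1 * math.sqrt(0.5) / 3.0)

    def test_target_outside_grid_raises(self):
        with pytest.raises(ValueError, match="outside"):
            extract_slices(self.make_map(), [0.5])

    def test_zero_normalization_intensity_raises(self):
        rows = np.zeros((3, 21))
        dmap = self.make_map(rows)
        dmap.sigma = np.ones((3, 21))
        with pytest.raises(ValueError, match="zero intensity"):
            extract_slices(dmap, [0.168], q_norm=0.01)

    def test_generator_round_trip_matches_model_within_noise(
        self, rbc_stack, rbc_domains
    ):
        dmap = simulate_diffuse_map(
            rbc_stack, rbc_domains, noise=NoiseModel(kind="poisson"), seed=2
        )
        (sl, _) = extract_slices(
            dmap, [2 * rbc_stack.q1, 2.5 * rbc_stack.q1], q_norm=0.01
        )
        model = CailleModel(rbc_stack.d, rbc_domains)
        qq = np.append(sl.qpar, sl.q_norm)
        S = model.structure_factor(rbc_stack, sl.qz, qq)
        expected = S[:-1] / S[-1]
        dev = np.abs(sl.intensity - expected) / sl.sigma
        assert np.quantile(dev, 0.95) < 3.0


class TestFitKappaB:
    def test_noiseless_self_consistency(self, rbc_stack, rbc_domains):
        dmap = simulate_diffuse_map(
            rbc_stack, rbc_domains, noise=NoiseModel(kind="none")
        )
        slices = extract_slices(
            dmap, [2 * rbc_stack.q1, 2.5 * rbc_stack.q1], q_norm=0.01
        )
        init = SmecticStackParams(kappa=6.0, B=8e-8, d=rbc_stack.d)
        fit = fit_kappa_B(slices, init, rbc_domains)
        assert fit.stack.kappa == pytest.approx(2.0, rel=0.01)
        assert fit.stack.B == pytest.approx(2e-7, rel=0.01)
        assert not fit.at_bounds

    def test_flat_slice_never_silently_succeeds(self, rbc_stack, rbc_domains):
        qpar = np.linspace(0.01, 0.1, 20)
        flat = DiffuseSlice(
            qz=2 * rbc_stack.q1, qpar=qpar, intensity=np.ones(20),
            sigma=0.01 * np.ones(20), q_norm=0.01,
        )
        try:
            fit = fit_kappa_B([flat], rbc_stack, rbc_domains)
        except FitError:
            return
        assert fit.at_bounds

    def test_too_few_points_rejected(self, rbc_stack, rbc_domains):
        s = DiffuseSlice(qz=0.168, qpar=np.linspace(0.01, 0.1, 5),
                         intensity=np.ones(5), sigma=np.ones(5), q_norm=0.01)
        with pytest.raises(ValueError, match="10 points"):
            fit_kappa_B([s], rbc_stack, rbc_domains)
        with pytest.raises(ValueError, match="at least one"):
            fit_kappa_B([], rbc_stack, rbc_domains)


class TestDomainSizeScan:
    def test_single_entry_grid(self, rbc_stack, rbc_domains):
        dmap = simulate_diffuse_map(
            rbc_stack, rbc_domains, noise=NoiseModel(kind="none")
        )
        slices = extract_slices(
            dmap, [2 * rbc_stack.q1, 2.5 * rbc_stack.q1], q_norm=0.01
        )
        best, results = scan_domain_size(slices, rbc_stack, [500.0])
        assert best == 500.0 and set(results) == {500.0}

    def test_recovers_generating_domain_size(self, rbc_stack, rbc_domains):
        dmap = simulate_diffuse_map(
            rbc_stack, rbc_domains, noise=NoiseModel(kind="none")
        )
        slices = extract_slices(
            dmap, [2 * rbc_stack.q1, 2.5 * rbc_stack.q1], q_norm=0.01
        )
        best, results = scan_domain_size(
            slices, rbc_stack, [250.0, 500.0, 1000.0], criterion="chi2"
        )
        assert best == 500.0
        assert all(results[best].chi2 <= r.chi2 for r in results.values())

    def test_unknown_criterion_rejected(self, rbc_stack):
        with pytest.raises(ValueError, match="criterion"):
            scan_domain_size([None], rbc_stack, [500.0], criterion="bogus")


class TestTiltEmulation:
    def test_stiff_tilt_reproduces_tilt_free_structure_factor(
        self, rbc_stack, rbc_domains
    ):
        qpar = np.linspace(0.01, 0.1, 10)
        tilt = TiltStackParams.with_default_band(rbc_stack, Kt=1e9, Lr=500.0)
        with_tilt = emulate_slices(tilt, rbc_domains, [2 * rbc_stack.q1], qpar)
        model = CailleModel(rbc_stack.d, rbc_domains)
        qq = np.append(qpar, 0.01)
        S = model.structure_factor(rbc_stack, 2 * rbc_stack.q1, qq)
        assert np.allclose(with_tilt[0].intensity, S[:-1] / S[-1], rtol=1e-6)

    def test_higher_order_peaks_progressively_weaker(self, rbc_stack, rbc_domains):
        tilt = TiltStackParams.with_default_band(rbc_stack, Kt=4.0, Lr=500.0)
        model = CailleModel(rbc_stack.d, rbc_domains, tilt=tilt)
        peaks = [
            model.structure_factor(rbc_stack, n * rbc_stack.q1, 0.005)
            for n in (1, 2, 3)
        ]
        assert peaks[0] > peaks[1] > peaks[2]

    def test_fixed_seed_reproducible(self, rbc_stack, rbc_domains):
        tilt = TiltStackParams.with_default_band(rbc_stack, Kt=4.0, Lr=500.0)
        qpar = np.linspace(0.01, 0.1, 10)
        kw = dict(noise=NoiseModel(kind="gaussian"), seed=42)
        a = emulate_slices(tilt, rbc_domains, [2 * rbc_stack.q1], qpar, **kw)
        b = emulate_slices(tilt, rbc_domains, [2 * rbc_stack.q1], qpar, **kw)
        assert np.array_equal(a[0].intensity, b[0].intensity)

    def test_stiff_tilt_scan_returns_grid_point_nearest_target(self):
        scan = tilt_emulation_scan(
            [1.5, 2.0, 3.0], Kt=1e9, target_kappa_fit=2.0,
            qpar=np.linspace(0.01, 0.1, 19),
        )
        assert scan.best_kappa_emu == 2.0
        # with rigid tilt the re-fit reproduces the emulated modulus
        assert np.allclose(scan.kappa_fit, scan.kappa_emu, rtol=1e-3)
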