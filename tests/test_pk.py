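import numpy as np
import pytest
from scipy.integrate import solve_ivp

from osmoforge.pk import (
    DispositionParams,
    DrugProperties,
    PKError,
    PlasmaProfile,
    ReleaseInput,
    TransitModelConfig,
    calibrate_ka,
    fit_two_compartment,
    nca,
    relative_bioavailability,
    simulate_two_compartment_oral,
    simulate_two_compartment_oral_ode,
    superpose,
    transit_absorption_simulate,
)
from osmoforge.synth_data import generate_plasma


class TestTwoCompartmentOral:
    def test_one_compartment_limit_auc(self):
        """k12, k21 -> 0: AUCinf equals F*Dose/(CL*weight) to 0.1%."""
        d = DispositionParams(Vc=0.5, k12=1e-8, k21=1e-8, CL=0.2, body_weight=70.0)
        t = np.arange(0.0, 400.0, 0.05)
        prof = simulate_two_compartment_oral(d, 1.5, 0.8, 100.0, t)
        auc_mg_l_h = np.trapezoid(prof.conc_ng_ml, t) / 1000.0
        expected = 0.8 * 100.0 / (0.2 * 70.0)
        assert auc_mg_l_h == pytest.approx(expected, rel=1e-3)

    def test_fast_absorption_approaches_bolus(self, disposition):
        t = np.arange(0.0, 24.0, 0.01)
        prof = simulate_two_compartment_oral(disposition, 500.0, 0.7, 50.0, t)
        c0_expected = 0.7 * 50.0 / disposition.V_central * 1000.0
        assert prof.conc_ng_ml[:50].max() == pytest.approx(c0_expected, rel=0.05)

    def test_closed_form_matches_ode_oracle(self, disposition):
        t = np.arange(0.0, 48.1, 0.1)
        a = simulate_two_compartment_oral(disposition, 1.0, 0.7, 50.0, t)
        b = simulate_two_compartment_oral_ode(disposition, 1.0, 0.7, 50.0, t)
        scale = a.conc_ng_ml.max()
        assert np.max(np.abs(a.conc_ng_ml - b.conc_ng_ml)) / scale < 1e-6

    def test_coincident_eigenvalue_flagged(self):
        d = DispositionParams(Vc=1.0, k12=0.2, k21=0.1, CL=0.3)
        lam1, _ = d.eigenvalues()
        prof = simulate_two_compartment_oral(d, lam1, 0.7, 50.0, np.arange(0.0, 24.0, 0.5))
        assert any("coincident" in f for f in prof.flags)
        assert np.all(np.isfinite(prof.conc_ng_ml))

    def test_dose_linearity(self, disposition):
        t = np.arange(0.0, 48.0, 0.5)
        c1 = simulate_two_compartment_oral(disposition, 1.0, 0.7, 50.0, t).conc_ng_ml
        c2 = simulate_two_compartment_oral(disposition, 1.0, 0.7, 100.0, t).conc_ng_ml
        assert c2 == pytest.approx(2.0 * c1, rel=1e-12)

    def test_invalid_inputs(self, disposition):
        with pytest.raises(PKError):
            simulate_two_compartment_oral(disposition, -1.0, 0.7, 50.0, [0, 1])
        with pytest.raises(PKError):
            simulate_two_compartment_oral(disposition, 1.0, 1.5, 50.0, [0, 1])
        with pytest.raises(PKError):
            DispositionParams(Vc=0.0, k12=0.1, k21=0.1, CL=0.1)


class TestFitTwoCompartment:
    def test_noiseless_recovery(self, disposition, pk_sampling_times):
        prof, _ = generate_plasma(disposition, 1.3, 0.7, 50.0, pk_sampling_times, cv=0.0)
        fit, diag = fit_two_compartment(prof, 50.0, 0.7)
        for name in ("Vc", "k12", "k21", "CL"):
            assert getattr(fit, name) == pytest.approx(getattr(disposition, name), rel=1e-4)
        assert diag["ka"] == pytest.approx(1.3, rel=1e-4)

    def test_noise_bias_bound_200_seeds(self, disposition, pk_sampling_times):
        """10% proportional noise: median |bias| <= 10% per parameter."""
        errs = []
        for seed in range(200):
            prof, _ = generate_plasma(disposition, 1.3, 0.7, 50.0, pk_sampling_times,
                                      cv=0.10, seed=seed)
            fit, _ = fit_two_compartment(prof, 50.0, 0.7, n_restarts=2, seed=seed)
            errs.append([abs(getattr(fit, n) / getattr(disposition, n) - 1.0)
                         for n in ("Vc", "k12", "k21", "CL")])
        med = np.median(np.array(errs), axis=0)
        assert np.all(med <= 0.10), med

    def test_mono_exponential_pins_k12(self):
        d1 = DispositionParams(Vc=1.0, k12=1e-9, k21=0.5, CL=0.2)
        t = np.concatenate([np.arange(0.25, 6, 0.25), np.arange(6, 72, 2.0)])
        prof, _ = generate_plasma(d1, 1.5, 0.8, 100.0, t, cv=0.0)
        fit, diag = fit_two_compartment(prof, 100.0, 0.8)
        assert fit.k12 <= 1e-3
        assert any("mono-exponential" in w for w in diag["warnings"])

    def test_too_few_points_rejected(self):
        prof = PlasmaProfile(np.arange(1.0, 6.0), np.array([10.0, 8, 6, 4, 2.0]))
        with pytest.raises(PKError):
            fit_two_compartment(prof, 50.0, 0.7)


class TestTransitModel:
    def test_oracle_equivalence_instantaneous_release(self, disposition, drug_properties):
        """Instant release + fast transit ~ closed form with very large ka."""
        t = np.arange(0.05, 48.0, 0.05)
        release = ReleaseInput(np.array([0.0, 0.02]), np.array([0.0, 1.0]), 50.0)
        cfg = TransitModelConfig(gastric_emptying_rate=200.0,
                                 intestinal_radius_cm=0.005,     # ka ~ 470 / h
                                 transit_time_h=3.32,
                                 colon_absorption_scale=1.0,
                                 bioavailable_fraction=0.7)
        sim = transit_absorption_simulate(release, drug_properties, disposition, cfg, t)
        ref = simulate_two_compartment_oral(disposition, 500.0, 0.7, 50.0, t)
        scale = ref.conc_ng_ml.max()
        # compare away from the initial boundary layer
        mask = t > 0.5
        assert np.max(np.abs(sim.profile.conc_ng_ml[mask] - ref.conc_ng_ml[mask])) / scale < 0.01

    def test_mass_conservation(self, disposition, drug_properties):
        t = np.arange(0.5, 48.5, 0.5)
        rel_t = np.linspace(0.0, 16.0, 33)
        release = ReleaseInput(rel_t, rel_t / 16.0, 190.0)
        sim = transit_absorption_simulate(release, drug_properties, disposition,
                                          TransitModelConfig(bioavailable_fraction=0.7), t)
        assert sim.balance_error_max <= 1e-6

    def test_cr_input_shifts_tmax_and_lowers_cmax(self, disposition, drug_properties):
        t = np.arange(0.1, 48.1, 0.1)
        rel_t = np.linspace(0.0, 16.0, 33)
        release = ReleaseInput(rel_t, rel_t / 16.0, 190.0)
        cfg = TransitModelConfig(bioavailable_fraction=0.7)
        cr = transit_absorption_simulate(release, drug_properties, disposition, cfg, t)
        cr_nca = nca(cr.profile)
        assert cr_nca.Tmax >= 8.0
        # same-total-dose instantaneous release through the same chain
        inst = transit_absorption_simulate(
            ReleaseInput(np.array([0.0, 0.02]), np.array([0.0, 1.0]), 190.0),
            drug_properties, disposition, cfg, t)
        assert cr_nca.Cmax < nca(inst.profile).Cmax
        assert cr_nca.Tmax > nca(inst.profile).Tmax

    def test_dose_linearity(self, disposition, drug_properties):
        t = np.arange(0.5, 36.5, 0.5)
        rel_t = np.linspace(0.0, 12.0, 25)
        cfg = TransitModelConfig()
        a = transit_absorption_simulate(
            ReleaseInput(rel_t, rel_t / 12.0, 95.0), drug_properties, disposition, cfg, t)
        b = transit_absorption_simulate(
            ReleaseInput(rel_t, rel_t / 12.0, 190.0), drug_properties, disposition, cfg, t)
        assert b.profile.conc_ng_ml == pytest.approx(2.0 * a.profile.conc_ng_ml, rel=1e-6)

    def test_non_monotone_release_rejected(self):
        with pytest.raises(PKError):
            ReleaseInput(np.array([0.0, 1.0, 2.0]), np.array([0.0, 0.5, 0.4]), 50.0)


class TestSuperposition:
    def test_single_dose_identity(self, disposition):
        t = np.arange(0.0, 48.25, 0.25)
        prof = simulate_two_compartment_oral(disposition, 1.0, 0.7, 50.0, t)
        single = superpose(prof, 6.0, 1)
        assert single.conc_ng_ml == pytest.approx(prof.conc_ng_ml, rel=1e-12)

    def test_accumulation_inequalities(self, disposition):
        t = np.arange(0.0, 48.25, 0.25)
        prof = simulate_two_compartment_oral(disposition, 1.0, 0.7, 50.0, t)
        multi = superpose(prof, 6.0, 4)
        assert multi.conc_ng_ml.max() >= prof.conc_ng_ml.max()
        trough1 = multi.conc_ng_ml[np.searchsorted(t, 6.0)]
        trough4 = multi.conc_ng_ml[np.searchsorted(t, 24.0)]
        assert trough4 >= trough1

    def test_auc_linearity(self, disposition):
        # long horizon so AUCinf of single and multi are both well estimated
        t = np.arange(0.0, 2000.0, 0.25)
        prof = simulate_two_compartment_oral(disposition, 1.0, 0.7, 50.0, t)
        multi = superpose(prof, 6.0, 4)
        auc1 = nca(prof).AUCinf
        auc4 = nca(multi).AUCinf
        assert auc4 == pytest.approx(4.0 * auc1, rel=0.01)

    def test_matches_direct_multidose_ode(self, disposition):
        """Superposed closed form vs ODE with repeated gut boluses, <= 0.1%."""
        t = np.arange(0.0, 48.1, 0.1)
        prof = simulate_two_compartment_oral(disposition, 1.0, 0.7, 50.0, t,
                                             dose_times=(0.0, 6.0, 12.0, 18.0))
        k10, k12, k21, ka, F = (disposition.k10, disposition.k12,
                                disposition.k21, 1.0, 0.7)

        def rhs(_t, y):
            return [-ka * y[0],
                    ka * y[0] * F - (k10 + k12) * y[1] + k21 * y[2],
                    k12 * y[1] - k21 * y[2]]

        y = np.zeros(3)
        conc = np.zeros_like(t)
        for start, end in ((0.0, 6.0), (6.0, 12.0), (12.0, 18.0), (18.0, 48.0)):
            y[0] += 50.0
            seg = (t >= start) & (t <= end)
            sol = solve_ivp(rhs, (start, end), y, t_eval=t[seg],
                            method="LSODA", rtol=1e-11, atol=1e-13)
            conc[seg] = sol.y[1] / disposition.V_central * 1000.0
            y = sol.y[:, -1]
        assert np.max(np.abs(prof.conc_ng_ml - conc)) / conc.max() < 1e-3

    def test_short_horizon_flagged(self, disposition):
        t = np.arange(0.0, 10.25, 0.25)
        prof = simulate_two_compartment_oral(disposition, 1.0, 0.7, 50.0, t)
        multi = superpose(prof, 6.0, 4)
        assert any("extrapolated" in f for f in multi.flags)


class TestNCA:
    def test_mono_exponential_closed_form(self):
        t = np.arange(0.0, 60.5, 0.5)
        prof = PlasmaProfile(t, 100.0 * np.exp(-0.1 * t))
        res = nca(prof)
        assert res.lambda_z == pytest.approx(0.100, abs=1e-3)
        assert res.AUCinf == pytest.approx(1000.0, rel=5e-3)
        assert res.AUCinf >= res.AUCt

    def test_cmax_tmax_from_samples(self):
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        c = np.array([0.0, 40.0, 70.0, 55.0, 30.0])
        res = nca(PlasmaProfile(t, c))
        assert res.Cmax == 70.0
        assert res.Tmax == 2.0

    def test_refinement_reduces_auc_error(self):
        lam, horizon = 0.1, 60.0
        exact = 100.0 / lam * (1.0 - np.exp(-lam * horizon))
        errors = []
        for dt in (2.0, 1.0, 0.5, 0.25):
            t = np.arange(0.0, horizon + dt / 2, dt)
            res = nca(PlasmaProfile(t, 100.0 * np.exp(-lam * t)))
            errors.append(abs(res.AUCt - exact))
        assert all(b < a for a, b in zip(errors, errors[1:]))

    def test_non_declining_tail_flagged(self):
        t = np.arange(0.0, 10.0)
        c = np.concatenate([np.linspace(0, 50, 5), np.full(5, 50.0)])
        res = nca(PlasmaProfile(t, c))
        assert res.AUCinf is None
        assert res.lambda_z is None
        assert res.flags


class TestRelativeBioavailability:
    def test_published_exposure_ratios(self):
        assert relative_bioavailability(7388.4, 190, 7917.4, 200) == 98.23
        assert round(relative_bioavailability(7663.8, 190, 7917.4, 200), 1) == 101.9
        assert round(relative_bioavailability(7559.6, 190, 7917.4, 200), 1) == 100.5

    def test_identity(self):
        assert relative_bioavailability(1000.0, 50.0, 1000.0, 50.0) == 100.0

    def test_zero_dose_rejected(self):
        with pytest.raises(PKError):
            relative_bioavailability(1000.0, 0.0, 1000.0, 50.0)


class TestCalibration:
    def test_ka_hits_target_tmax(self, disposition):
        ka = calibrate_ka(disposition, 0.7, 50.0, target_tmax_h=1.12)
        t = np.arange(0.0, 12.0, 0.01)
        prof = simulate_two_compartment_oral(disposition, ka, 0.7, 50.0, t)
        tmax = t[np.argmax(prof.conc_ng_ml)]
        assert tmax == pytest.approx(1.12, abs=0.05)


class TestToxicThreshold:
    def test_cr_cmax_below_2000_ng_ml(self, disposition, drug_properties):
        """Release-rate-limited 190 mg input stays below the toxic level."""
        t = np.arange(0.25, 48.25, 0.25)
        rel_t = np.linspace(0.0, 16.0, 33)
        release = ReleaseInput(rel_t, rel_t / 16.0, 190.0)
        sim = transit_absorption_simulate(release, drug_properties, disposition,
                                          TransitModelConfig(bioavailable_fraction=0.7), t)
        assert nca(sim.profile).Cmax < 2000.0
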