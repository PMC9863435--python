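import math

import numpy as np
import pytest
from scipy.integrate import quad

from dermivivc.dpk import (
    estimate_sc_thickness_tewl,
    profile_auc,
    relative_depth_profile,
    strip_masses,
    study_auc,
)
from dermivivc.ivrt import run_arc
from dermivivc.synthetic import (
    IVRTSimConfig,
    TSSimConfig,
    sc_concentration_profile,
    sc_depth_fraction_integral,
    simulate_ivrt_run,
    simulate_tape_strip_study,
)


class TestConfigValidation:
    def test_ivrt_invalid_field_named(self):
        with pytest.raises(ValueError, match="sample_volume"):
            IVRTSimConfig(true_arc=10, sample_volume=8.0)
        with pytest.raises(ValueError, match="n_cells"):
            IVRTSimConfig(true_arc=10, n_cells=1)
        with pytest.raises(ValueError, match="sample_times"):
            IVRTSimConfig(true_arc=10, sample_times=(30, 15, 45))
        with pytest.raises(ValueError, match="noise_cv"):
            IVRTSimConfig(true_arc=10, noise_cv=-0.1)

    def test_ts_invalid_field_named(self):
        with pytest.raises(ValueError, match="n_strips"):
            TSSimConfig(n_strips=2)
        with pytest.raises(ValueError, match="sc_thickness_mean"):
            TSSimConfig(sc_thickness_mean=0)
        with pytest.raises(ValueError, match="strip_mass_decay"):
            TSSimConfig(strip_mass_decay=1.0)


class TestSimulateIVRT:
    def test_zero_noise_inversion(self):
        cfg = IVRTSimConfig(true_arc=37.80, noise_cv=0.0, cell_arc_cv=0.0, seed=0)
        run, _ = simulate_ivrt_run(cfg, "ref")
        res = run_arc(run)
        np.testing.assert_allclose(res.cell_slopes, 37.80, rtol=1e-9)

    def test_nonzero_intercept_round_trip(self):
        cfg = IVRTSimConfig(true_arc=20.0, intercept_true=5.0, noise_cv=0.0,
                            cell_arc_cv=0.0, seed=0)
        run, _ = simulate_ivrt_run(cfg, "p")
        res = run_arc(run)
        np.testing.assert_allclose(res.cell_slopes, 20.0, rtol=1e-9)
        assert res.fits[0].intercept == pytest.approx(5.0, rel=1e-9)

    def test_parameter_recovery_vs_drawn_slopes(self):
        cfg = IVRTSimConfig(true_arc=37.80, seed=21)
        run, truth = simulate_ivrt_run(cfg, "ref")
        res = run_arc(run)
        # oracle: the generator's own drawn cell slopes (2% sampling noise
        # propagates into each fitted slope, hence the loose tolerance)
        np.testing.assert_allclose(res.cell_slopes, truth.cell_slopes, rtol=0.15)
        se = res.arc_sd / math.sqrt(res.n_cells)
        assert abs(res.arc_mean - 37.80) <= 3 * max(se, 1e-6)

    def test_seed_determinism(self):
        cfg = IVRTSimConfig(true_arc=30.0, seed=99)
        run_a, truth_a = simulate_ivrt_run(cfg, "p")
        run_b, truth_b = simulate_ivrt_run(cfg, "p")
        np.testing.assert_array_equal(truth_a.cell_slopes, truth_b.cell_slopes)
        for ca, cb in zip(run_a.cells, run_b.cells):
            np.testing.assert_array_equal(ca.concentrations, cb.concentrations)


class TestSCConcentrationProfile:
    def test_sink_boundary(self):
        for t in (1.0, 60.0, 1e6):
            assert sc_concentration_profile(1.0, t, 100.0, 0.002) == 0.0

    def test_steady_state_limit(self):
        # t → ∞ leaves the linear profile K·Cv·(1 − u)
        assert sc_concentration_profile(0.5, 1e9, 100.0, 0.002) == pytest.approx(50.0)
        assert sc_concentration_profile(0.25, 1e9, 100.0, 0.002) == pytest.approx(75.0)

    def test_monotone_decreasing_in_depth(self):
        u = np.linspace(0, 1, 101)
        c = sc_concentration_profile(u, 60.0, 100.0, 0.002)
        assert np.all(np.diff(c) <= 1e-9)
        assert np.all(c >= 0)

    def test_invalid_time(self):
        with pytest.raises(ValueError, match="time"):
            sc_concentration_profile(0.5, 0.0, 100.0, 0.002)

    def test_against_finite_difference_oracle(self):
        # explicit FTCS solution of ∂c/∂τ = ∂²c/∂u² with c(0)=1, c(1)=0, c(·,0)=0
        nx = 201
        u = np.linspace(0, 1, nx)
        du = u[1] - u[0]
        dtau = 0.2 * du**2
        tau_end = 0.002 * 60.0
        c = np.zeros(nx)
        c[0] = 1.0
        steps = int(round(tau_end / dtau))
        dtau = tau_end / steps
        lam = dtau / du**2
        for _ in range(steps):
            c[1:-1] = c[1:-1] + lam * (c[2:] - 2 * c[1:-1] + c[:-2])
        for uf in (0.2, 0.5, 0.8):
            series = sc_concentration_profile(uf, 60.0, 1.0, 0.002)
            fd = np.interp(uf, u, c)
            assert series == pytest.approx(fd, abs=0.005)

    def test_depth_integral_matches_quadrature(self):
        for (u1, u2) in [(0.0, 0.3), (0.2, 0.7), (0.5, 1.0)]:
            analytic = sc_depth_fraction_integral(u1, u2, 60.0, 0.002)
            numeric, _ = quad(
                lambda u: sc_concentration_profile(u, 60.0, 1.0, 0.002), u1, u2,
                limit=200,
            )
            assert analytic == pytest.approx(numeric, abs=1e-9)


def _analyze_aucs(study, product, use_true_thickness=True):
    if use_true_thickness:
        thickness = study.sc_thickness
    else:
        thickness = {pid: estimate_sc_thickness_tewl(s, site_area=study.config.site_area)
                     for pid, s in study.tewl_series.items()}
    profiles = [relative_depth_profile(s, thickness[s.participant_id],
                                       sc_density=study.config.sc_density)
                for s in study.sites if s.product_id == product]
    return study_auc(profiles, product)


class TestSimulateTapeStrip:
    def test_linearity_in_product_scale(self):
        # zero mass noise so both products' sites remove identical SC layers
        cfg = TSSimConfig(n_participants=3, drug_noise_cv=0.0, strip_mass_cv=0.0,
                          seed=8)
        study = simulate_tape_strip_study(cfg, ["a", "b"], {"a": 1.0, "b": 2.0})
        for pid in study.sc_thickness:
            sa = next(s for s in study.sites
                      if s.participant_id == pid and s.product_id == "a")
            sb = next(s for s in study.sites
                      if s.participant_id == pid and s.product_id == "b")
            np.testing.assert_allclose(sb.drug_amount, 2 * sa.drug_amount,
                                       rtol=1e-9)
        auc_a = _analyze_aucs(study, "a").auc_mean
        auc_b = _analyze_aucs(study, "b").auc_mean
        assert auc_b == pytest.approx(2 * auc_a, rel=1e-9)

    def test_study_auc_cv_in_plausible_band(self):
        # regime check against the published 77.46 ± 13.48 (CV ≈ 17%)
        cvs = []
        for seed in range(5):
            study = simulate_tape_strip_study(TSSimConfig(seed=seed), ["a"],
                                              {"a": 1.0})
            res = _analyze_aucs(study, "a", use_true_thickness=False)
            cvs.append(res.auc_sd / res.auc_mean)
        assert 0.10 <= np.mean(cvs) <= 0.30

    def test_tewl_zero_noise_recovers_thickness(self):
        cfg = TSSimConfig(n_participants=4, tewl_noise_cv=0.0, seed=13)
        study = simulate_tape_strip_study(cfg, ["a"], {"a": 1.0})
        for pid, series in study.tewl_series.items():
            est = estimate_sc_thickness_tewl(series, site_area=cfg.site_area,
                                             sc_density=cfg.sc_density)
            assert est == pytest.approx(study.sc_thickness[pid], rel=1e-9)

    def test_missing_product_scale_rejected(self):
        with pytest.raises(ValueError, match="b"):
            simulate_tape_strip_study(TSSimConfig(n_participants=2, seed=1),
                                      ["a", "b"], {"a": 1.0})

    def test_mass_sanity(self):
        cfg = TSSimConfig(seed=3)
        study = simulate_tape_strip_study(cfg, ["a"], {"a": 1.0})
        dose_ug = cfg.dose_mass * 1000.0
        for site in study.sites:
            assert np.all(site.drug_amount >= 0)
            assert site.drug_amount.sum() <= dose_ug
        # strip masses stay below the SC mass implied by thickness
        for (pid, label), masses in study.true_site_masses.items():
            sc_mass = (study.sc_thickness[pid] * 1e-4 * cfg.site_area
                       * cfg.sc_density * 1e6)
            assert masses.sum() < sc_mass

    def test_seed_determinism_byte_identical(self, tmp_path):
        from dermivivc.io import write_tapestrip_csv, write_tewl_csv
        cfg = TSSimConfig(n_participants=3, seed=42)
        paths = []
        for tag in ("a", "b"):
            study = simulate_tape_strip_study(cfg, ["x"], {"x": 1.0})
            p1 = tmp_path / f"strips_{tag}.csv"
            p2 = tmp_path / f"tewl_{tag}.csv"
            write_tapestrip_csv(study.sites, p1)
            write_tewl_csv(list(study.tewl_series.values()), p2)
            paths.append((p1.read_bytes(), p2.read_bytes()))
        assert paths[0] == paths[1]

    def test_zero_noise_full_round_trip(self):
        # every generator parameter is recovered by the analysis stages
        cfg = TSSimConfig(n_participants=3, drug_noise_cv=0.0, tewl_noise_cv=0.0,
                          strip_mass_cv=0.0, seed=17)
        study = simulate_tape_strip_study(cfg, ["a"], {"a": 1.0})
        for site in study.sites:
            masses = strip_masses(site)
            np.testing.assert_allclose(
                masses, study.true_site_masses[(site.participant_id, site.site)],
                rtol=1e-9, atol=1e-8,
            )
        for pid, series in study.tewl_series.items():
            est = estimate_sc_thickness_tewl(series, site_area=cfg.site_area)
            assert est == pytest.approx(study.sc_thickness[pid], rel=1e-9)
        for site in study.sites:
            if site.product_id == "blank":
                continue
            prof = relative_depth_profile(site,
                                          study.sc_thickness[site.participant_id])
            np.testing.assert_allclose(
                prof.drug_amount,
                study.true_site_amounts[(site.participant_id, site.site)],
                rtol=1e-9,
            )
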