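"""Synthetic campaign generator: curves, measurement model, full campaigns."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import small_spec
from patchflux.emissions import cumulative_table, ef_table
from patchflux.flux import estimate_all_fluxes, fit_chamber_slope, ideal_gas_flux
from patchflux.inference import splitplot_anova
from patchflux.io import validate_campaign
from patchflux.simulate import (
    CampaignDesignSpec,
    FluxCurveParams,
    simulate_campaign,
    simulate_chamber_series,
    simulate_flux_curve,
)


class TestFluxCurve:
    def test_zero_amplitude_is_flat_baseline(self):
        p = FluxCurveParams(baseline=2.0, pulse_amplitude=0.0, pulse_peak_day=3.0)
        np.testing.assert_allclose(
            simulate_flux_curve(p, [-1, 0, 1, 5, 20]), 2.0
        )

    def test_maximum_is_baseline_plus_amplitude_at_peak(self):
        p = FluxCurveParams(baseline=1.0, pulse_amplitude=50.0, pulse_peak_day=4.0)
        t = np.linspace(-2, 30, 2000)
        f = simulate_flux_curve(p, t)
        assert simulate_flux_curve(p, [4.0])[0] == pytest.approx(51.0, rel=1e-12)
        assert f.max() <= 51.0 + 1e-9

    def test_closed_form_evaluation(self):
        # baseline 1, amplitude 100, peak 3 at t=6: 1 + 100*2*e^-1 = 74.5759
        p = FluxCurveParams(baseline=1.0, pulse_amplitude=100.0, pulse_peak_day=3.0)
        assert simulate_flux_curve(p, [6.0])[0] == pytest.approx(
            1 + 100 * 2 * math.exp(-1), rel=1e-12
        )

    def test_baseline_before_application(self):
        p = FluxCurveParams(baseline=0.7, pulse_amplitude=100.0, pulse_peak_day=3.0)
        np.testing.assert_allclose(simulate_flux_curve(p, [-5, -1]), 0.7)

    def test_decay_parameter_sharpens_tail_but_keeps_peak(self):
        slow = FluxCurveParams(baseline=0, pulse_amplitude=10, pulse_peak_day=3, pulse_decay=3)
        fast = FluxCurveParams(baseline=0, pulse_amplitude=10, pulse_peak_day=3, pulse_decay=1.5)
        assert simulate_flux_curve(fast, [3.0])[0] == pytest.approx(10.0)
        assert simulate_flux_curve(fast, [12.0])[0] < simulate_flux_curve(slow, [12.0])[0]

    def test_rain_coupling_multiplies_pulse_only(self):
        p = FluxCurveParams(baseline=1.0, pulse_amplitude=10.0, pulse_peak_day=3.0,
                            rain_coupling=0.1)
        f_dry = simulate_flux_curve(p, [3.0], rain_mm=[0.0])[0]
        f_wet = simulate_flux_curve(p, [3.0], rain_mm=[10.0])[0]
        assert f_wet == pytest.approx(1.0 + 10.0 * 2.0, rel=1e-12)
        assert f_dry == pytest.approx(11.0, rel=1e-12)


class TestChamberSeries:
    def test_noise_free_roundtrip_identity(self, geometry):
        rng = np.random.default_rng(0)
        for truth in (-1.0, 0.0, 3.7, 120.0):
            s = simulate_chamber_series(truth, geometry, 21.0, 99.0, 0.0, rng)
            est = ideal_gas_flux(fit_chamber_slope(s), geometry, 21.0, 99.0)
            assert est.flux == pytest.approx(truth, rel=1e-10, abs=1e-12)

    def test_zero_flux_zero_noise_is_flat_ambient(self, geometry):
        rng = np.random.default_rng(0)
        s = simulate_chamber_series(0.0, geometry, 25.0, 101.325, 0.0, rng)
        assert s.concentrations == [330.0] * 4
        assert s.minutes == [0.0, 15.0, 30.0, 45.0]

    def test_fixed_seed_reproduces_identical_series(self, geometry):
        a = simulate_chamber_series(5.0, geometry, 25.0, 101.325, 2.0,
                                    np.random.default_rng(77))
        b = simulate_chamber_series(5.0, geometry, 25.0, 101.325, 2.0,
                                    np.random.default_rng(77))
        assert a.concentrations == b.concentrations


class TestSimulateCampaign:
    def test_output_passes_validation_with_zero_violations(self, small_campaign):
        ds, _ = small_campaign
        assert validate_campaign(ds) == []

    def test_series_count_is_units_times_sampling_events(self, small_campaign):
        ds, _ = small_campaign
        spec_days = 7
        assert len(ds.series) == len(ds.units) * spec_days

    def test_identical_spec_and_seed_reproduce_identical_dataset(self):
        ds1, _ = simulate_campaign(small_spec(seed=5))
        ds2, _ = simulate_campaign(small_spec(seed=5))
        c1 = [s.concentrations for s in ds1.series]
        c2 = [s.concentrations for s in ds2.series]
        assert c1 == c2
        w1 = [w.rainfall for w in ds1.weather]
        w2 = [w.rainfall for w in ds2.weather]
        assert w1 == w2

    def test_adding_a_site_does_not_perturb_existing_sites(self):
        ds2, _ = simulate_campaign(small_spec(seed=5, n_sites=2))
        ds3, _ = simulate_campaign(
            small_spec(seed=5, n_sites=3, urine_n_kg_ha=(464, 789, 500),
                       site_mean_temp_c=(22, 27, 20))
        )
        s2 = {(s.chamber_id, str(s.deployment_date)): s.concentrations for s in ds2.series}
        s3 = {(s.chamber_id, str(s.deployment_date)): s.concentrations for s in ds3.series}
        assert all(s3[k] == v for k, v in s2.items())

    def test_equal_multipliers_give_unit_true_ef_ratio(self):
        # replicate dispersion off: the only LVC/AVC asymmetry is the multiplier
        ds, truth = simulate_campaign(
            small_spec(seed=9, condition_multipliers=(("LVC", 1.0), ("AVC", 1.0)),
                       replicate_effect_sigma=0.0)
        )
        assert truth.regional_ef_ratio == pytest.approx(1.0, rel=1e-9)

    def test_true_ef_satisfies_ef_formula_on_noisefree_cumulatives(self, small_campaign):
        ds, truth = small_campaign
        for _, row in truth.ef.dropna(subset=["true_ef_percent"]).iterrows():
            expect = (
                (row["true_emitted_kg_ha"] - row["true_control_kg_ha"])
                / row["n_applied_kg_ha"] * 100.0
            )
            assert row["true_ef_percent"] == pytest.approx(expect, rel=1e-12)

    def test_missing_urine_n_site_has_undefined_true_ef(self):
        ds, truth = simulate_campaign(small_spec(seed=4, urine_n_kg_ha=(464, None)))
        site2 = truth.ef[truth.ef["site"] == "S02"]
        assert site2["true_ef_percent"].isna().all()
        report = validate_campaign(ds)
        assert any(v.startswith("info:") and "S02" in v for v in report)

    def test_noise_free_pipeline_reproduces_ground_truth_exactly(self, noisefree_campaign):
        ds, truth = noisefree_campaign
        flux = estimate_all_fluxes(ds)
        cum = cumulative_table(flux, ds)
        merged = cum.merge(
            truth.cumulative, left_on="chamber_id", right_on="chamber_id"
        )
        np.testing.assert_allclose(
            merged["kg_n2o_n_per_ha"], merged["true_cumulative_kg_ha"],
            rtol=1e-10, atol=1e-12,
        )
        ef = ef_table(cum, ds)
        site_ef = ef.groupby(["site", "condition"])["ef_percent"].mean().reset_index()
        merged_ef = site_ef.merge(truth.ef, on=["site", "condition"])
        np.testing.assert_allclose(
            merged_ef["ef_percent"], merged_ef["true_ef_percent"], rtol=1e-9, atol=1e-12
        )

    def test_power_increases_with_condition_multiplier(self):
        """Split-plot Condition rejections rise monotonically with the true effect."""
        sims = 200
        rates = []
        for level, mult in enumerate((1.0, 1.8, 3.0)):
            rej = 0
            for k in range(sims):
                ds, _ = simulate_campaign(
                    small_spec(
                        seed=100_000 * (level + 1) + k,
                        n_sites=4,
                        urine_n_kg_ha=(464, 789, 546, 619),
                        site_mean_temp_c=(22, 27, 20, 18),
                        condition_multipliers=(("LVC", mult), ("AVC", 1.0)),
                        site_effect_sigma=0.3,
                    )
                )
                cum = cumulative_table(estimate_all_fluxes(ds), ds)
                d = cum.rename(columns={"site": "location", "treatment": "nitrogen"})
                d = d.assign(y=np.log(d["kg_n2o_n_per_ha"].clip(lower=1e-6)))
                p = splitplot_anova(d).set_index("source").loc["Condition", "p"]
                rej += p < 0.05
            rates.append(rej / sims)
        assert rates[0] < rates[1] < rates[2]
        assert rates[0] < 0.2  # near-null level stays low
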