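import numpy as np
import pytest

from slugflow.design_space import Setpoint, default_selfopt_space, sample_lhc
from slugflow.kinetics import initial_state, simulate
from slugflow.synthetic_reactor import (ImpurityChannels,
                                        InfeasibleSetpointError, NoiseSpec,
                                        PumpStock, SpectrumBatch,
                                        StockSolutions, compute_pump_rates,
                                        default_stocks, generate_spectra,
                                        make_spectrum_library, material_usage,
                                        records_from_frame, records_to_frame,
                                        run_experiment)


def _setpoint(**kw):
    base = dict(amine_equiv=1.28, conc=0.33, t_res=6.5, temp=135.0,
                dbu_equiv=1.61, cat_loading=4.85)
    base.update(kw)
    return Setpoint(**base)


class TestPumpRates:
    def test_rates_sum_to_makeup_rate(self, stocks):
        space = default_selfopt_space()
        for sp in sample_lhc(space, 100, seed=3):
            rates = compute_pump_rates(sp, stocks)
            assert sum(rates.values()) == pytest.approx(stocks.slug_makeup_rate, rel=1e-12)

    def test_mixing_balance_reconstructs_initial_state(self, stocks):
        """Composition from rates x stock concentrations equals the
        setpoint-derived slug composition."""
        space = default_selfopt_space()
        for sp in sample_lhc(space, 50, seed=4):
            rates = compute_pump_rates(sp, stocks)
            total = sum(rates.values())
            target = initial_state(sp)
            for name, pump in stocks.pumps.items():
                for species, c_stock in pump.species.items():
                    got = rates[name] / total * c_stock
                    assert got == pytest.approx(target[species], rel=1e-12)

    def test_equal_split_at_four_times_stocks(self):
        """Stocks at exactly 4x their targets put every reagent pump at a
        quarter of the total (solved by hand from the mixing balance)."""
        sp = _setpoint(amine_equiv=1.0, conc=0.3, dbu_equiv=1.0, cat_loading=100.0)
        stocks = StockSolutions(pumps={
            "aryl_bromide": PumpStock("aryl_bromide", {"A": 1.2}, 1.0),
            "amine": PumpStock("amine", {"B": 1.2}, 1.0),
            "dbu": PumpStock("dbu", {"DBU": 1.2}, 1.0),
            "catalyst": PumpStock("catalyst", {"Cat": 1.2}, 1.0),
            "solvent": PumpStock("solvent", {}, 1.0),
        })
        rates = compute_pump_rates(sp, stocks)
        for name in ("aryl_bromide", "amine", "dbu", "catalyst"):
            assert rates[name] == pytest.approx(0.25 * stocks.slug_makeup_rate)
        assert rates["solvent"] == pytest.approx(0.0, abs=1e-12)

    def test_nearly_pure_solvent_setpoint(self, stocks):
        sp = _setpoint(conc=1e-9)
        rates = compute_pump_rates(sp, stocks)
        assert rates["solvent"] == pytest.approx(stocks.slug_makeup_rate, rel=1e-6)

    def test_infeasible_composition_names_pump(self):
        stocks = default_stocks()
        weak = {**stocks.pumps,
                "amine": PumpStock("amine", {"B": 0.5}, 80.0)}
        stocks = StockSolutions(pumps=weak)
        with pytest.raises(InfeasibleSetpointError, match="amine"):
            compute_pump_rates(_setpoint(conc=0.5, amine_equiv=2.0), stocks)


class TestRunExperiment:
    def test_same_seed_identical_record(self, stocks, true_params, noise):
        a = run_experiment(_setpoint(), stocks, true_params, noise, seed=42)
        b = run_experiment(_setpoint(), stocks, true_params, noise, seed=42)
        assert a.measured == b.measured
        assert a.objectives.as_tuple() == b.objectives.as_tuple()

    def test_noise_free_record_equals_direct_simulation(self, stocks, true_params,
                                                        noise_free, no_impurities):
        sp = _setpoint()
        rec = run_experiment(sp, stocks, true_params, noise_free, seed=0,
                             impurities=no_impurities)
        course = simulate(sp, true_params, np.array([0.0, sp.t_res]),
                          rtol=1e-10, atol=1e-14)
        final = course.states.iloc[-1]
        assert rec.measured["1"] == pytest.approx(final["A"], rel=1e-12)
        assert rec.measured["2"] == pytest.approx(final["B"], rel=1e-12)
        assert rec.measured["3"] == pytest.approx(final["P"], rel=1e-12)
        assert rec.measured["nitrobenzene"] == 0.0
        assert rec.measured["unknown"] == 0.0

    def test_high_forcing_noiseless_yield_near_one(self, stocks, noise_free,
                                                   no_impurities):
        from slugflow.kinetics import KineticParams

        params = KineticParams(Ea=8.0e4, logA=9.8, k_side=0.0)
        sp = _setpoint(temp=140.0, cat_loading=6.0, t_res=12.0)
        rec = run_experiment(sp, stocks, params, noise_free, seed=0,
                             impurities=no_impurities)
        assert rec.yield_frac == pytest.approx(1.0, abs=5e-3)

    def test_noise_cv_recovery(self, stocks, true_params):
        """200 replicates at one setpoint show a product CV close to the
        configured 2% relative SD."""
        noise = NoiseSpec(rel_sd=0.02)
        vals = [run_experiment(_setpoint(), stocks, true_params, noise, seed=s).measured["3"]
                for s in range(200)]
        cv = np.std(vals) / np.mean(vals)
        assert cv == pytest.approx(0.02, abs=0.004)

    def test_impurity_directions(self, stocks, true_params, noise_free):
        """Nitrobenzene is promoted by temperature and amine loading and
        disfavoured by catalyst loading; the unknown impurity rises with
        DBU loading."""
        imp = ImpurityChannels()
        base = imp.nitrobenzene(_setpoint())
        assert imp.nitrobenzene(_setpoint(temp=140.0)) > base
        assert imp.nitrobenzene(_setpoint(amine_equiv=1.5)) > base
        assert imp.nitrobenzene(_setpoint(cat_loading=5.4)) < base
        assert imp.unknown(_setpoint(dbu_equiv=2.0)) > imp.unknown(_setpoint())

    def test_nitrobenzene_low_level_over_doe_box(self, stocks):
        """Below 7 mmol/L everywhere on the response-surface box."""
        import itertools

        imp = ImpurityChannels()
        for am, T, dbu, cat in itertools.product((1.07, 1.28), (130.0, 140.0),
                                                 (1.07, 1.61), (4.3, 5.4)):
            sp = _setpoint(amine_equiv=am, temp=T, dbu_equiv=dbu, cat_loading=cat)
            assert imp.nitrobenzene(sp) < 7e-3


class TestSpectra:
    def test_slug_window_mixture_and_baseline(self, stocks, true_params, noise_free):
        rec = run_experiment(_setpoint(), stocks, true_params, noise_free, seed=0)
        lib = make_spectrum_library(seed=99)
        batch = generate_spectra(rec, lib, seed=1, stocks=stocks,
                                 baseline_amp=0.0, noise_sd=0.0)
        assert np.all(np.diff(batch.timestamps) == pytest.approx(5.0))
        t0 = rec.slug_detect_time
        t1 = t0 + stocks.slug_window_s
        mixture = sum(rec.measured[a] * lib.pure[a] for a in ("1", "2", "3"))
        for t, spec in zip(batch.timestamps, batch.absorbances):
            if t0 <= t <= t1:
                np.testing.assert_allclose(spec, mixture, atol=1e-12)
            else:
                np.testing.assert_allclose(spec, 0.0, atol=1e-12)

    def test_single_species_slug_proportional_to_pure_spectrum(self, stocks):
        lib = make_spectrum_library(seed=99)
        rec_measured = {"1": 0.0, "2": 0.0, "3": 0.25,
                        "nitrobenzene": 0.0, "unknown": 0.0}
        from dataclasses import replace

        base = run_experiment(_setpoint(), stocks,
                              __import__("slugflow").KineticParams(Ea=8e4, logA=9.8),
                              NoiseSpec(0.0), seed=0)
        rec = replace(base, measured=rec_measured)
        batch = generate_spectra(rec, lib, seed=1, stocks=stocks,
                                 baseline_amp=0.0, noise_sd=0.0)
        in_window = (batch.timestamps >= rec.slug_detect_time) & \
                    (batch.timestamps <= rec.slug_detect_time + stocks.slug_window_s)
        spec = batch.absorbances[in_window][0]
        np.testing.assert_allclose(spec, 0.25 * lib.pure["3"], atol=1e-14)

    def test_least_squares_unmixing_recovers_concentrations(self, stocks, true_params,
                                                            noise_free):
        """Independent linear-solve oracle on a noiseless 3-species slug."""
        rec = run_experiment(_setpoint(), stocks, true_params, noise_free, seed=0)
        lib = make_spectrum_library(seed=99)
        batch = generate_spectra(rec, lib, seed=1, stocks=stocks,
                                 baseline_amp=0.0, noise_sd=0.0)
        in_window = (batch.timestamps >= rec.slug_detect_time) & \
                    (batch.timestamps <= rec.slug_detect_time + stocks.slug_window_s)
        S = np.column_stack([lib.pure[a] for a in ("1", "2", "3")])
        conc, *_ = np.linalg.lstsq(S, batch.absorbances[in_window][0], rcond=None)
        expected = [rec.measured[a] for a in ("1", "2", "3")]
        np.testing.assert_allclose(conc, expected, atol=1e-10)

    def test_grid_mismatch_rejected(self, stocks, true_params, noise_free):
        rec = run_experiment(_setpoint(), stocks, true_params, noise_free, seed=0)
        lib = make_spectrum_library(seed=99)
        bad = {k: v[:-1] for k, v in lib.pure.items()}
        from slugflow.synthetic_reactor import SpectrumLibrary

        with pytest.raises(ValueError):
            SpectrumLibrary(wavenumbers=lib.wavenumbers, pure=bad)
        lib2 = make_spectrum_library(seed=99, analytes=("1", "2"))
        with pytest.raises(ValueError, match="'3'"):
            generate_spectra(rec, lib2, seed=1, stocks=stocks)


class TestMaterialUsage:
    def test_empty_log_all_zero(self, stocks):
        usage = material_usage([], stocks)
        assert (usage["volume_ul"] == 0).all()
        assert (usage["moles"] == 0).all()

    def test_single_slug_sums_to_slug_volume(self, stocks, true_params, noise):
        rec = run_experiment(_setpoint(), stocks, true_params, noise, seed=1)
        usage = material_usage([rec], stocks)
        assert usage["volume_ul"].sum() == pytest.approx(stocks.slug_volume_ul)

    def test_totals_additive_over_records(self, stocks, true_params, noise):
        recs = [run_experiment(_setpoint(), stocks, true_params, noise, seed=s,
                               record_id=f"r{s}") for s in range(3)]
        usage = material_usage(recs, stocks)
        single = material_usage(recs[:1], stocks)
        np.testing.assert_allclose(usage["volume_ul"], 3 * single["volume_ul"])


def test_record_frame_round_trip(stocks, true_params, noise):
    recs = [run_experiment(_setpoint(temp=100.0 + 10 * i), stocks, true_params,
                           noise, seed=i, record_id=f"r{i}") for i in range(4)]
    df = records_to_frame(recs)
    back = records_from_frame(df)
    for a, b in zip(recs, back):
        assert a.id == b.id
        assert a.setpoint == b.setpoint
        assert a.measured == pytest.approx(b.measured)
        assert a.objectives.as_tuple() == pytest.approx(b.objectives.as_tuple())
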