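"""Synthetic generators: starvation kinetics, wells, plating, cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vitacyt import (
    CohortSpec,
    GateConfig,
    StarvationScenario,
    calibrated_ecoli_scenario,
    cfu_per_ml,
    gate_run,
    derive_eub338_threshold,
    living_rate,
    simulate_cohort,
    simulate_dilution_series,
    simulate_plating,
    simulate_stained_well,
    simulate_starvation,
    select_dilution,
    microbial_load,
)
from vitacyt.io import gate_wells
from vitacyt.quantify import quantify_series


class TestStarvation:
    def test_initial_conditions(self):
        s = StarvationScenario(initial_total=1e9, initial_viable_fraction=0.7)
        t0 = simulate_starvation(s).iloc[0]
        assert t0.total == pytest.approx(1e9)
        assert t0.viable / t0.total == pytest.approx(0.7)
        assert t0.lysed == pytest.approx(0.0)

    def test_zero_rates_everything_constant(self):
        s = StarvationScenario(death_rate=0.0, lysis_rate=0.0)
        tr = simulate_starvation(s)
        assert tr.total.nunique() == 1
        assert (tr.atp == 0).all()

    def test_mass_conservation(self):
        s = calibrated_ecoli_scenario()
        tr = simulate_starvation(s)
        balance = tr.viable + tr.dead + tr.lysed
        assert np.allclose(balance, s.initial_total, rtol=1e-9)

    def test_calibrated_endpoints_match_printed_values(self):
        """Default E. coli scenario: 9.3 -> 8.9 total, 9.3 -> 7.9 viable,
        9.0 -> 7.6 CFU over 168 h (log10 cells/mL)."""
        tr = simulate_starvation(calibrated_ecoli_scenario())
        t0 = tr[tr.time_h == 0].iloc[0]
        end = tr[tr.time_h == 168].iloc[0]
        assert np.log10(t0.total) == pytest.approx(9.3, abs=1e-9)
        assert np.log10(end.total) == pytest.approx(8.9, abs=1e-9)
        assert np.log10(end.viable) == pytest.approx(7.9, abs=1e-9)
        assert np.log10(t0.cfu) == pytest.approx(9.0, abs=1e-9)
        assert np.log10(end.cfu) == pytest.approx(7.6, abs=1e-9)

    def test_atp_rises_monotonically(self):
        tr = simulate_starvation(calibrated_ecoli_scenario())
        assert (np.diff(tr.atp) > 0).all()

    def test_negative_timepoint_rejected(self):
        with pytest.raises(ValueError):
            StarvationScenario(timepoints=(-1.0, 0.0))


class TestStainedWell:
    def test_zero_acquisition_empty_table(self):
        well = simulate_stained_well(1e9, 0.5, 100, acquisition_fraction=0.0, seed=1)
        assert len(well) == 0

    def test_truth_labels_present(self):
        well = simulate_stained_well(1e9, 0.5, 100, acquisition_fraction=1e-3, seed=2)
        assert well.has_truth
        assert set(well.events.truth_label) <= {"bead", "live_cell", "dead_cell", "debris"}

    def test_concentration_recovered_within_tolerance(self):
        """Gated pipeline estimate of the true concentration within 0.05 log10."""
        cfg = GateConfig()
        conc = 10 ** 8.9
        ctrl = simulate_stained_well(conc, 0.999, 10, acquisition_fraction=0.005,
                                     seed=31, control_probe=True)
        thr = derive_eub338_threshold(ctrl, cfg)
        well = simulate_stained_well(conc, 0.9, 10, acquisition_fraction=0.1, seed=32)
        run = gate_run(well, thr, cfg, dilution_factor=10)
        est = microbial_load(run)
        assert abs(np.log10(est) - np.log10(conc)) <= 0.05

    def test_living_rate_recovered(self):
        cfg = GateConfig()
        ctrl = simulate_stained_well(1e9, 0.999, 10, acquisition_fraction=0.005,
                                     seed=33, control_probe=True)
        thr = derive_eub338_threshold(ctrl, cfg)
        well = simulate_stained_well(1e9, 0.68, 10, acquisition_fraction=0.01, seed=34)
        run = gate_run(well, thr, cfg, dilution_factor=10)
        assert living_rate(run.eub338_count, run.sytobc_count) == pytest.approx(
            0.68, abs=0.02)

    def test_determinism(self):
        a = simulate_stained_well(1e9, 0.5, 100, acquisition_fraction=1e-3, seed=9)
        b = simulate_stained_well(1e9, 0.5, 100, acquisition_fraction=1e-3, seed=9)
        pd.testing.assert_frame_equal(a.events, b.events)

    def test_oversized_acquisition_rejected(self):
        with pytest.raises(ValueError, match="acquisition too large"):
            simulate_stained_well(1e12, 0.5, 1, acquisition_fraction=1.0, seed=0)


class TestDilutionSeries:
    def test_default_fecal_series_selects_a_dilution(self):
        """At a typical fecal load (~10^10.9 cells/g) the standard
        400/2000/10000 series leaves at least one run in the bead window."""
        cfg = GateConfig()
        conc = 10 ** 10.9
        wells = simulate_dilution_series(conc, seed=41)
        ctrl = simulate_stained_well(conc, 0.999, 2000, acquisition_fraction=5e-3,
                                     seed=42, control_probe=True)
        series = gate_wells(wells, ctrl, cfg)
        picked = select_dilution(series)
        assert 200 <= picked.bead_count <= 1500
        res = quantify_series(series)
        assert abs(np.log10(res.microbial_load) - 10.9) <= 0.05

    def test_extreme_dilutions_fail_window(self):
        cfg = GateConfig()
        wells = simulate_dilution_series(10 ** 8.9, dilutions=(4e4, 2e5), seed=43)
        ctrl = simulate_stained_well(10 ** 8.9, 0.999, 10, acquisition_fraction=5e-3,
                                     seed=44, control_probe=True)
        series = gate_wells(wells, ctrl, cfg)
        with pytest.raises(ValueError, match="no valid dilution"):
            select_dilution(series)

    def test_determinism(self):
        a = simulate_dilution_series(1e9, dilutions=(10.0, 50.0), seed=5)
        b = simulate_dilution_series(1e9, dilutions=(10.0, 50.0), seed=5)
        for (da, ta), (db, tb) in zip(a, b):
            assert da == db
            pd.testing.assert_frame_equal(ta.events, tb.events)


class TestPlating:
    def test_zero_concentration_zero_colonies(self):
        plates = simulate_plating(0.0, replicates=5, seed=1)
        assert (plates.colonies == 0).all()

    def test_poisson_mean_recovered(self):
        """100 replicates at ~100 colonies/plate: mean CFU within 3 SE."""
        conc = 2.4e8
        dil = conc * 0.050 / 100.0   # -> mean 100 colonies
        plates = simulate_plating(conc, dilutions=(dil,), replicates=100, seed=2)
        est = np.array([cfu_per_ml(c, 0.050, dil) for c in plates.colonies])
        se = conc / np.sqrt(100 * 100)
        assert abs(est.mean() - conc) <= 3 * se

    def test_countable_flag(self):
        plates = simulate_plating(1e4, dilutions=(1.0, 1e4), replicates=3, seed=3)
        hi = plates[plates.dilution == 1.0]
        lo = plates[plates.dilution == 1e4]
        assert not hi.countable.any()     # ~500 colonies
        assert not lo.countable.any()     # ~0 colonies

    def test_determinism(self):
        a = simulate_plating(1e6, replicates=10, seed=7)
        b = simulate_plating(1e6, replicates=10, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestCohort:
    def test_determinism_bitwise(self):
        a = simulate_cohort(CohortSpec(n_subjects=20, seed=13))
        b = simulate_cohort(CohortSpec(n_subjects=20, seed=13))
        pd.testing.assert_frame_equal(a.cohort, b.cohort)
        pd.testing.assert_frame_equal(a.pos_fraction.abundance,
                                      b.pos_fraction.abundance)

    def test_rate_tied_to_sorted_fractions(self, default_cohort):
        """Composition-implied living rate equals the drawn rate exactly."""
        truth = default_cohort.truth
        implied = (truth["bulk_composition"] * truth["per_subject_viability"]).sum(axis=1)
        drawn = default_cohort.cohort.living_rate / 100.0
        assert np.allclose(implied, drawn, atol=1e-12)

    def test_fraction_frequencies_complementary(self, default_cohort):
        total = (default_cohort.pos_fraction.fraction_frequency
                 + default_cohort.neg_fraction.fraction_frequency)
        assert np.allclose(total, 1.0)

    def test_copula_hits_target_spearman(self):
        """n=5000: achieved rank correlation within +-0.05 of target."""
        spec = CohortSpec(n_subjects=5000, seed=17)
        res = simulate_cohort(spec)
        for marker, (target, _, _) in spec.marker_spec.items():
            got = sps.spearmanr(res.cohort.living_rate, res.cohort[marker]).statistic
            assert got == pytest.approx(target, abs=0.05)

    def test_uniform_viability_centres_ei_on_zero(self):
        """With one shared viability and rates at 50% the two sorted fractions
        have identical expected composition and frequency, so EI centres on 0."""
        taxa = {t: (w, 0.5) for t, (w, _) in CohortSpec().taxa.items()}
        res = simulate_cohort(CohortSpec(n_subjects=40, taxa=taxa, seed=19,
                                         rate_mean=50.0, rate_sd=2.0))
        from vitacyt import ei_table
        et = ei_table(res.pos_fraction, res.neg_fraction)
        assert abs(et.ei.to_numpy().mean()) < 0.02

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(rate_mean=120.0)
        with pytest.raises(ValueError):
            CohortSpec(taxa={"A": (1.0, 1.5)})
        with pytest.raises(ValueError):
            CohortSpec(marker_spec={"m": (-2.0, 1.0, 0.3)})
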