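"""Synthetic acquisition generator: designs, determinism, ground truth."""

import numpy as np
import pytest

from eicoquant.errors import SchedulingError, UnknownAnalyteError
from eicoquant.method_library import RtTable
from eicoquant.mzml_io import write_mzml
from eicoquant.signal_extraction import detect_peak, extract_channel
from eicoquant.synthetic import (
    PeakModel,
    RunRecipe,
    campaign_manifest,
    make_calibration_design,
    make_is_levels,
    make_qc_design,
    simulate_run,
    simulate_validation_campaign,
)


class TestDesignConstants:
    def test_calibration_levels_are_the_printed_series(self):
        levels = make_calibration_design()
        assert levels == [2.3, 4.6, 9.2, 18.5, 37.0, 74.0, 148.1, 222.2, 333.3, 500.0]
        assert len(levels) == 10
        assert (min(levels), max(levels)) == (2.3, 500.0)
        assert levels == sorted(levels)

    def test_qc_levels(self):
        assert make_qc_design() == {"LQC": 0.15, "MQC": 1.5, "HQC": 5.0}

    def test_is_levels(self):
        assert make_is_levels() == {"LQC": 18.5, "MQC": 148.1, "HQC": 500.0}


class TestPeakModel:
    def test_zero_asymmetry_is_symmetric_gaussian(self):
        pm = PeakModel(apex_rt_min=5.0, sigma_min=0.05, true_area=100.0)
        t = np.linspace(4.5, 5.5, 2001)
        y = pm.profile(t)
        assert np.allclose(y, y[::-1], atol=1e-9)
        assert np.trapezoid(y, t) == pytest.approx(100.0, rel=1e-6)

    def test_tailed_profile_still_integrates_to_area(self):
        pm = PeakModel(apex_rt_min=5.0, sigma_min=0.05, true_area=100.0, asymmetry=1.5)
        t = np.linspace(4.0, 7.0, 20001)
        assert np.trapezoid(pm.profile(t), t) == pytest.approx(100.0, rel=1e-4)
        # exponential tailing skews to later times
        y = pm.profile(t)
        apex_t = t[np.argmax(y)]
        mean_t = np.trapezoid(t * y, t) / np.trapezoid(y, t)
        assert mean_t > apex_t

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PeakModel(5.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            PeakModel(5.0, 0.05, -1.0)


class TestSimulateRun:
    def _recipe(self, **kw):
        base = dict(
            run_id="r",
            sample_kind="qc",
            level_label="x",
            analyte_concentrations={"PGE2": 5.0},
            is_concentrations={"PGE2-d4": 148.1},
            seed=11,
        )
        base.update(kw)
        return RunRecipe(**base)

    def test_blank_recipe_gives_zero_traces(self, library, rt_table, by_id):
        rec = self._recipe(
            sample_kind="blank",
            analyte_concentrations={"PGE2": 0.0},
            is_concentrations={},
            noise_sd=0.0,
        )
        run, truth = simulate_run(rec, library, rt_table)
        chrom = extract_channel(run, by_id["PGE2"])
        assert len(chrom) > 0
        assert np.all(chrom.intensities == 0.0)
        assert truth.per_transition["PGE2"].true_area == 0.0

    def test_noiseless_area_recovered_within_half_percent(self, library, rt_table, by_id):
        rec = self._recipe()
        run, truth = simulate_run(rec, library, rt_table)
        chrom = extract_channel(run, by_id["PGE2"])
        peak = detect_peak(chrom, rt_table.rt_for("PGE2") + truth.rt_shift_min)
        expected = truth.per_transition["PGE2"].expected_area_after_factors
        assert peak.found
        assert peak.area == pytest.approx(expected, rel=0.005)

    def test_same_seed_identical_output(self, library, rt_table):
        rec = self._recipe(noise_sd=4.0, baseline_level=20.0, area_cv=0.05)
        run1, truth1 = simulate_run(rec, library, rt_table)
        run2, truth2 = simulate_run(rec, library, rt_table)
        assert truth1 == truth2
        assert len(run1) == len(run2)
        for a, b in zip(run1.scans, run2.scans):
            assert a.rt_min == b.rt_min
            assert np.array_equal(a.mz, b.mz)
            assert np.array_equal(a.intensity, b.intensity)

    def test_same_seed_identical_mzml_bytes(self, library, rt_table, tmp_path):
        rec = self._recipe(noise_sd=4.0, baseline_level=20.0)
        for name in ("a", "b"):
            run, _ = simulate_run(rec, library, rt_table)
            write_mzml(run, tmp_path / f"{name}.mzML")
        assert (tmp_path / "a.mzML").read_bytes() == (tmp_path / "b.mzML").read_bytes()

    def test_unknown_analyte_and_missing_rt_raise(self, library, rt_table):
        with pytest.raises(UnknownAnalyteError):
            simulate_run(
                self._recipe(analyte_concentrations={"nope": 1.0}), library, rt_table
            )
        gappy = RtTable(ph_label="5.8", entries={"PGE2": None, "PGE2-d4": 5.2})
        with pytest.raises(SchedulingError):
            simulate_run(self._recipe(), library, gappy)

    def test_co_isolated_isomers_share_scan_content(self, library, rt_table, by_id):
        rec = self._recipe(
            analyte_concentrations={"PGE2": 5.0, "PGD2": 5.0}, is_concentrations={}
        )
        run, truth = simulate_run(rec, library, rt_table)
        chrom = extract_channel(run, by_id["PGE2"])
        shift = truth.rt_shift_min
        # both isomer peaks appear in the shared channel
        for analyte in ("PGE2", "PGD2"):
            peak = detect_peak(chrom, rt_table.rt_for(analyte) + shift)
            assert peak.found
            assert peak.apex_rt_min == pytest.approx(
                rt_table.rt_for(analyte) + shift, abs=0.02
            )


class TestFactorBookkeeping:
    @pytest.mark.parametrize(
        "kind,matrix,expect_rec,expect_mat",
        [
            ("matrix_pre_spike", "plasma", 0.8, 0.9),
            ("matrix_post_spike", "plasma", 1.0, 0.9),
            ("neat_standard", "none", 1.0, 1.0),
            ("qc", "none", 1.0, 1.0),
        ],
    )
    def test_factors_applied_by_sample_kind(
        self, library, rt_table, kind, matrix, expect_rec, expect_mat
    ):
        rec = RunRecipe(
            run_id="f",
            sample_kind=kind,
            level_label="HQC",
            is_concentrations={"PGE2-d4": 500.0},
            matrix=matrix,
            recovery_factor=0.8,
            matrix_factor=0.9,
            seed=3,
        )
        _, truth = simulate_run(rec, library, rt_table)
        tt = truth.per_transition["PGE2-d4"]
        assert truth.recovery_factor == expect_rec
        assert truth.matrix_factor == expect_mat
        assert tt.true_area == 500.0 * rec.response_factor
        assert tt.expected_area_after_factors == pytest.approx(
            tt.true_area * expect_rec * expect_mat
        )

    def test_campaign_truth_equals_brute_force_factor_product(self, library, rt_table):
        recipes = simulate_validation_campaign(
            library,
            rt_table,
            analytes=("PGE2",),
            n_calibration_replicates=1,
            n_qc_replicates=1,
            days=1,
            n_recovery_replicates=2,
            matrices=("plasma",),
            seed=5,
        )
        for rec in recipes:
            _, truth = simulate_run(rec, library, rt_table)
            for tt in truth.per_transition.values():
                factors = 1.0
                if rec.sample_kind == "matrix_pre_spike":
                    factors *= rec.recovery_factor
                if rec.sample_kind in {"matrix_pre_spike", "matrix_post_spike"}:
                    factors *= rec.matrix_factor
                assert tt.expected_area_after_factors == pytest.approx(
                    tt.true_area * factors
                )


class TestCampaignDesign:
    def test_counts_match_the_study_design(self, library, rt_table):
        recipes = simulate_validation_campaign(library, rt_table, seed=1)
        manifest = campaign_manifest(recipes)
        counts = manifest["sample_kind"].value_counts()
        assert counts["calibration"] == 10 * 5
        assert counts["qc"] == 3 * 5 * 3  # 3 levels x 5 replicates x 3 days
        # recovery design per matrix: 3 levels x 6 replicates x 2 conditions
        # (neat solvent standards carry matrix="none" but belong to the block)
        plasma = manifest[manifest["run_id"].str.startswith("rec_plasma")]
        pre_plus_neat = plasma[
            plasma["sample_kind"].isin(["matrix_pre_spike", "neat_standard"])
        ]
        assert len(pre_plus_neat) == 3 * 6 * 2
        assert len(plasma) == 3 * 6 * 3  # plus the post-extraction spikes

    def test_days_flag_controls_qc_block(self, library, rt_table):
        recipes = simulate_validation_campaign(
            library, rt_table, days=1, n_qc_replicates=2, seed=1
        )
        qc = [r for r in recipes if r.sample_kind == "qc"]
        assert {r.day for r in qc} == {1}
        assert len(qc) == 3 * 2

    def test_manifest_deterministic_for_fixed_seed(self, library, rt_table):
        m1 = campaign_manifest(simulate_validation_campaign(library, rt_table, seed=9))
        m2 = campaign_manifest(simulate_validation_campaign(library, rt_table, seed=9))
        assert m1.equals(m2)

    def test_replicate_floor(self, library, rt_table):
        with pytest.raises(ValueError):
            simulate_validation_campaign(library, rt_table, n_recovery_replicates=1, seed=1)
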