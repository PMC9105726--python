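"""Sweep drivers: aggregation semantics, cross-sweep consistency,
determinism, and the CLI surface."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from megsim.cli import main as cli_main
from megsim.experiments import (
    aggregate_subjects,
    build_subjects,
    component_matched_rms_ratios,
    run_baseline_rms,
    run_depth_sweep,
    run_noise_grid,
    run_sensor_count_sweep,
    run_spontaneous_sweep,
    run_ambient_sweep,
)

SMALL_CFG = {
    "head": {"n_subjects": 2, "subdivision": 3},
    "source_space": {"n_candidates": 400},
    "simulation": {"n_samples": 6},
    "fit": {"n_coarse": 100},
}


@pytest.fixture(scope="module")
def subjects():
    return build_subjects(5, SMALL_CFG)


class TestAggregateSubjects:
    def test_duplicated_subject_has_zero_sd(self):
        row = {
            "configuration": "OPM-NOR",
            "sigma_fT": 75.0,
            "rms_signal": 1.0,
            "rms_noise": 0.5,
            "snr_db": 6.0,
            "re": 0.1,
            "cc": 0.99,
            "d_sf": 0.002,
        }
        per = pd.DataFrame([{**row, "subject": f"S{i}"} for i in range(8)])
        agg = aggregate_subjects(per, ["sigma_fT"])
        assert agg["d_sf_std"].iloc[0] == pytest.approx(0.0, abs=1e-15)
        assert agg["d_sf_mean"].iloc[0] == pytest.approx(0.002)

    def test_mean_equals_recomputation_from_flat_table(self, subjects):
        res = run_baseline_rms(subjects, configurations=("OPM-NOR", "OPM-TAN-LAT"))
        flat = res.per_subject
        direct = flat.groupby("configuration")["rms_signal"].mean()
        agg = res.aggregate.set_index("configuration")["rms_signal_mean"]
        for conf in direct.index:
            assert agg[conf] == pytest.approx(direct[conf], rel=1e-12)

    def test_mismatched_grids_rejected(self):
        per = pd.DataFrame(
            [
                {"configuration": "A", "subject": "S1", "sigma_fT": 0.0},
                {"configuration": "A", "subject": "S2", "sigma_fT": 75.0},
            ]
        )
        for col in ["rms_signal", "rms_noise", "snr_db", "re", "cc", "d_sf"]:
            per[col] = 1.0
        with pytest.raises(ValueError):
            aggregate_subjects(per, ["sigma_fT"])


class TestBaseline:
    def test_normal_component_has_highest_rms(self, subjects):
        res = run_baseline_rms(subjects)
        agg = res.aggregate.set_index("configuration")["rms_signal_mean"]
        assert agg["OPM-NOR"] > agg["OPM-TAN-LAT"]
        assert agg["OPM-NOR"] > agg["OPM-TAN-LON"]
        assert agg["SQUID-NOR"] > agg["SQUID-TAN-LAT"]

    def test_opm_exceeds_matched_squid(self, subjects):
        res = run_baseline_rms(subjects)
        ratios = component_matched_rms_ratios(res)
        assert all(v > 1.0 for v in ratios.values())

    def test_zero_source_strength_zeroes_everything(self, subjects):
        res = run_baseline_rms(subjects, configurations=("OPM-NOR",), q=0.0)
        assert (res.per_subject["rms_signal"] == 0).all()


class TestSweepConsistency:
    def test_shared_zero_noise_point_identical_across_sweeps(self, subjects):
        amb = run_ambient_sweep(
            subjects, sigma_grid_fT=(0.0, 150.0), configurations=("OPM-NOR",)
        )
        spo = run_spontaneous_sweep(
            subjects, q_spont_grid_nAm=(0.0, 2.0), configurations=("OPM-NOR",)
        )
        a = amb.per_subject.query("sigma_fT == 0").sort_values("subject")
        s = spo.per_subject.query("q_spont_nAm == 0").sort_values("subject")
        assert np.array_equal(a["d_sf"].to_numpy(), s["d_sf"].to_numpy())
        assert np.array_equal(a["rms_signal"].to_numpy(), s["rms_signal"].to_numpy())

    def test_sweep_is_deterministic(self, subjects):
        kw = dict(sigma_grid_fT=(75.0,), configurations=("OPM-TAN-LAT",))
        a = run_ambient_sweep(subjects, **kw).per_subject
        b = run_ambient_sweep(build_subjects(5, SMALL_CFG), **kw).per_subject
        pd.testing.assert_frame_equal(a, b)

    def test_noise_grid_covers_full_product(self, subjects):
        res = run_noise_grid(
            subjects,
            sigma_grid_fT=(0.0, 150.0),
            q_spont_grid_nAm=(0.0, 3.0),
            configurations=("OPM-ALL",),
            n_samples=4,
        )
        agg = res.aggregate
        assert len(agg) == 4  # 2 x 2 grid
        corner = agg.query("sigma_fT == 0 and q_spont_nAm == 0")["d_sf_mean"].iloc[0]
        worst = agg.query("sigma_fT == 150 and q_spont_nAm == 3")["d_sf_mean"].iloc[0]
        assert corner < 1e-3 < worst

    def test_snr_at_zero_noise_is_nan_not_infinite(self, subjects):
        amb = run_ambient_sweep(subjects, sigma_grid_fT=(0.0,), configurations=("OPM-NOR",))
        assert amb.per_subject["snr_db"].isna().all()


class TestSensorCountSweep:
    def test_site_arithmetic_and_full_array_at_zero(self, subjects):
        res = run_sensor_count_sweep(
            subjects,
            fractions_removed=(0.0, 0.5),
            configurations=("OPM-ALL",),
            cases=((75e-15, 0.0),),
        )
        per = res.per_subject
        for s in subjects:
            full = per.query("subject == @s.head.subject_id and fraction_removed == 0")
            half = per.query("subject == @s.head.subject_id and fraction_removed == 0.5")
            n = s.array("OPM-ALL").n_sites
            assert int(full["n_sites"].iloc[0]) == n
            assert int(half["n_sites"].iloc[0]) == round(0.5 * n)
            assert int(half["n_channels"].iloc[0]) == 3 * round(0.5 * n)

    def test_zero_fraction_matches_ambient_sweep_point(self, subjects):
        res = run_sensor_count_sweep(
            subjects,
            fractions_removed=(0.0,),
            configurations=("OPM-NOR",),
            cases=((75e-15, 0.0),),
        )
        amb = run_ambient_sweep(
            subjects, sigma_grid_fT=(75.0,), configurations=("OPM-NOR",)
        )
        a = res.per_subject.sort_values("subject")["d_sf"].to_numpy()
        b = amb.per_subject.sort_values("subject")["d_sf"].to_numpy()
        assert np.array_equal(a, b)


class TestDepthSweep:
    def test_rms_decreases_with_depth(self, subjects):
        res = run_depth_sweep(
            subjects,
            depth_grid_cm=(1.5, 3.0, 4.5),
            configurations=("OPM-NOR", "SQUID-NOR"),
            cases=((75e-15, 0.0),),
            n_samples=8,
            deep_space_candidates=600,
            do_fit=False,
        )
        agg = res.aggregate
        for conf in ("OPM-NOR", "SQUID-NOR"):
            r = agg.query("configuration == @conf").sort_values("h_cm")["rms_signal_mean"]
            assert list(r) == sorted(r, reverse=True)

    def test_unreachable_depth_bins_skipped_and_reported(self, subjects):
        res = run_depth_sweep(
            subjects,
            depth_grid_cm=(2.0, 7.5),  # 7.5 cm is deeper than the head allows
            configurations=("OPM-NOR",),
            cases=((75e-15, 0.0),),
            n_samples=4,
            deep_space_candidates=400,
            do_fit=False,
        )
        assert res.provenance["skipped_bins"]
        assert set(res.per_subject["h_cm"]) == {2.0}


class TestCli:
    def test_make_head_and_baseline_sweep(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "head: {n_subjects: 2, subdivision: 2}\n"
            "source_space: {n_candidates: 150}\n"
            "simulation: {n_samples: 4}\n"
            "fit: {n_coarse: 50}\n"
        )
        out = tmp_path / "run"
        args = ["--config", str(cfg), "--seed", "3", "--out", str(out)]
        r1 = runner.invoke(cli_main, args + ["make-head"])
        assert r1.exit_code == 0, r1.output
        assert (out / "S01" / "scalp.off").exists()
        assert (out / "S01" / "source_space.csv").exists()
        assert (out / "manifest.json").exists()
        r2 = runner.invoke(cli_main, args + ["sweep", "baseline"])
        assert r2.exit_code == 0, r2.output
        table = pd.read_csv(out / "baseline_aggregate.csv")
        assert "rms_signal_mean" in table.columns
        assert len(table) == 8  # 4 OPM + 4 SQUID configurations
        r3 = runner.invoke(cli_main, args + ["report"])
        assert r3.exit_code == 0
        assert "baseline_aggregate" in r3.output

    def test_array_export(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "head: {n_subjects: 1, subdivision: 2}\nsource_space: {n_candidates: 100}\n"
        )
        out = tmp_path / "arr"
        r = runner.invoke(
            cli_main,
            ["--config", str(cfg), "--seed", "1", "--out", str(out), "make-arrays",
             "--configurations", "OPM-NOR"],
        )
        assert r.exit_code == 0, r.output
        frame = pd.read_csv(out / "S01" / "array_OPM-NOR.csv")
        assert {"label", "kind", "weight", "x", "y", "z"} <= set(frame.columns)
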