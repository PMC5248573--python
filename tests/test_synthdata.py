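"""Tests for the synthetic generators: determinism, planted structure, limits."""

import numpy as np
import pandas as pd
import pytest

from celladapt import exprfilter as ef
from celladapt import pharm
from celladapt import screenpath as sp
from celladapt import synthdata as sd
from celladapt import tracekit as tk


class TestPresets:
    def test_builtin_presets_validate(self):
        for kind in ("fate", "plate", "expression", "screen", "biopsy", "growth"):
            for name in sd.preset_names(kind):
                sd.get_preset(kind, name)  # constructors validate invariants

    def test_unknown_preset_raises(self):
        with pytest.raises(KeyError):
            sd.get_preset("fate", "nope")
        with pytest.raises(KeyError):
            sd.get_preset("nokind", "colo858_vem")

    def test_invalid_probability_vector_rejected(self, colo858_vem_params):
        with pytest.raises(ValueError):
            colo858_vem_params.replace(p_death=0.9)

    def test_death_window_must_fit_movie(self, colo858_vem_params):
        with pytest.raises(ValueError):
            colo858_vem_params.replace(movie_length_h=40.0)


class TestFateCohort:
    def test_seed_reproducibility_bit_identical(self, colo858_vem_params):
        a = sd.simulate_fate_cohort(colo858_vem_params, 50, seed=9)
        b = sd.simulate_fate_cohort(colo858_vem_params, 50, seed=9)
        assert a.labels == b.labels
        for ta, tb in zip(a.traces, b.traces):
            np.testing.assert_array_equal(ta.geminin, tb.geminin)
            np.testing.assert_array_equal(ta.alive, tb.alive)

    def test_label_counts_near_mixture(self, colo858_cohort):
        counts = colo858_cohort.label_counts()
        n = 300
        for fate, p in (("dead", 0.6), ("arrested", 0.2), ("adapted", 0.2)):
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(counts[fate] - n * p) <= 3 * sigma

    def test_frequencies_converge_at_large_n(self, colo858_vem_params):
        cohort = sd.simulate_fate_cohort(colo858_vem_params, 10_000, seed=13)
        counts = cohort.label_counts()
        for fate, p in (("dead", 0.6), ("arrested", 0.2), ("adapted", 0.2)):
            sigma = np.sqrt(10_000 * p * (1 - p))
            assert abs(counts[fate] - 10_000 * p) <= 3 * sigma

    def test_pure_death_mixture(self, colo858_vem_params):
        params = colo858_vem_params.replace(p_death=1.0, p_arrest=0.0, p_adapt=0.0)
        cohort = sd.simulate_fate_cohort(params, 40, seed=2)
        for tr, sched in zip(cohort.traces, cohort.schedules):
            assert sched.fate == "dead"
            assert sched.death_h is not None
            assert sched.division_times_h == []
            assert not tr.alive[-1]

    def test_death_times_inside_window(self, colo858_cohort):
        lo, hi = colo858_cohort.params.death_window_h
        for sched in colo858_cohort.schedules:
            if sched.death_h is not None:
                assert lo <= sched.death_h <= hi

    def test_uniform_death_switch(self, colo858_vem_params):
        params = colo858_vem_params.replace(
            death_time_dist="uniform", p_death=1.0, p_arrest=0.0, p_adapt=0.0
        )
        cohort = sd.simulate_fate_cohort(params, 200, seed=3)
        deaths = np.array([s.death_h for s in cohort.schedules])
        lo, hi = params.death_window_h
        assert deaths.min() >= lo and deaths.max() <= hi
        # roughly uniform: mean near midpoint within 4 SE
        se = (hi - lo) / np.sqrt(12 * len(deaths))
        assert abs(deaths.mean() - (lo + hi) / 2) < 4 * se

    def test_fixed_schedule_is_analytic(self, colo858_vem_params):
        # degenerate draws: re-entry ~ U(48, 48+eps), cv=0 -> first division
        # at re-entry + s_g2, second at +65 h
        params = colo858_vem_params.replace(
            noise_sd=0.0,
            p_death=0.0,
            p_arrest=0.0,
            p_adapt=1.0,
            reentry_window_h=(48.0, 48.0 + 1e-6),
            intermitotic_cv=0.0,
            movie_length_h=150.0,
        )
        cohort = sd.simulate_fate_cohort(params, 3, seed=1)
        for tr, sched in zip(cohort.traces, cohort.schedules):
            np.testing.assert_allclose(sched.division_times_h, [58.0, 123.0], atol=0.1)
            ev = tk.detect_events(tr)
            np.testing.assert_allclose(ev.divisions, sched.division_times_h, atol=1e-9)

    def test_noiseless_trace_reconstructible_from_schedule(self, colo858_vem_params):
        params = colo858_vem_params.replace(noise_sd=0.0)
        cohort = sd.simulate_fate_cohort(params, 30, seed=8)
        for tr, sched in zip(cohort.traces, cohort.schedules):
            # rebuild the waveform from the schedule alone (oracle equality)
            g = np.zeros_like(tr.times)
            s_g2 = params.s_g2_duration_h
            for d in sched.division_times_h:
                mask = (tr.times >= d - s_g2) & (tr.times < d)
                g[mask] = sd.GEMININ_AMPLITUDE * (tr.times[mask] - (d - s_g2)) / s_g2
            if sched.fate == "adapted":
                nxt = (
                    sched.division_times_h[-1]
                    if sched.division_times_h
                    else sched.reentry_h + s_g2
                )
                # censored partial rise toward the next (unobserved) division
                last = sched.division_times_h[-1] if sched.division_times_h else 0.0
                mask = tr.times >= max(last, 0.0)
                partial = tr.geminin[mask]
                g_partial = g[mask]
                # only compare frames where the rebuilt waveform is defined
                defined = g_partial > 0
                np.testing.assert_allclose(
                    partial[defined], g_partial[defined], atol=1e-9
                )
            if sched.death_h is not None:
                assert not tr.alive[tr.times >= sched.death_h].any()


class TestUntreatedCohort:
    def test_mean_intermitotic_near_24h(self, dmso_cohort):
        gaps = []
        for sched in dmso_cohort.schedules:
            gaps.extend(np.diff(sched.division_times_h))
        assert np.mean(gaps) == pytest.approx(24.0, abs=1.0)

    def test_short_movie_censors_without_error(self, colo858_dmso_params):
        params = colo858_dmso_params.replace(movie_length_h=12.0, death_window_h=(1, 10), reentry_window_h=(1, 10))
        cohort = sd.simulate_untreated_cohort(params, 100, seed=4)
        zero_div = sum(1 for s in cohort.schedules if not s.division_times_h)
        assert zero_div > 20  # substantial fraction with no division

    def test_no_deaths(self, dmso_cohort):
        for tr in dmso_cohort.traces:
            assert tr.alive.all()

    def test_determinism(self, colo858_dmso_params):
        a = sd.simulate_untreated_cohort(colo858_dmso_params, 20, seed=5)
        b = sd.simulate_untreated_cohort(colo858_dmso_params, 20, seed=5)
        for ta, tb in zip(a.traces, b.traces):
            np.testing.assert_array_equal(ta.geminin, tb.geminin)


class TestEndpointPlate:
    def test_zero_dose_matches_control_growth(self):
        preset = sd.get_preset("plate", "colo858_dr")
        plate = sd.simulate_endpoint_plate(preset, seed=1)
        ctrl = plate[plate.dose_um == 0]["viable_count"].mean()
        expected = preset.initial_count * 2**preset.control_doublings
        assert ctrl == pytest.approx(expected, rel=0.1)

    def test_negative_dose_rejected(self):
        preset = sd.get_preset("plate", "colo858_dr")
        with pytest.raises(ValueError):
            sd.simulate_endpoint_plate(preset, pretreat_dose=-1.0, seed=1)

    def test_mmacsf_monotone_in_total_dose(self):
        # no adaptation term: expected viability falls monotonically with
        # total dose (checked noise-free)
        base = sd.get_preset("plate", "mmacsf_seq").to_dict()
        base["replicate_cv"] = 0.0
        preset = sd.PlatePreset(**base)
        plate = sd.simulate_sequential_plate(preset, second_dose_um=1.0, seed=2)
        means = plate.groupby("pretreat_dose_um")["viable_count"].mean()
        assert (np.diff(means.to_numpy()) <= 0).all()

    def test_colo858_protection_peaks_near_2p5_fold(self):
        preset = sd.get_preset("plate", "colo858_seq")
        plate = sd.simulate_sequential_plate(preset, second_dose_um=1.0, seed=4)
        summ = pharm.sequential_dosing_summary(plate)
        peak = summ.loc[summ["fold_change_mean"].idxmax()]
        assert peak["pretreat_dose_um"] == pytest.approx(0.1)
        assert peak["fold_change_mean"] == pytest.approx(2.5, abs=0.35)

    def test_per_cell_records_attached(self):
        preset = sd.get_preset("plate", "colo858_dr")
        plate = sd.simulate_endpoint_plate(preset, seed=3)
        cells = plate.attrs["cells"]
        assert {"spot_intensity", "nucleus_area", "true_apoptotic"} <= set(cells.columns)


class TestExpressionTable:
    def test_planted_and_only_planted_pass_filter_at_zero_dispersion(self):
        preset = sd.ExpressionPreset(
            n_genes=500,
            n_planted_up=25,
            n_planted_down=25,
            planted_log2ratio=2.0,
            fpkm_floor=1.0,
            q_signal=0.001,
            q_null=0.5,
            dispersion=0.0,
        )
        table = sd.simulate_expression_table(preset, seed=6)
        sel = ef.select_differential_genes(table)
        planted = set(table.attrs["planted_up"]) | set(table.attrs["planted_down"])
        assert set(sel.all_selected()) == planted
        for t in sel.up:
            assert set(sel.up[t]) == set(table.attrs["planted_up"])
            assert set(sel.down[t]) == set(table.attrs["planted_down"])

    def test_null_table_selects_nothing(self):
        preset = sd.ExpressionPreset(
            n_genes=300, n_planted_up=0, n_planted_down=0, planted_log2ratio=2.0,
            fpkm_floor=1.0, q_signal=0.001, q_null=0.5, dispersion=0.01,
        )
        table = sd.simulate_expression_table(preset, seed=7)
        sel = ef.select_differential_genes(table)
        assert sel.all_selected() == []

    def test_ngfr_like_gene_ratio(self):
        # up 15-fold in line A while down 4-fold in line B: ratio = 60
        rows = []
        for line, fc, q in (("A", 15.0, 0.001), ("B", 0.25, 0.001)):
            rows.append(("NGFR", line, "DMSO", 100.0, 1.0))
            rows.append(("NGFR", line, "drug48h", 100.0 * fc, q))
        table = pd.DataFrame(rows, columns=["gene", "line", "condition", "fpkm", "q"])
        sel = ef.select_differential_genes(table, stabilize=False)
        assert sel.up["drug48h"] == ["NGFR"]
        ratio = np.log2(15.0 / 0.25)
        assert ratio == pytest.approx(np.log2(60))

    def test_fpkm_non_negative(self):
        preset = sd.get_preset("expression", "default")
        table = sd.simulate_expression_table(preset, seed=8)
        assert (table["fpkm"] >= 0).all()


class TestScreen:
    def test_noiseless_hits_exactly_planted(self):
        preset = sd.ScreenPreset(suppressor_ids=[3, 11, 38], noise_sd=0.0)
        plate = sd.simulate_screen(preset, seed=1)
        hits = sp.screen_hits(plate, k_lowest=5)
        assert hits.hits == plate.attrs["planted_suppressors"]

    def test_default_preset_recovers_planted(self):
        preset = sd.get_preset("screen", "default")
        plate = sd.simulate_screen(preset, seed=6)
        hits = sp.screen_hits(plate, k_lowest=5)
        assert hits.hits == plate.attrs["planted_suppressors"]

    def test_null_suppression_matches_permutation_oracle(self):
        # with no planted effect, hits arise only from random rank
        # intersections; compare the simulated mean hit count with a
        # brute-force Monte Carlo of independent random rankings
        preset = sd.ScreenPreset(suppressor_ids=[], suppression_log2=0.0, noise_sd=0.2)
        n_plates = 200
        sim_counts = []
        for s in range(n_plates):
            plate = sd.simulate_screen(preset, seed=s)
            sim_counts.append(len(sp.screen_hits(plate, k_lowest=5).hits))

        rng = np.random.default_rng(999)
        mc_counts = []
        for _ in range(2000):
            sets = [
                set(rng.permutation(preset.n_compounds)[:5])
                for _ in range(preset.n_lines)
            ]
            mc_counts.append(len(set.intersection(*sets)))
        sim_mean, mc_mean = np.mean(sim_counts), np.mean(mc_counts)
        se = np.std(mc_counts) / np.sqrt(len(mc_counts)) + np.std(sim_counts) / np.sqrt(
            n_plates
        )
        assert abs(sim_mean - mc_mean) < 4 * se + 0.05

    def test_replicate_structure(self):
        preset = sd.get_preset("screen", "default")
        plate = sd.simulate_screen(preset, seed=2)
        sizes = plate.groupby(["compound", "dose_um", "line"]).size()
        assert (sizes == preset.n_replicates).all()


class TestBiopsy:
    def test_gate_recovers_planted_fraction(self):
        preset = sd.get_preset("biopsy", "on_treatment")
        table = sd.simulate_biopsy_table(preset, seed=5)
        kept, _ = sp.exclude_background(table, table.attrs["background_threshold"])
        res = sp.gate_high(kept, markers=("ngfr_log",), method="otsu")
        assert res.fractions_high["ngfr_log"] == pytest.approx(0.30, abs=0.03)

    def test_zero_high_fraction(self):
        preset = sd.BiopsyPreset(
            n_cells=5000,
            frac_marker_high={"ngfr": 0.0, "ki67": 0.5},
            high_low_separation=2.5,
            background_frac=0.0,
            background_boost=3.0,
        )
        table = sd.simulate_biopsy_table(preset, seed=1)
        # fixed threshold at the planted component boundary: false-positive
        # rate of the unimodal low component only
        thr = preset.low_mean_log + preset.high_low_separation / 2
        res = sp.gate_high(
            table, markers=("ngfr_log",), method="fixed",
            fixed_thresholds={"ngfr_log": thr},
        )
        assert res.fractions_high["ngfr_log"] < 0.01

    def test_background_exclusion_restores_planted_fraction(self):
        preset = sd.BiopsyPreset(
            n_cells=10000,
            frac_marker_high={"ngfr": 0.30, "ki67": 0.40},
            high_low_separation=2.5,
            background_frac=0.10,
            background_boost=4.0,
        )
        table = sd.simulate_biopsy_table(preset, seed=9)
        thr = preset.low_mean_log + preset.high_low_separation / 2
        gate_kw = dict(
            markers=("ngfr_log",), method="fixed", fixed_thresholds={"ngfr_log": thr}
        )
        with_bg = sp.gate_high(table, **gate_kw).fractions_high["ngfr_log"]
        kept, n_excl = sp.exclude_background(table, table.attrs["background_threshold"])
        without_bg = sp.gate_high(kept, **gate_kw).fractions_high["ngfr_log"]
        assert with_bg > 0.33  # inflated by boosted background cells
        assert without_bg == pytest.approx(0.30, abs=0.02)
        assert n_excl == pytest.approx(0.10 * preset.n_cells, rel=0.15)

    def test_determinism(self):
        preset = sd.get_preset("biopsy", "on_treatment")
        a = sd.simulate_biopsy_table(preset, seed=3)
        b = sd.simulate_biopsy_table(preset, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestGrowthTrajectories:
    def test_noiseless_exponential(self):
        preset = sd.GrowthPreset(doubling_h=24.0, initial_count=100, n_replicates=1, replicate_cv=0.0)
        df = sd.simulate_growth_trajectories(preset, duration_h=72.0, interval_h=24.0, seed=1)
        counts = df["count"].to_numpy()
        np.testing.assert_allclose(counts, [100, 200, 400, 800])


class TestDiskIO:
    def test_cohort_roundtrip_with_sidecar(self, tmp_path, colo858_cohort):
        path = tmp_path / "cohort.csv"
        sd.write_cohort(colo858_cohort, path, with_truth=True)
        assert path.exists()
        assert (tmp_path / "cohort.csv.json").exists()
        assert (tmp_path / "cohort_truth.csv").exists()
        back = tk.read_trace_csv(path)
        assert len(back) == len(colo858_cohort.traces)

    def test_table_sidecar(self, tmp_path):
        preset = sd.get_preset("plate", "colo858_dr")
        plate = sd.simulate_endpoint_plate(preset, seed=3)
        path = tmp_path / "plate.csv"
        sd.write_table(plate, path)
        assert path.exists()
        assert (tmp_path / "plate.csv.json").exists()
        assert (tmp_path / "plate_cells.csv").exists()
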