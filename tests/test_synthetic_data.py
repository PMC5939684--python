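import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirlag.synthetic_data import (
    SimulationConfig,
    simulate_annotation,
    simulate_expression,
    simulate_prediction_table,
    simulate_qpcr,
)


class TestConfigValidation:
    def test_fraction_sum_above_one_rejected(self):
        with pytest.raises(ValueError, match="sum <= 1"):
            SimulationConfig(frac_groupA=0.6, frac_groupB=0.5)

    @pytest.mark.parametrize("kwargs", [{"n_mirna": 0}, {"n_replicates": -1}, {"noise_sd": -0.1}])
    def test_nonpositive_dimensions_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_duplicate_timepoints_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            SimulationConfig(timepoints=("P13", "P13", "P17"))


class TestSimulateExpression:
    def test_shapes_and_sample_encoding(self, small_config, small_sim):
        n_samples = 2 * 3 * small_config.n_replicates
        assert small_sim.mirna.values.shape == (small_config.n_mirna, n_samples)
        assert small_sim.mrna.values.shape == (small_config.n_mrna, n_samples)
        assert "rd10_P15_2" in small_sim.mirna.sample_ids
        assert small_sim.mirna_calls.matches(small_sim.mirna)

    def test_seed_determinism_byte_identical(self, small_config):
        a = simulate_expression(small_config)
        b = simulate_expression(small_config)
        assert a.mirna.values.to_csv() == b.mirna.values.to_csv()
        assert a.mrna.values.to_csv() == b.mrna.values.to_csv()
        pd.testing.assert_frame_equal(a.truth.de_mirnas, b.truth.de_mirnas)

    def test_different_seed_differs(self, small_config):
        a = simulate_expression(small_config)
        b = simulate_expression(dataclasses.replace(small_config, seed=small_config.seed + 1))
        assert a.mirna.values.to_csv() != b.mirna.values.to_csv()

    def test_zero_fractions_mean_no_planted_de(self):
        cfg = SimulationConfig(n_mirna=30, n_mrna=30, frac_groupA=0.0, frac_groupB=0.0, seed=3)
        sim = simulate_expression(cfg)
        assert len(sim.truth.de_mirnas) == 0
        assert len(sim.truth.true_targets) == 0
        # non-DE features share true means across genotypes
        tl = sim.truth.true_log2_mirna
        pd.testing.assert_frame_equal(
            tl[[f"rd10_{t}" for t in cfg.timepoints]].set_axis(cfg.timepoints, axis=1),
            tl[[f"WT_{t}" for t in cfg.timepoints]].set_axis(cfg.timepoints, axis=1),
        )

    def test_temporal_templates(self, small_sim):
        de = small_sim.truth.de_mirnas
        a, b = de[de["group"] == "A"], de[de["group"] == "B"]
        assert (a["lr_P15"] != 0).all() and (a["lr_P17"] != 0).all() and (a["lr_P13"] == 0).all()
        assert (b["lr_P17"] != 0).all() and (b["lr_P15"] == 0).all() and (b["lr_P13"] == 0).all()

    def test_targets_oppose_their_regulator(self, small_sim):
        truth = small_sim.truth
        de_dir = truth.de_mirnas["direction"]
        for m, g, tp, gdir in truth.true_targets.itertuples(index=False):
            assert gdir == -de_dir[m]
            case_shift = truth.true_log2_mrna.loc[g, f"rd10_{tp}"] - truth.true_log2_mrna.loc[g, f"WT_{tp}"]
            assert np.sign(case_shift) == gdir

    def test_delayed_response_timepoint(self, small_sim):
        # group-A regulators are active from P15 but their targets shift at P17 only
        truth = small_sim.truth
        a_ids = set(truth.de_mirnas.index[truth.de_mirnas["group"] == "A"])
        a_targets = truth.true_targets[truth.true_targets["mirna_id"].isin(a_ids)]
        assert (a_targets["response_timepoint"] == "P17").all()
        for g in a_targets["gene_id"]:
            assert truth.true_log2_mrna.loc[g, "rd10_P15"] == truth.true_log2_mrna.loc[g, "WT_P15"]

    def test_background_detection_rate_within_binomial_bounds(self):
        cfg = SimulationConfig(
            n_mirna=300, n_mrna=200, frac_background=0.5,
            frac_groupA=0.02, frac_groupB=0.02, targets_per_mirna=1, seed=11,
        )
        sim = simulate_expression(cfg)
        bg = sorted(sim.truth.background_mirnas)
        calls = sim.mirna_calls.calls.loc[bg].to_numpy()
        n_trials = calls.size
        # present iff above the 0.95 background quantile -> Binomial(n, 0.05)
        lo, hi = stats.binom.ppf([0.005, 0.995], n_trials, 0.05)
        assert lo <= calls.sum() <= hi

    def test_planted_effect_detectable_by_t_test(self):
        # a planted group-A miRNA at P15 rejects a Welch test at alpha=0.05
        # in >=80% of 200 seeded repetitions (measured oracle: ~0.97)
        hits = 0
        for seed in range(200):
            cfg = SimulationConfig(
                n_mirna=1, n_mrna=4, frac_groupA=1.0, frac_groupB=0.0,
                targets_per_mirna=1, frac_background=0.0, seed=seed,
            )
            sim = simulate_expression(cfg)
            case = np.log2(sim.mirna.values[["rd10_P15_1", "rd10_P15_2", "rd10_P15_3"]].to_numpy()[0])
            ctrl = np.log2(sim.mirna.values[["WT_P15_1", "WT_P15_2", "WT_P15_3"]].to_numpy()[0])
            hits += stats.ttest_ind(case, ctrl, equal_var=False).pvalue < 0.05
        assert hits / 200 >= 0.80


class TestSimulatePredictionTable:
    def test_zero_rate_gives_exactly_true_pairs(self, small_config, small_sim):
        cfg = dataclasses.replace(small_config, false_prediction_rate=0.0)
        table = simulate_prediction_table(cfg, small_sim.truth)
        got = set(zip(table.table["mirna_id"], table.table["gene_id"]))
        truth = small_sim.truth.true_targets
        assert got == set(zip(truth["mirna_id"], truth["gene_id"]))

    def test_true_pairs_always_have_two_plus_algorithms(self, small_config, small_sim):
        table = simulate_prediction_table(small_config, small_sim.truth)
        truth_pairs = set(zip(small_sim.truth.true_targets["mirna_id"], small_sim.truth.true_targets["gene_id"]))
        for m, g, algos in table.table.itertuples(index=False):
            if (m, g) in truth_pairs:
                assert len(algos) >= 2

    def test_spurious_count_within_binomial_bounds(self):
        cfg = SimulationConfig(
            n_mirna=10, n_mrna=100, frac_groupA=0.1, frac_groupB=0.1,
            targets_per_mirna=2, frac_background=0.0, false_prediction_rate=0.001, seed=5,
        )
        sim = simulate_expression(cfg)
        table = simulate_prediction_table(cfg, sim.truth)
        n_true = len(sim.truth.true_targets)
        n_spurious = len(table) - n_true
        lo, hi = stats.binom.ppf([0.005, 0.995], 10 * 100 - n_true, 0.001)
        assert lo <= n_spurious <= hi

    def test_deterministic_under_seed(self, small_config, small_sim):
        t1 = simulate_prediction_table(small_config, small_sim.truth)
        t2 = simulate_prediction_table(small_config, small_sim.truth)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_id_space_mismatch_rejected(self, small_config, small_sim):
        cfg = dataclasses.replace(small_config, n_mirna=small_config.n_mirna + 1)
        with pytest.raises(ValueError, match="id space"):
            simulate_prediction_table(cfg, small_sim.truth)


class TestSimulateAnnotation:
    def test_planted_terms_recorded_and_sized(self, small_config, small_sim):
        ann = simulate_annotation(small_config, small_sim.truth)
        assert len(ann) == small_config.n_planted_terms + small_config.n_decoy_terms
        assert set(small_sim.truth.planted_terms) <= set(ann)
        for _, genes in ann.values():
            assert len(genes) == small_config.term_size


class TestSimulateQpcr:
    def test_noise_free_ddct_recovers_planted_ratio(self, small_config):
        cfg = dataclasses.replace(small_config, noise_sd=0.0, ct_tech_sd=0.0)
        sim = simulate_expression(cfg)
        truth = sim.truth
        fid = truth.de_mirnas.index[truth.de_mirnas["group"] == "B"][0]
        ct = simulate_qpcr(cfg, truth, [fid])
        planted = truth.de_mirnas.loc[fid, "lr_P17"]
        rd = ct.mean_ct(fid)[[f"rd10_P17_{r}" for r in (1, 2, 3)]].mean()
        wt = ct.mean_ct(fid)[[f"WT_P17_{r}" for r in (1, 2, 3)]].mean()
        # Ct difference equals minus the planted log2 ratio
        assert rd - wt == pytest.approx(-planted, abs=1e-12)

    def test_reference_features_have_zero_ct_sd_without_noise(self, small_config):
        cfg = dataclasses.replace(small_config, noise_sd=0.0, ct_tech_sd=0.0)
        sim = simulate_expression(cfg)
        ref = sorted(sim.truth.null_mirnas())[0]
        ct = simulate_qpcr(cfg, sim.truth, [ref])
        assert ct.mean_ct(ref).std(ddof=1) == pytest.approx(0.0, abs=1e-12)

    def test_unknown_feature_rejected(self, small_config, small_sim):
        with pytest.raises(KeyError, match="unknown feature"):
            simulate_qpcr(small_config, small_sim.truth, ["nope"])

    def test_triplicate_technical_replicates(self, small_config, small_sim):
        fid = small_sim.truth.de_mirnas.index[0]
        ct = simulate_qpcr(small_config, small_sim.truth, [fid])
        counts = ct.table.groupby("sample_id")["tech_rep"].count()
        assert (counts == 3).all()
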