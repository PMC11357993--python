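import numpy as np
import pandas as pd
import pytest

from engram import (
    AgonistChannel,
    CountTable,
    ProgrammeFeatureMatrix,
    ReadModel,
    SimConfig,
    classify_programmes,
    condition_grid,
    differential_activity,
    enumerate_programmes,
    fit_dose_response,
    order_recovery_experiment,
    pca_embed,
    programme_feature_matrix,
    simulate_dose_response,
)
from engram.analysis import FitError, _four_pl
from engram.tape import feature_names


class TestDoseResponseFit:
    def test_noiseless_logistic_recovered_exactly(self):
        doses = np.array([0.0] + [0.05 * 2**i for i in range(12)])
        y = _four_pl(doses, 0.01, 0.6, 2.0, 1.5)
        fit = fit_dose_response(doses, y)
        assert fit.ec50 == pytest.approx(2.0, rel=1e-4)
        assert fit.hill_n == pytest.approx(1.5, rel=1e-3)
        assert fit.floor == pytest.approx(0.01, abs=1e-6)
        assert fit.ceiling == pytest.approx(0.6, rel=1e-4)

    def test_flat_response_raises(self):
        doses = [0, 1, 2, 4, 8, 16]
        with pytest.raises(FitError):
            fit_dose_response(doses, [0.3] * 6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response([1, 2, 4], [0.1, 0.2, 0.3])

    @pytest.mark.parametrize("ec50,top_dose", [(0.17, 8.0), (2.5, 64.0), (2.2, 32.0)])
    def test_ec50_recovery_from_simulation(self, ec50, top_dose):
        """Simulating a dilution series from each reported half-maximal
        concentration recovers it within 20% at 5,000 cells."""
        ch = AgonistChannel("X", "X", ec50=ec50, hill_n=1.5,
                            basal_rate=7.5e-4, max_rate=1.5e-2)
        doses = [0.0] + [top_dose / 2**i for i in range(10)]
        df = simulate_dose_response(
            ch, doses, 2.0, SimConfig(n_cells=5000, tapes_per_cell=20, seed=23))
        fit = fit_dose_response(df["dose"], df["edited_fraction"])
        assert abs(fit.ec50 - ec50) / ec50 < 0.2


class TestOrderRecovery:
    def test_symmetric_exposure_gives_small_ratio(self, tape_spec,
                                                  tape_channels, small_config,
                                                  read_model):
        from engram import SignalProgramme

        sym = SignalProgramme(
            "sym", 4.0,
            segments={"TET": ((0.0, 4.0, 0.1),), "WNT": ((0.0, 4.0, 1.25),)},
            pattern="serial", first_channel="TET")
        # concentrations chosen so both channels run at comparable rates
        df = order_recovery_experiment(
            tape_channels, tape_spec, small_config, seeds=[1, 2, 3],
            read_model=read_model, programmes=[sym])
        assert abs(df["replicate_mean_ratio"].iloc[0]) < 1.0

    def test_basal_free_serial_programmes_sign_correct(self, tape_spec,
                                                       small_config, read_model):
        channels = [
            AgonistChannel("TET", "TET", ec50=0.17, hill_n=1.5, basal_rate=0.0,
                           max_rate=0.5),
            AgonistChannel("WNT", "WNT", ec50=2.2, hill_n=2.0, basal_rate=0.0,
                           max_rate=0.5),
        ]
        progs = [p for p in enumerate_programmes(intervals_days=[2])
                 if p.pattern == "serial"]
        df = order_recovery_experiment(channels, tape_spec, small_config,
                                       seeds=[4], read_model=read_model,
                                       programmes=progs)
        assert df["sign_correct"].all()
        assert (df["bigram_log_ratio"] > 0).all()

    def test_requires_two_channels(self, tape_spec, small_config):
        only = [AgonistChannel("TET", "TET", ec50=1, hill_n=1, max_rate=0.5)]
        with pytest.raises(ValueError):
            order_recovery_experiment(only, tape_spec, small_config, seeds=[1])


def toy_matrix(n_labels=4, n_reps=3, n_feats=6, separation=5.0, seed=0):
    rng = np.random.default_rng(seed)
    centres = rng.normal(0, separation, size=(n_labels, n_feats))
    rows, labels, reps = [], [], []
    for i in range(n_labels):
        for r in range(n_reps):
            rows.append(centres[i] + rng.normal(0, 0.1, n_feats))
            labels.append(f"prog{i}")
            reps.append(r)
    return ProgrammeFeatureMatrix(
        values=np.vstack(rows), labels=labels, replicate_ids=reps,
        feature_names=[f"f{j}" for j in range(n_feats)])


class TestPca:
    def test_rank_one_matrix_explained_by_first_component(self):
        u = np.linspace(0, 1, 12)[:, None]
        v = np.arange(1, 6)[None, :]
        m = ProgrammeFeatureMatrix(
            values=u @ v, labels=[f"p{i}" for i in range(12)],
            replicate_ids=list(range(12)),
            feature_names=[f"f{j}" for j in range(5)])
        _, evr = pca_embed(m, n_components=3, scale=False)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_two_cluster_design_separates_on_leading_pcs(self):
        m = toy_matrix(n_labels=2, n_reps=6, separation=8.0, seed=1)
        scores, _ = pca_embed(m, n_components=2)
        labels = np.array(m.labels)
        gap = abs(scores[labels == "prog0", 0].mean()
                  - scores[labels == "prog1", 0].mean())
        spread = scores[:, 0].std()
        assert gap > spread

    def test_explained_variance_non_increasing(self):
        m = toy_matrix(n_labels=5, n_reps=4, n_feats=10, seed=2)
        _, evr = pca_embed(m, n_components=3)
        assert (np.diff(evr) <= 1e-12).all()

    def test_constant_columns_dropped_with_warning(self):
        m = toy_matrix(seed=3)
        m.values[:, 2] = 7.0
        with pytest.warns(UserWarning):
            scores, _ = pca_embed(m, n_components=2)
        assert scores.shape == (len(m.labels), 2)


class TestClassifier:
    def test_separable_features_classified_perfectly(self):
        acc, confusion = classify_programmes(toy_matrix(separation=10.0), seed=1)
        assert acc == 1.0
        assert (np.diag(confusion.values) == 3).all()

    def test_label_permutation_drops_to_chance(self):
        """Shuffled labels leave only chance accuracy (~1/15 for 15
        programmes), within binomial noise."""
        m = toy_matrix(n_labels=15, n_reps=3, n_feats=26, separation=6.0, seed=4)
        rng = np.random.default_rng(5)
        accs = []
        for seed in range(3):
            perm = rng.permutation(len(m.labels))
            shuffled = ProgrammeFeatureMatrix(
                values=m.values, labels=[m.labels[i] for i in perm],
                replicate_ids=m.replicate_ids, feature_names=m.feature_names)
            acc, _ = classify_programmes(shuffled, seed=seed)
            accs.append(acc)
        n_total = len(m.labels) * len(accs)
        chance = 1 / 15
        se = np.sqrt(chance * (1 - chance) / n_total)
        assert abs(np.mean(accs) - chance) < 4 * se + 1e-9

    def test_single_replicate_rejected(self):
        m = toy_matrix(n_reps=1)
        with pytest.raises(ValueError):
            classify_programmes(m)

    def test_end_to_end_simulated_programmes_above_chance(self, tape_spec,
                                                          tape_channels):
        """Small-scale simulation of all 15 programmes in triplicate is
        classified well above the 1/15 chance level."""
        progs = enumerate_programmes()
        cfg = SimConfig(n_cells=150, tapes_per_cell=20)
        m = programme_feature_matrix(
            progs, tape_channels, tape_spec, cfg,
            ReadModel(reads_per_sample=1500), seeds=[1, 2, 3])
        assert m.values.shape == (45, 26)
        assert m.feature_names == feature_names(tape_spec)
        acc, _ = classify_programmes(m, seed=2)
        assert acc > 3 / 15


class TestDifferentialActivity:
    @staticmethod
    def tables(props, n=20000, reps=3, seed=0):
        rng = np.random.default_rng(seed)
        syms = list(props)
        p = np.array([props[s] for s in syms], dtype=float)
        p = p / p.sum()
        out = []
        for _ in range(reps):
            counts = rng.multinomial(n, p)
            out.append(CountTable(counts=dict(zip(syms, map(int, counts)))))
        return out

    def test_identical_conditions_make_no_calls(self):
        props = {"A": 0.3, "B": 0.3, "C": 0.4}
        res = differential_activity(self.tables(props, seed=1),
                                    self.tables(props, seed=2))
        assert not res["called"].any()
        assert res["log2_fold_change"].abs().max() < 0.2

    def test_fourfold_symbol_called_with_expected_lfc(self):
        a = self.tables({"A": 0.4, "B": 0.3, "C": 0.3}, seed=3)
        b = self.tables({"A": 0.1, "B": 0.45, "C": 0.45}, seed=4)
        res = differential_activity(a, b).set_index("symbol")
        assert res.loc["A", "called"]
        assert res.loc["A", "log2_fold_change"] == pytest.approx(2.0, abs=0.3)

    def test_bh_adjustment_never_below_raw_p(self):
        a = self.tables({"A": 0.5, "B": 0.25, "C": 0.25}, seed=5)
        b = self.tables({"A": 0.2, "B": 0.4, "C": 0.4}, seed=6)
        res = differential_activity(a, b)
        assert (res["adjusted_p"] >= res["p_value"] - 1e-15).all()

    def test_symbol_absent_in_one_condition_excluded(self):
        a = self.tables({"A": 0.5, "B": 0.5}, seed=7)
        b = self.tables({"A": 0.5, "B": 0.5}, seed=8)
        for t in b:
            t.counts["B"] = 0
        with pytest.warns(UserWarning):
            res = differential_activity(a, b)
        assert "B" not in set(res["symbol"])

    def test_replicate_minimum_enforced(self):
        t = self.tables({"A": 1.0}, reps=1, seed=9)
        with pytest.raises(ValueError):
            differential_activity(t, t)


class TestConditionGrid:
    def test_three_agonists_three_levels_triplicate_is_81(self):
        grid = condition_grid(
            {"TET": [0.1, 0.5, 2.0], "NFKB": [1, 10, 64], "WNT": [1, 3, 30]},
            n_replicates=3)
        assert len(grid) == 81

    def test_presence_absence_design_is_24(self):
        grid = condition_grid(
            {"TET": [0.0, 0.5], "NFKB": [0.0, 10.0], "WNT": [0.0, 3.0]},
            n_replicates=3)
        assert len(grid) == 24

    def test_rows_unique_per_replicate(self):
        grid = condition_grid({"A": [0, 1], "B": [0, 1]}, n_replicates=2)
        assert len(grid.drop_duplicates()) == len(grid) == 8
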