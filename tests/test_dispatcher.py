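import numpy as np
import pandas as pd
import pytest

from pyrabeat.dispatcher import (
    NSDispatcher,
    apply_rules,
    estimate_normal_prerr,
    threshold_grid,
)
from pyrabeat.synthetic import two_cluster_beat_table


class TestRules:
    def test_regular_beat_is_normal(self):
        # both rule values are exactly 0, which is not < t
        assert apply_rules(0.8, 0.8, 0.8, t=-0.05) == "N"

    def test_rule1_catches_premature_beat_before_pause(self):
        # (0.4 - 0.8) / 0.8 = -0.5 < -0.3
        assert apply_rules(0.4, 0.8, 0.8, t=-0.3) == "S"

    def test_rule2_catches_successive_short_beats(self):
        # rule 1: (0.5 - 0.5)/0.8 = 0; rule 2: (0.5 - 0.8)/0.8 = -0.375 < -0.3
        assert apply_rules(0.5, 0.5, 0.8, t=-0.3) == "S"

    def test_vectorized_matches_scalar(self):
        pre = np.array([0.8, 0.4, 0.5])
        post = np.array([0.8, 0.8, 0.5])
        out = apply_rules(pre, post, 0.8, t=-0.3)
        assert list(out) == ["N", "S", "S"]

    def test_nonpositive_normal_prerr_rejected(self):
        with pytest.raises(ValueError):
            apply_rules(0.8, 0.8, 0.0, t=-0.1)

    def test_s_set_shrinks_as_t_decreases(self, rng):
        """Monotonicity: strict-< rules label fewer beats S at more negative t."""
        pre = rng.uniform(0.3, 1.2, 300)
        post = rng.uniform(0.3, 1.2, 300)
        prev_s = None
        for t in threshold_grid():  # ordered least to most negative
            s_set = set(np.flatnonzero(apply_rules(pre, post, 0.8, t) == "S"))
            if prev_s is not None:
                assert s_set <= prev_s
            prev_s = s_set


class TestNormalPreRREstimator:
    def test_no_outliers_takes_median(self):
        assert estimate_normal_prerr(np.full(50, 0.8)) == pytest.approx(0.8)

    def test_heavy_contamination_blends_outlier_mean_and_median(self):
        # IQR = 0 makes the 0.4s beats outliers; 15% > 10% threshold
        x = np.array([0.8] * 85 + [0.4] * 15)
        assert estimate_normal_prerr(x) == pytest.approx(0.6)

    def test_light_contamination_keeps_median(self):
        x = np.array([0.8] * 97 + [0.4] * 3)
        assert estimate_normal_prerr(x) == pytest.approx(0.8)

    def test_exactly_ten_percent_takes_median_branch(self):
        x = np.array([0.8] * 90 + [0.4] * 10)
        assert estimate_normal_prerr(x) == pytest.approx(0.8)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_normal_prerr(np.array([]))


def _patient_frame(pre, post, labels, pid):
    return (
        pd.DataFrame({"preRR": pre, "postRR": post}),
        np.asarray(labels, dtype=object),
        np.full(len(pre), pid, dtype=object),
    )


class TestThresholdTraining:
    def test_grid_matches_exhaustive_oracle_with_tiebreak(self):
        """Exhaustive oracle: all t in {-0.05..-0.45} are perfect; ties
        resolve to the least negative, -0.05."""
        pre = [0.8] * 20 + [0.4] * 5
        post = [0.8] * 25
        X, y, pids = _patient_frame(pre, post, ["N"] * 20 + ["S"] * 5, "p1")
        model = NSDispatcher().fit(X, y, patients=pids)

        # independent oracle: brute-force every grid threshold
        def sens(cls, true, pred):
            m = true == cls
            return np.mean(pred[m] == cls)

        best = max(
            threshold_grid(),
            key=lambda t: (
                sens("N", y, apply_rules(np.array(pre), np.array(post), 0.8, t))
                + sens("S", y, apply_rules(np.array(pre), np.array(post), 0.8, t)),
                t,
            ),
        )
        assert model.thresholds_["p1"] == pytest.approx(best)
        assert model.thresholds_["p1"] == pytest.approx(-0.05)

    def test_s_free_patient_gets_sentinel(self):
        X, y, pids = _patient_frame([0.8] * 10, [0.8] * 10, ["N"] * 10, "p1")
        model = NSDispatcher().fit(X, y, patients=pids)
        assert model.thresholds_["p1"] == 0.0

    def test_normal_prerr_is_median_of_n_beats(self):
        X, y, pids = _patient_frame(
            [0.7, 0.8, 0.9, 0.4], [0.8] * 4, ["N", "N", "N", "S"], "p1"
        )
        model = NSDispatcher().fit(X, y, patients=pids)
        assert model.normal_pre_rr_["p1"] == pytest.approx(0.8)

    def test_patient_without_n_beats_rejected(self):
        X, y, pids = _patient_frame([0.4] * 5, [0.8] * 5, ["S"] * 5, "p1")
        with pytest.raises(ValueError, match="no N beats"):
            NSDispatcher().fit(X, y, patients=pids)

    def test_trained_thresholds_within_grid(self):
        tbl = two_cluster_beat_table(300, 0.15, 0.6, rng=0)
        model = NSDispatcher().fit(
            tbl[["preRR", "postRR"]], tbl["label"],
            patients=np.full(len(tbl), "p"),
        )
        t = model.thresholds_["p"]
        assert -0.95 <= t <= 0.0

    def test_vfq_beats_ignored_in_training(self):
        pre = [0.8] * 20 + [0.4] * 5 + [0.2] * 5
        post = [0.8] * 30
        labels = ["N"] * 20 + ["S"] * 5 + ["V"] * 5
        X, y, pids = _patient_frame(pre, post, labels, "p1")
        m1 = NSDispatcher().fit(X, y, patients=pids)
        X2, y2, p2 = _patient_frame(pre[:25], post[:25], labels[:25], "p1")
        m2 = NSDispatcher().fit(X2, y2, patients=p2)
        assert m1.thresholds_ == m2.thresholds_


class TestNeighborLookup:
    def _fit_two_patients(self):
        t1 = two_cluster_beat_table(200, 0.1, 0.6, base_rr=0.8, rng=1)
        t2 = two_cluster_beat_table(200, 0.3, 0.6, base_rr=0.5, rng=2)
        X = pd.concat([t1, t2], ignore_index=True)
        pids = np.array(["a"] * len(t1) + ["b"] * len(t2), dtype=object)
        return NSDispatcher().fit(
            X[["preRR", "postRR"]], X["label"], patients=pids
        ), t1, t2

    def test_identical_distribution_is_own_neighbor(self):
        model, t1, _ = self._fit_two_patients()
        assert model.get_neighbor(t1["preRR"].to_numpy()) == "a"

    def test_similar_cluster_structure_wins(self):
        model, _, _ = self._fit_two_patients()
        probe = two_cluster_beat_table(200, 0.3, 0.6, base_rr=0.5, rng=3)
        assert model.get_neighbor(probe["preRR"].to_numpy()) == "b"

    def test_single_patient_table_always_wins(self):
        tbl = two_cluster_beat_table(200, 0.1, 0.6, rng=4)
        model = NSDispatcher().fit(
            tbl[["preRR", "postRR"]], tbl["label"],
            patients=np.full(len(tbl), "only"),
        )
        assert model.get_neighbor(np.random.default_rng(0).uniform(0.3, 1, 50)) == "only"


class TestLevel1Classification:
    def test_sentinel_neighbor_replaced_by_table_minimum(self):
        # patient 'a' is S-free (t=0); 'b' has S beats and a negative t
        ta = two_cluster_beat_table(200, 0.0, 0.6, base_rr=0.8, rng=5)
        tb = two_cluster_beat_table(200, 0.3, 0.6, base_rr=0.5, rng=6)
        X = pd.concat([ta, tb], ignore_index=True)
        pids = np.array(["a"] * len(ta) + ["b"] * len(tb), dtype=object)
        model = NSDispatcher().fit(X[["preRR", "postRR"]], X["label"], patients=pids)
        assert model.thresholds_["a"] == 0.0
        assert model.thresholds_["b"] < 0.0
        probe = two_cluster_beat_table(100, 0.0, 0.6, base_rr=0.8, rng=7)
        neighbor, t = model.threshold_for(probe["preRR"].to_numpy())
        assert neighbor == "a"
        assert t == model.thresholds_["b"]

    def test_all_sentinel_table_falls_back(self, caplog):
        tbl = two_cluster_beat_table(100, 0.0, 0.6, rng=8)
        model = NSDispatcher().fit(
            tbl[["preRR", "postRR"]], tbl["label"],
            patients=np.full(len(tbl), "p"),
        )
        with caplog.at_level("WARNING"):
            _, t = model.threshold_for(tbl["preRR"].to_numpy())
        assert t == model.fallback_t

    def test_regular_rhythm_all_normal(self):
        train = two_cluster_beat_table(200, 0.1, 0.6, rng=9)
        model = NSDispatcher().fit(
            train[["preRR", "postRR"]], train["label"],
            patients=np.full(len(train), "p"),
        )
        rng = np.random.default_rng(10)
        n = 100
        X = pd.DataFrame(
            {"preRR": rng.normal(0.8, 0.01, n), "postRR": rng.normal(0.8, 0.01, n)}
        )
        assert set(model.predict(X)) == {"N"}

    def test_depends_only_on_rhythm_columns(self):
        train = two_cluster_beat_table(200, 0.1, 0.6, rng=11)
        model = NSDispatcher().fit(
            train[["preRR", "postRR"]], train["label"],
            patients=np.full(len(train), "p"),
        )
        probe = two_cluster_beat_table(150, 0.1, 0.6, rng=12)
        base = model.predict(probe[["preRR", "postRR"]])
        again = model.predict(probe[["preRR", "postRR"]].copy())
        assert np.array_equal(base, again)

    def test_threshold_recovery_on_held_out_patients(self):
        """Separated two-cluster rhythm: perfect training objective and
        near-perfect held-out S sensitivity via EMD threshold transfer."""
        frames, pids = [], []
        for i in range(5):
            tbl = two_cluster_beat_table(220, 0.1, 0.6, rng=100 + i)
            frames.append(tbl)
            pids += [f"tr{i}"] * len(tbl)
        X = pd.concat(frames, ignore_index=True)
        model = NSDispatcher().fit(
            X[["preRR", "postRR"]], X["label"], patients=np.array(pids, dtype=object)
        )
        # training objective is perfect at the fitted threshold
        for i, tbl in enumerate(frames):
            t = model.thresholds_[f"tr{i}"]
            pred = apply_rules(
                tbl["preRR"].to_numpy(), tbl["postRR"].to_numpy(),
                model.normal_pre_rr_[f"tr{i}"], t,
            )
            true = tbl["label"].to_numpy()
            assert np.all(pred[true == "S"] == "S")
            assert np.all(pred[true == "N"] == "N")
        # held-out patients
        test = two_cluster_beat_table(220, 0.1, 0.6, rng=999)
        pred = model.predict(test[["preRR", "postRR"]])
        true = test["label"].to_numpy()
        assert np.mean(pred[true == "S"] == "S") >= 0.95


def test_threshold_table_json_roundtrip(tmp_path):
    tbl = two_cluster_beat_table(200, 0.1, 0.6, rng=13)
    model = NSDispatcher().fit(
        tbl[["preRR", "postRR"]], tbl["label"], patients=np.full(len(tbl), "p")
    )
    path = tmp_path / "thresholds.json"
    model.to_json(path)
    back = NSDispatcher.from_json(path)
    assert back.thresholds_ == model.thresholds_
    assert back.normal_pre_rr_ == model.normal_pre_rr_
    probe = two_cluster_beat_table(100, 0.1, 0.6, rng=14)
    assert np.array_equal(
        back.predict(probe[["preRR", "postRR"]]),
        model.predict(probe[["preRR", "postRR"]]),
    )
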