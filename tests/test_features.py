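import numpy as np
import pandas as pd
import pytest

from mtqsar.chemio import PairRecord
from mtqsar.errors import DegenerateInputError, EmptyClassError
from mtqsar.features import (
    ForwardStepwiseSelector,
    MovingAverageFeaturizer,
    TargetClassProfile,
    build_class_profiles,
    featurize_pair,
    forward_stepwise_select,
    get_profile,
)


def _profiles_fixture():
    records = [
        PairRecord("d1", "CCO", "1.1", 1),
        PairRecord("d2", "CCC", "1.1", 0),
        PairRecord("d3", "CCN", "2.7", 1),
    ]
    desc = pd.DataFrame({"wiener": [2.0, 4.0, 7.0], "randic": [1.0, 3.0, 5.0]})
    return records, desc


class TestClassProfiles:
    def test_arithmetic_means(self):
        records, desc = _profiles_fixture()
        profiles = build_class_profiles(records, desc)
        assert profiles["1.1"].means["wiener"] == 3.0
        assert profiles["1.1"].n_pairs == 2

    def test_singleton_class(self):
        records, desc = _profiles_fixture()
        profiles = build_class_profiles(records, desc)
        assert profiles["2.7"].means["randic"] == 5.0
        assert profiles["2.7"].n_pairs == 1

    def test_absent_class_raises(self):
        records, desc = _profiles_fixture()
        profiles = build_class_profiles(records, desc)
        with pytest.raises(EmptyClassError):
            get_profile(profiles, "9.9")

    def test_interacting_only_scope(self):
        records, desc = _profiles_fixture()
        profiles = build_class_profiles(records, desc, contributors="interacting")
        assert profiles["1.1"].means["wiener"] == 2.0  # only the label-1 record


class TestFeaturizePair:
    def test_centering_gives_zero_dmd(self):
        prof = TargetClassProfile("1.1", {"wiener": 3.0}, 2)
        fv = featurize_pair({"wiener": 3.0}, prof, ["wiener"])
        assert fv.values.tolist() == [3.0, 3.0, 0.0]

    def test_deviation(self):
        prof = TargetClassProfile("1.1", {"wiener": 3.0}, 2)
        fv = featurize_pair({"wiener": 5.0}, prof, ["wiener"])
        assert fv.values.tolist() == [5.0, 3.0, 2.0]

    def test_thirteen_descriptors_expand_to_39(self):
        names = [f"d{i}" for i in range(13)]
        prof = TargetClassProfile("1.1", {n: 0.0 for n in names}, 1)
        fv = featurize_pair({n: 1.0 for n in names}, prof, names)
        assert len(fv.values) == 39

    def test_missing_descriptor_raises(self):
        prof = TargetClassProfile("1.1", {"wiener": 3.0}, 2)
        with pytest.raises(KeyError):
            featurize_pair({"wiener": 3.0}, prof, ["randic"])


class TestMovingAverageFeaturizer:
    def _data(self, seed=0, n=120):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        X["ec_family"] = np.where(np.arange(n) % 2 == 0, "1.1", "2.7")
        return X

    def test_dmd_centered_on_training_rows(self):
        X = self._data()
        feat = MovingAverageFeaturizer().fit(X)
        out = feat.transform(X)
        for fam in ["1.1", "2.7"]:
            mask = (X["ec_family"] == fam).to_numpy()
            for col in ["a__dmd", "b__dmd", "c__dmd"]:
                assert abs(out.loc[mask, col].mean()) < 1e-12

    def test_reconstruction_is_lossless(self):
        X = self._data(seed=1)
        feat = MovingAverageFeaturizer().fit(X)
        out = feat.transform(X)
        for col in ["a", "b", "c"]:
            np.testing.assert_allclose(
                (out[f"{col}__mean"] + out[f"{col}__dmd"]).to_numpy(),
                out[col].to_numpy(),
                rtol=0, atol=1e-15,
            )

    def test_unseen_family_raises(self):
        X = self._data()
        feat = MovingAverageFeaturizer().fit(X)
        bad = X.head(2).copy()
        bad["ec_family"] = "9.9"
        with pytest.raises(EmptyClassError):
            feat.transform(bad)


def _planted(seed=0, n=400, n_noise=9, effect=2.0):
    """One informative feature + noise features; labels threshold the
    informative feature plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, n_noise + 1)),
        columns=["signal"] + [f"noise{i}" for i in range(n_noise)],
    )
    y = (effect * X["signal"].to_numpy() + rng.normal(size=n) > 0).astype(int)
    return X, y


def _single_feature_auc_scan(X, y):
    """Independent oracle: rank candidates by single-feature separation."""
    from scipy.stats import mannwhitneyu

    scores = {}
    for col in X.columns:
        u = mannwhitneyu(X.loc[y == 1, col], X.loc[y == 0, col]).statistic
        auc = u / ((y == 1).sum() * (y == 0).sum())
        scores[col] = abs(auc - 0.5)
    return max(scores, key=scores.get)


class TestForwardStepwise:
    def test_planted_feature_selected_first(self):
        X, y = _planted()
        assert _single_feature_auc_scan(X, y) == "signal"  # oracle sanity
        result = forward_stepwise_select(X, y, max_features=3)
        assert result.selected[0] == "signal"
        assert result.log[0] == {
            "step": 1, "action": "enter", "name": "signal",
            "p_value": result.log[0]["p_value"],
        }

    def test_max_features_zero(self):
        X, y = _planted()
        assert forward_stepwise_select(X, y, max_features=0).selected == []

    def test_never_exceeds_max_features(self):
        X, y = _planted(seed=3)
        result = forward_stepwise_select(X, y, max_features=2)
        assert len(result.selected) <= 2

    def test_all_constant_raises(self):
        X = pd.DataFrame({"a": np.ones(50), "b": np.zeros(50)})
        y = np.arange(50) % 2
        with pytest.raises(DegenerateInputError):
            forward_stepwise_select(X, y)

    def test_deterministic_replay(self):
        X, y = _planted(seed=5)
        r1 = forward_stepwise_select(X, y, max_features=4)
        r2 = forward_stepwise_select(X, y, max_features=4)
        assert r1.selected == r2.selected and r1.log == r2.log

    def test_removals_follow_entries(self):
        X, y = _planted(seed=8, n=250)
        sel = ForwardStepwiseSelector(max_features=5).fit(X, y)
        entered = set()
        for step in sel.log_:
            if step["action"] == "enter":
                entered.add(step["name"])
            else:
                assert step["name"] in entered

    def test_recovery_over_seeds(self):
        """With a strong planted effect the informative feature leads the
        selection in nearly every replicate."""
        hits = sum(
            forward_stepwise_select(*_planted(seed=s, n=300), max_features=3).selected[0]
            == "signal"
            for s in range(20)
        )
        assert hits >= 18
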