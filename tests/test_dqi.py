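"""Index builders: theoretical weights, group merging, ridge-weighted
indexes, and the 0-100 standardized scale."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from likingdqi import defaults
from likingdqi.cohort import CohortSpec, generate_cohort
from likingdqi.dqi import (DQIConfig, StandardizedScale, empirical_dqi,
                           hybrid_dqi, merge_correlated_groups,
                           merge_map_from_correlation, standardize_hybrid,
                           theoretical_dqi)
from likingdqi.errors import LikingDQIError, MissingGroupError
from likingdqi.validation import Dataset

GROUPS_12 = list(defaults.GROUP_ORDER)


def _groups_frame(values: dict[str, float]) -> pd.DataFrame:
    cols = {g: [0.0] for g in GROUPS_12}
    cols["low-fat protein"] = [0.0]
    cols.update({k: [v] for k, v in values.items()})
    return pd.DataFrame(cols, index=["s"])


class TestTheoretical:
    def test_zero_profile_scores_zero(self):
        assert theoretical_dqi(_groups_frame({})).scores.iloc[0] == 0.0

    def test_extreme_profile_attains_maximum_240(self):
        values = {}
        for g, w in defaults.THEORETICAL_WEIGHTS.items():
            values[g] = 100.0 if w > 0 else -100.0
        res = theoretical_dqi(_groups_frame(values))
        assert res.scores.iloc[0] == pytest.approx(240.0)

    def test_vegetable_sensitivity_is_weight_over_ten(self):
        a = theoretical_dqi(_groups_frame({"vegetable": 0.0})).scores.iloc[0]
        b = theoretical_dqi(_groups_frame({"vegetable": 10.0})).scores.iloc[0]
        assert b - a == pytest.approx(3.0)   # weight +3, /10

    def test_missing_weighted_group_named(self):
        frame = _groups_frame({}).drop(columns=["low-fat protein"])
        with pytest.raises(MissingGroupError, match="low-fat protein"):
            theoretical_dqi(frame)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 99), c=st.floats(-1, 1))
    def test_linearity(self, seed, c):
        r = np.random.default_rng(seed)
        values = {g: float(v) for g, v in zip(
            GROUPS_12 + ["low-fat protein"], r.uniform(-100, 100, 13))}
        s1 = theoretical_dqi(_groups_frame(values)).scores.iloc[0]
        s2 = theoretical_dqi(
            _groups_frame({k: v * c for k, v in values.items()})).scores.iloc[0]
        assert s2 == pytest.approx(s1 * c, abs=1e-9)


class TestMerging:
    def test_published_matrix_merges_to_nine_groups(self):
        merge_map = merge_map_from_correlation(defaults.group_correlations())
        assert len(merge_map) == 9
        merged = {k: set(v) for k, v in merge_map.items() if len(v) > 1}
        assert {"salty", "high-fat protein"} in merged.values()
        assert {"sweet", "saturated fat", "refined carbohydrate"} in merged.values()

    def test_components_strategy_chains_through_borderline_pair(self):
        # the printed matrix has refined carb--salty r = 0.55, so transitive
        # closure fuses both published clusters into one (8 groups)
        merge_map = merge_map_from_correlation(
            defaults.group_correlations(), strategy="components")
        assert len(merge_map) == 8

    def test_identity_correlation_leaves_groups_untouched(self):
        corr = pd.DataFrame(np.eye(12), index=GROUPS_12, columns=GROUPS_12)
        merge_map = merge_map_from_correlation(corr)
        assert len(merge_map) == 12
        assert all(len(v) == 1 for v in merge_map.values())

    def test_three_way_merge_averages_by_hand(self, rng):
        base = rng.normal(size=300)
        df = pd.DataFrame({
            "a": base + 0.2 * rng.normal(size=300),
            "b": base + 0.2 * rng.normal(size=300),
            "c": base + 0.2 * rng.normal(size=300),
            "d": rng.normal(size=300),
        })
        merged, merge_map = merge_correlated_groups(df, threshold=0.5)
        assert set(merge_map["a+b+c"]) == {"a", "b", "c"}
        hand = (df["a"] + df["b"] + df["c"]) / 3.0
        np.testing.assert_allclose(merged["a+b+c"], hand, atol=1e-12)
        np.testing.assert_allclose(merged["d"], df["d"], atol=1e-12)

    def test_idempotent_on_default_cohort(self, default_dataset):
        groups = default_dataset.food_group_table()
        merged, _ = merge_correlated_groups(groups)
        merged2, merge_map2 = merge_correlated_groups(merged)
        assert all(len(v) == 1 for v in merge_map2.values())
        pd.testing.assert_frame_equal(
            merged2[merged.columns], merged, check_names=False)

    def test_default_cohort_reproduces_published_merges(self, default_dataset):
        _, merge_map = merge_correlated_groups(
            default_dataset.food_group_table())
        nontrivial = {frozenset(v) for v in merge_map.values() if len(v) > 1}
        assert frozenset({"salty", "high-fat protein"}) in nontrivial
        assert frozenset(
            {"sweet", "saturated fat", "refined carbohydrate"}) in nontrivial
        assert len(merge_map) == 9


@pytest.fixture(scope="module")
def fitted_hybrid(default_dataset):
    from likingdqi import build_crfs
    _, crfs = build_crfs(default_dataset.biomarkers)
    hyb = hybrid_dqi(default_dataset.food_group_table(), crfs,
                     default_dataset.covariate_table(), DQIConfig(seed=0))
    return hyb, crfs


class TestHybrid:
    def test_reverse_coding_contract(self, fitted_hybrid):
        hyb, crfs = fitted_hybrid
        assert np.corrcoef(hyb.scores, crfs)[0, 1] <= 0

    def test_vegetable_weight_positive_after_reverse_coding(self, fitted_hybrid):
        hyb, _ = fitted_hybrid
        assert hyb.weights["vegetable"] > 0
        # harmful planted block carries negative (moderation) weight
        assert hyb.weights[
            "refined carbohydrate+sweet+saturated fat"] < 0

    def test_scorer_reproduces_training_scores(self, fitted_hybrid,
                                               default_dataset):
        hyb, _ = fitted_hybrid
        np.testing.assert_allclose(
            hyb.apply(default_dataset.food_group_table()), hyb.scores,
            atol=1e-10)

    def test_null_cohort_yields_negligible_heldout_signal(self):
        from likingdqi import build_crfs
        from likingdqi.validation import heldout_delta_r2
        deltas = []
        for seed in range(5):
            cohort = generate_cohort(CohortSpec(n=600, seed=100 + seed).null())
            ds = Dataset.from_cohort(cohort)
            groups = ds.food_group_table()
            cov = ds.covariate_table()
            model, crfs = build_crfs(ds.biomarkers.iloc[:400])
            hyb = hybrid_dqi(groups.iloc[:400], crfs, cov.iloc[:400],
                             DQIConfig(seed=seed))
            crfs_test = model.apply(ds.biomarkers.iloc[400:])
            dqi_test = hyb.apply(groups.iloc[400:])
            deltas.append(heldout_delta_r2(cov.iloc[400:], dqi_test,
                                           crfs_test)[2])
        assert np.mean(deltas) < 0.02


class TestEmpirical:
    def test_reverse_coding_contract(self, default_dataset):
        from likingdqi import build_crfs
        _, crfs = build_crfs(default_dataset.biomarkers)
        emp = empirical_dqi(default_dataset.survey, crfs,
                            default_dataset.covariate_table(),
                            DQIConfig(seed=1))
        assert np.corrcoef(emp.scores, crfs)[0, 1] <= 0
        assert len([w for w in emp.weights]) == 10

    def test_planted_single_signal_recovered_out_of_sample(self,
                                                           default_dataset):
        # outcome manufactured to be exactly -z(vegetable liking)
        groups = default_dataset.food_group_table()
        veg = groups["vegetable"]
        crfs = -(veg - veg.mean()) / veg.std(ddof=1)
        train = np.arange(0, 600)
        test = np.arange(600, len(groups))
        emp = empirical_dqi(default_dataset.survey.iloc[train],
                            crfs.iloc[train],
                            default_dataset.covariate_table().iloc[train],
                            DQIConfig(seed=2))
        dqi_test = emp.apply(default_dataset.survey.iloc[test])
        assert np.corrcoef(dqi_test, veg.iloc[test])[0, 1] > 0.9


class TestStandardizedScale:
    def test_published_points_table_loads(self):
        scale = StandardizedScale.from_points()
        assert int(scale.max_points.sum()) == 100
        assert scale.max_points["vegetable"] == 18
        assert scale.max_points["sweet+saturated fat+refined carbohydrate"] == 52

    def test_best_possible_profile_scores_100(self):
        scale = StandardizedScale.from_points()
        values = {}
        for comp in scale.components:
            members = comp.split("+")
            liking = 100.0 if comp in scale.adequacy else -100.0
            for m in members:
                values[m] = liking
        frame = pd.DataFrame([values])
        assert scale.score(frame).iloc[0] == pytest.approx(100.0)

    def test_vegetable_contribution_18_points_and_0(self):
        scale = StandardizedScale.from_points()
        neutral = {g: 0.0 for g in GROUPS_12}
        hi = pd.DataFrame([dict(neutral, vegetable=100.0)])
        lo = pd.DataFrame([dict(neutral, vegetable=-100.0)])
        assert scale.component_points(hi)["vegetable"].iloc[0] == \
            pytest.approx(18.0)
        assert scale.component_points(lo)["vegetable"].iloc[0] == \
            pytest.approx(0.0)

    def test_neutral_profile_scores_midpoint_50(self):
        scale = StandardizedScale.from_points()
        frame = pd.DataFrame([{g: 0.0 for g in GROUPS_12}])
        assert scale.score(frame).iloc[0] == pytest.approx(50.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 999))
    def test_bounded_and_monotone(self, seed):
        scale = StandardizedScale.from_points()
        r = np.random.default_rng(seed)
        values = {g: float(v)
                  for g, v in zip(GROUPS_12, r.uniform(-100, 100, 12))}
        frame = pd.DataFrame([values])
        score = scale.score(frame).iloc[0]
        assert 0.0 <= score <= 100.0
        bumped = dict(values, vegetable=min(values["vegetable"] + 10, 100.0))
        up = scale.score(pd.DataFrame([bumped])).iloc[0]
        assert up >= score - 1e-9
        worse = dict(values, **{"complex carbohydrate":
                                min(values["complex carbohydrate"] + 10, 100.0)})
        down = scale.score(pd.DataFrame([worse])).iloc[0]
        assert down <= score + 1e-9

    def test_derived_from_fitted_hybrid(self, fitted_hybrid, default_dataset):
        hyb, _ = fitted_hybrid
        scale = standardize_hybrid(hyb)
        assert int(scale.max_points.sum()) == 100
        assert scale.normalized_weights.sum() == pytest.approx(1.0)
        assert "vegetable" in scale.adequacy
        scores = scale.score(default_dataset.food_group_table())
        assert scores.between(0, 100).all()

    def test_all_zero_weights_rejected(self, fitted_hybrid):
        from dataclasses import replace
        hyb, _ = fitted_hybrid
        degenerate = replace(hyb, weights={k: 0.0 for k in hyb.weights})
        with pytest.raises(LikingDQIError):
            standardize_hybrid(degenerate)

    def test_largest_remainder_rounding_sums_to_100(self):
        from likingdqi.dqi import _largest_remainder_points
        w = pd.Series([1, 1, 1], index=list("abc"), dtype=float) / 3
        pts = _largest_remainder_points(w)
        assert int(pts.sum()) == 100
        assert sorted(pts) == [33, 33, 34]
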