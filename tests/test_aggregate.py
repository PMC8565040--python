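import math

import numpy as np
import pandas as pd
import pytest

from alcmeta.aggregate import (SurveyMeta, aggregate_surveys,
                               effective_sample_size, estimate_prevalence,
                               recalibrate_weights, tabulate_consumption)


class TestRecalibrate:
    def test_uniform_scaling(self):
        out = recalibrate_weights([1.0, 1.0], ["a", "a"], {"a": 10.0})
        assert np.allclose(out, [5.0, 5.0])

    def test_ratio_preserving(self):
        out = recalibrate_weights([1.0, 3.0], ["a", "a"], {"a": 8.0})
        assert np.allclose(out, [2.0, 6.0])

    def test_two_strata(self):
        out = recalibrate_weights([1, 1, 1, 1], ["a", "a", "b", "b"],
                                  {"a": 10.0, "b": 20.0})
        assert np.allclose(out, [5, 5, 10, 10])

    def test_idempotent(self):
        w = [0.5, 2.5, 1.0]
        once = recalibrate_weights(w, ["a", "a", "a"], {"a": 7.0})
        twice = recalibrate_weights(once, ["a", "a", "a"], {"a": 7.0})
        assert np.allclose(once, twice)

    def test_errors(self):
        with pytest.raises(ValueError, match="positive"):
            recalibrate_weights([0.0, 1.0], ["a", "a"], {"a": 1.0})
        with pytest.raises(ValueError, match="b"):
            recalibrate_weights([1.0], ["b"], {"a": 1.0})


class TestPrevalence:
    def test_all_drinkers(self):
        pp, pse = estimate_prevalence([1, 1, 1, 1], [1, 1, 1, 1],
                                      [1, 1, 2, 2])
        assert pp == 1.0
        assert pse == 0.0

    def test_srs_matches_binomial_formula(self):
        n = 100
        flags = np.array([1] * 50 + [0] * 50)
        pp, pse = estimate_prevalence(flags, np.ones(n), np.arange(n))
        assert pp == pytest.approx(0.5, abs=1e-14)
        # linearised design-based SRS variance: p(1-p)/(n-1)
        assert pse == pytest.approx(math.sqrt(0.25 / (n - 1)), abs=1e-10)

    def test_identical_cluster_means_give_zero_variance(self):
        flags = [1, 0, 1, 0]
        pp, pse = estimate_prevalence(flags, np.ones(4), [1, 1, 2, 2])
        assert pp == 0.5
        assert pse == pytest.approx(0.0, abs=1e-14)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="cluster"):
            estimate_prevalence([1, 0], [1, 1], [1, 1])


class TestTabulate:
    def test_single_record(self):
        out = tabulate_consumption([(0.0, 5.0)], [2.0])
        assert out == [(0.0, 5.0, 1.0)]

    def test_equal_weights_split(self):
        out = tabulate_consumption([(0, 1), (1, 2)], [1.0, 1.0])
        assert [pc for _, _, pc in out] == pytest.approx([0.5, 0.5])

    def test_weighted_tally(self):
        out = tabulate_consumption([(0, 1), (0, 1), (1, 2)], [1.0, 2.0, 1.0])
        assert [pc for _, _, pc in out] == pytest.approx([0.75, 0.25])

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tabulate_consumption([], [])


class TestEffectiveSampleSize:
    def test_single_survey_unchanged(self):
        ne = effective_sample_size([0.02], [15], [350])
        assert ne == pytest.approx([350.0])

    def test_quality_shifts_weight_and_conserves_total(self):
        ne = effective_sample_size([0.02, 0.02], [20, 10], [300, 300])
        assert ne[0] > ne[1]
        assert ne.sum() == pytest.approx(600.0)

    def test_identical_surveys_symmetric(self):
        ne = effective_sample_size([0.03, 0.03], [12, 12], [200, 200])
        assert np.allclose(ne, [200.0, 200.0])

    def test_higher_precision_earns_more(self):
        ne = effective_sample_size([0.01, 0.04], [15, 15], [250, 250])
        assert ne[0] > ne[1]
        assert ne.sum() == pytest.approx(500.0)

    def test_missing_bias_score_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size([0.02, 0.02], [15, np.nan], [100, 100])


def _micro(rng, n=400, p=0.4, clusters=8):
    sex = rng.integers(1, 3, n)
    age = rng.integers(1, 3, n)
    drinker = (rng.random(n) < p).astype(int)
    lc = np.where(drinker, 1.0, np.nan)
    uc = np.where(drinker, 5.0, np.nan)
    return pd.DataFrame(dict(sex=sex, age_group=age,
                             cluster=rng.integers(0, clusters, n),
                             weight=rng.uniform(0.5, 2.0, n),
                             drinker=drinker, lc=lc, uc=uc))


class TestAggregateSurveys:
    def test_contract_and_conservation(self):
        rng = np.random.default_rng(0)
        micro = {"S1": _micro(rng), "S2": _micro(rng)}
        meta = {"S1": SurveyMeta("S1", 2008, 15),
                "S2": SurveyMeta("S2", 2010, 10)}
        prev, cons = aggregate_surveys(micro, meta)
        assert set(prev.columns) == {"survey_id", "sex", "age_group", "pp", "pse"}
        sums = cons.groupby(["survey_id", "sex", "age_group"])["pc"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)
        # effective sample sizes conserve the pooled drinker count per cell
        ne = cons.groupby(["survey_id", "sex", "age_group"])["ne"].first()
        raw = {sid: int(df.drinker.sum()) for sid, df in micro.items()}
        per_cell = ne.groupby(level=[1, 2]).sum()
        raw_cells = pd.concat(
            [df[df.drinker == 1].groupby(["sex", "age_group"]).size()
             for df in micro.values()], axis=1).fillna(0).sum(axis=1)
        assert np.allclose(per_cell.sort_index(), raw_cells.sort_index())

    def test_prevalence_only_survey_has_no_tuples(self):
        rng = np.random.default_rng(1)
        micro = {"Q": _micro(rng), "P": _micro(rng)}
        meta = {"Q": SurveyMeta("Q", 2008, 15),
                "P": SurveyMeta("P", 2009, 12, has_quantity=False)}
        prev, cons = aggregate_surveys(micro, meta)
        assert "P" in set(prev.survey_id)
        assert "P" not in set(cons.survey_id)

    def test_per_survey_mode_conserves_survey_totals(self):
        rng = np.random.default_rng(2)
        micro = {"S1": _micro(rng), "S2": _micro(rng)}
        meta = {"S1": SurveyMeta("S1", 2008, 18),
                "S2": SurveyMeta("S2", 2010, 8)}
        _, cons = aggregate_surveys(micro, meta, ne_mode="per_survey")
        ne = cons.groupby(["survey_id", "sex", "age_group"])["ne"].first()
        total = ne.groupby(level=0).sum().sum()
        raw_total = sum(int(df.drinker.sum()) for df in micro.values())
        assert total == pytest.approx(raw_total)
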