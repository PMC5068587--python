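"""Orthogonal contrasts, contrast scores and the inference layer."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gcsr.stats import (
    FREQ_BINS_HZ,
    SSD_LEVELS,
    TRIAL_TYPES,
    channel_gradient,
    contrast_score,
    group_contrast_anova,
    one_sample_contrast_test,
    poly_weights,
    stepwise_forward,
    trait_correlations,
)

# classical orthogonal-polynomial tables for equally spaced levels
TEXTBOOK = {
    (3, 1): (-1, 0, 1),
    (3, 2): (1, -2, 1),
    (9, 1): (-4, -3, -2, -1, 0, 1, 2, 3, 4),
    (9, 2): (28, 7, -8, -17, -20, -17, -8, 7, 28),
    (9, 3): (-14, 7, 13, 9, 0, -9, -13, -7, 14),
}


class TestPolyWeights:
    @pytest.mark.parametrize("n, order", sorted(TEXTBOOK))
    def test_matches_textbook_tables(self, n, order):
        assert poly_weights(n, order).weights == TEXTBOOK[(n, order)]

    @pytest.mark.parametrize("n", [3, 5, 9])
    def test_zero_sum_and_pairwise_orthogonality(self, n):
        ws = [poly_weights(n, k).as_array() for k in range(1, min(4, n))]
        for w in ws:
            assert w.sum() == 0
        for i in range(len(ws)):
            for j in range(i + 1, len(ws)):
                assert np.dot(ws[i], ws[j]) == 0

    def test_order_must_be_below_levels(self):
        with pytest.raises(ValueError):
            poly_weights(3, 3)

    def test_named_orders(self):
        assert poly_weights(3, "quadratic").weights == (1, -2, 1)


def _full_cells(fill):
    """Complete 2 x 3 x 9 cell table; fill(tt, lvl, f) -> log power."""
    rows = []
    for tt in TRIAL_TYPES:
        for lvl in SSD_LEVELS:
            for f in FREQ_BINS_HZ:
                rows.append(dict(trial_type=tt, ssd_level=lvl, frequency_hz=f,
                                 log_power=fill(tt, lvl, f)))
    return pd.DataFrame(rows)


class TestContrastScore:
    def test_constant_cells_annihilated(self):
        cells = _full_cells(lambda tt, lvl, f: 4.2)
        assert contrast_score(cells, "cubic") == pytest.approx(0.0)

    def test_self_contrast_gives_sum_of_squared_weights(self):
        w_tt = {"stop": 1.0, "go": -1.0}
        w_ssd = dict(zip(SSD_LEVELS, (-1.0, 2.0, -1.0)))
        w_f = dict(zip(FREQ_BINS_HZ, poly_weights(9, "cubic").as_array()))
        cells = _full_cells(lambda tt, lvl, f: w_tt[tt] * w_ssd[lvl] * w_f[f])
        expected = sum(
            (w_tt[tt] * w_ssd[lvl] * w_f[f]) ** 2
            for tt in TRIAL_TYPES for lvl in SSD_LEVELS for f in FREQ_BINS_HZ
        )
        assert contrast_score(cells, "cubic") == pytest.approx(expected)
        assert expected > 0

    @pytest.mark.parametrize("order", ["linear", "quadratic", "cubic"])
    def test_matches_brute_force_triple_sum(self, order):
        rng = np.random.default_rng(5)
        values = {}
        cells = _full_cells(lambda tt, lvl, f: values.setdefault((tt, lvl, f),
                                                                 float(rng.normal())))
        w_tt = {"stop": 1.0, "go": -1.0}
        w_ssd = dict(zip(SSD_LEVELS, (-1.0, 2.0, -1.0)))
        w_f = dict(zip(FREQ_BINS_HZ, poly_weights(9, order).as_array()))
        brute = sum(values[tt, lvl, f] * w_tt[tt] * w_ssd[lvl] * w_f[f]
                    for tt in TRIAL_TYPES for lvl in SSD_LEVELS for f in FREQ_BINS_HZ)
        assert contrast_score(cells, order) == pytest.approx(brute)

    def test_incomplete_cells_give_nan(self):
        cells = _full_cells(lambda tt, lvl, f: 1.0)
        cells = cells[~((cells.trial_type == "go") & (cells.ssd_level == "long"))]
        assert np.isnan(contrast_score(cells, "cubic"))


class TestOneSampleContrastTest:
    def test_all_zero_scores_degenerate(self):
        res = one_sample_contrast_test(np.zeros(10))
        assert res.degenerate
        assert res.f_value == 0.0

    def test_near_constant_scores_saturate(self):
        rng = np.random.default_rng(0)
        res = one_sample_contrast_test(1.0 + 1e-8 * rng.normal(size=8))
        assert res.f_value > 1e10

    def test_f_equals_t_squared_and_p_matches_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.3, 1.0, 24)
        res = one_sample_contrast_test(x)
        t, p = sps.ttest_1samp(x, 0.0)
        assert res.f_value == pytest.approx(t**2)
        assert res.p_value == pytest.approx(p)
        assert res.df == (1, 23)


class TestGroupAnova:
    def test_identical_groups_give_zero_f(self):
        scores = np.tile([1.0, 2.0, 3.0], 3)
        groups = np.repeat(["a", "b", "c"], 3)
        # every group holds the same values -> between-group SS exactly 0
        res = group_contrast_anova(scores, groups)
        assert res.f_value == pytest.approx(0.0, abs=1e-12)

    def test_large_separation_detected(self):
        rng = np.random.default_rng(2)
        scores = np.concatenate([rng.normal(0, 1, 10), rng.normal(10, 1, 10)])
        groups = np.repeat(["a", "b"], 10)
        res = group_contrast_anova(scores, groups)
        assert res.p_value < 1e-6

    def test_matches_hand_computed_sums_of_squares(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=36)
        groups = np.repeat(list("abcd"), 9)
        res = group_contrast_anova(scores, groups)
        grand = scores.mean()
        ssb = sum(9 * (scores[groups == g].mean() - grand) ** 2 for g in "abcd")
        ssw = sum(((scores[groups == g] - scores[groups == g].mean()) ** 2).sum()
                  for g in "abcd")
        f_oracle = (ssb / 3) / (ssw / 32)
        assert res.f_value == pytest.approx(f_oracle)
        assert res.df == (3, 32)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            group_contrast_anova(np.arange(4.0), np.array(["a", "a", "a", "b"]))


class TestTraitCorrelations:
    def _gcsr_table(self, rng, n=20):
        rows = []
        for pid in range(n):
            for f in FREQ_BINS_HZ:
                rows.append(dict(participant=f"p{pid:02d}", block=1,
                                 frequency_hz=f, gcsr=float(rng.normal())))
        return pd.DataFrame(rows)

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(4)
        table = self._gcsr_table(rng)
        f7 = table[table.frequency_hz == 7].set_index("participant")["gcsr"]
        out = trait_correlations(table, f7)
        row = out[out.frequency_hz == 7].iloc[0]
        assert row["r"] == pytest.approx(1.0)

    def test_independent_trait_mean_r_near_zero(self):
        rng = np.random.default_rng(5)
        rs = []
        for _ in range(40):
            table = self._gcsr_table(rng)
            trait = pd.Series(rng.normal(size=20),
                              index=[f"p{i:02d}" for i in range(20)])
            rs.extend(trait_correlations(table, trait)["r"].tolist())
        assert abs(np.mean(rs)) < 0.03

    def test_constant_trait_gives_nan(self):
        rng = np.random.default_rng(6)
        table = self._gcsr_table(rng)
        trait = pd.Series(5.0, index=[f"p{i:02d}" for i in range(20)])
        assert trait_correlations(table, trait)["r"].isna().all()


class TestStepwise:
    def test_true_predictor_enters_first(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(60, 9)),
                         columns=[f"gcsr_{f}Hz" for f in FREQ_BINS_HZ])
        y = 2.0 * X["gcsr_7Hz"] + 0.1 * rng.normal(size=60)
        steps = stepwise_forward(X, y)
        assert steps[0].predictor == "gcsr_7Hz"
        assert steps[0].p_value < 1e-6

    def test_f_change_matches_explicit_nested_rss(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = X["a"] + 0.5 * X["b"] + rng.normal(size=30)
        steps = stepwise_forward(X, y, p_enter=1.0)
        first = steps[0].predictor

        def rss(cols):
            design = np.column_stack([np.ones(30)] + [X[c] for c in cols])
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            return float(((y - design @ beta) ** 2).sum())

        rss0, rss1 = rss([]), rss([first])
        f_oracle = (rss0 - rss1) / (rss1 / (30 - 2))
        assert steps[0].f_change == pytest.approx(f_oracle)
        rss2 = rss([first, steps[1].predictor])
        f_oracle2 = (rss1 - rss2) / (rss2 / (30 - 3))
        assert steps[1].f_change == pytest.approx(f_oracle2)

    def test_null_selection_rate_near_familywise_level(self):
        """With 9 independent null predictors, some selection happens in
        roughly 1 - 0.95^9 ~ 37% of datasets (uncorrected forward entry)."""
        rng = np.random.default_rng(9)
        hits = 0
        reps = 300
        for _ in range(reps):
            X = pd.DataFrame(rng.normal(size=(60, 9)),
                             columns=[str(f) for f in FREQ_BINS_HZ])
            y = rng.normal(size=60)
            hits += bool(stepwise_forward(X, y))
        assert 0.20 < hits / reps < 0.55

    def test_constant_response_selects_nothing(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        assert stepwise_forward(X, pd.Series(np.full(40, 2.0))) == []


class TestChannelGradient:
    def test_focus_minus_others(self):
        rows = []
        for ch, v in [("F8", 1.0), ("F7", 0.2), ("F3", 0.0), ("Fz", 0.1), ("F4", 0.3)]:
            rows.append(dict(participant="p", block=1, channel=ch,
                             frequency_hz=8, gcsr=v))
        out = channel_gradient(pd.DataFrame(rows))
        assert out["gradient"].iloc[0] == pytest.approx(1.0 - 0.15)
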