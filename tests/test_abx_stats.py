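"""Trial scoring, discrimination fractions, and the within-subject ANOVA."""

import numpy as np
import pandas as pd
import pytest

from echowall import abx_stats


def _trial_row(**kw):
    base = dict(
        participant=1, configuration="normal", distance=0.81, pair_i="a", pair_j="b",
        repetition=1, x_assignment="A", response="A", answered=True, response_time=5.0,
    )
    base.update(kw)
    return base


@pytest.fixture()
def hand_fixture():
    """90-trial table with a known answer key: 60 correct, 30 incorrect
    (20 wrong responses + 10 timeouts with a 'correct' recorded response)."""
    rows = []
    k = 0
    for i in range(90):
        if i < 60:
            rows.append(_trial_row(participant=i % 5, response="A", x_assignment="A"))
        elif i < 80:
            rows.append(_trial_row(participant=i % 5, response="B", x_assignment="A"))
        else:
            rows.append(_trial_row(participant=i % 5, response="A", x_assignment="A", answered=False, response_time=30.0))
        k += 1
    return pd.DataFrame(rows)


class TestScoring:
    def test_hand_tally(self, hand_fixture):
        scored = abx_stats.score_trials(hand_fixture)
        assert int(scored["correct"].sum()) == 60
        assert abx_stats.pooled_df(scored) == pytest.approx(60 / 90)

    def test_match_is_correct(self):
        scored = abx_stats.score_trials(pd.DataFrame([_trial_row(response="B", x_assignment="B")]))
        assert bool(scored["correct"].iloc[0])

    def test_timeout_is_incorrect_even_if_response_matches(self):
        scored = abx_stats.score_trials(pd.DataFrame([_trial_row(answered=False)]))
        assert not bool(scored["correct"].iloc[0])

    def test_malformed_row_raises(self):
        with pytest.raises(ValueError, match="malformed"):
            abx_stats.score_trials(pd.DataFrame([_trial_row(response="X")]))

    def test_overtime_raises(self):
        with pytest.raises(ValueError, match="limit"):
            abx_stats.score_trials(pd.DataFrame([_trial_row(response_time=31.0)]))


class TestComputeDF:
    def test_ceiling(self):
        rows = [_trial_row() for _ in range(6)]
        scored = abx_stats.score_trials(pd.DataFrame(rows))
        table = abx_stats.compute_df(scored, ["participant"])
        assert table["df"].iloc[0] == 1.0
        assert table["n_trials"].iloc[0] == 6

    def test_exact_fraction(self):
        rows = [_trial_row(response=("A" if i < 3 else "B")) for i in range(4)]
        scored = abx_stats.score_trials(pd.DataFrame(rows))
        assert abx_stats.compute_df(scored, ["pair_i"])["df"].iloc[0] == pytest.approx(0.75)

    def test_pooled_equals_weighted_mean_of_groups(self, hand_fixture):
        scored = abx_stats.score_trials(hand_fixture)
        by_p = abx_stats.compute_df(scored, ["participant"])
        weighted = (by_p["df"] * by_p["n_trials"]).sum() / by_p["n_trials"].sum()
        assert weighted == pytest.approx(abx_stats.pooled_df(scored))

    def test_per_texture_aggregates_containing_pairs(self):
        pairwise = pd.DataFrame(
            {"pair_i": ["a", "a", "b"], "pair_j": ["b", "c", "c"], "df": [0.6, 0.8, 1.0]}
        )
        out = abx_stats.per_texture_df(pairwise)
        a = out[out["texture"] == "a"]["df"].iloc[0]
        assert a == pytest.approx((0.6 + 0.8) / 2)


class TestBinomial:
    def test_at_chance_maximal_p(self):
        assert abx_stats.binomial_vs_chance(0.5, 100) == pytest.approx(1.0, abs=0.1)

    def test_perfect_42_of_42(self):
        assert abx_stats.binomial_vs_chance(1.0, 42) == pytest.approx(2 * 0.5**42, rel=1e-9)

    def test_perfect_2_of_2_not_significant(self):
        assert abx_stats.binomial_vs_chance(1.0, 2) == pytest.approx(0.5)

    def test_zero_trials_raises(self):
        with pytest.raises(ValueError):
            abx_stats.binomial_vs_chance(0.5, 0)


class TestRMAnova:
    def test_null_factor_f_near_zero(self):
        rng = np.random.default_rng(0)
        rows = []
        for s in range(6):
            base = rng.normal(0.7, 0.05)
            for t in ("x", "y"):
                for d in (0.8, 5.0):
                    rows.append({"participant": s, "texture": t, "distance": d,
                                 "df": base + (0.1 if d > 1 else 0.0) + rng.normal(0, 0.01)})
        res = abx_stats.rm_anova(pd.DataFrame(rows), within=["texture", "distance"])
        tex = res.effect("texture")
        assert tex["p"] > 0.05 and tex["eta_sq"] < 0.05
        assert res.effect("distance")["p"] < 0.001

    def test_two_by_two_hand_oracle(self):
        """SS decomposition on 8 numbers against a hand computation."""
        # subjects s1, s2; factor A levels a1, a2; factor B levels b1, b2
        data = {
            (1, "a1", "b1"): 1.0, (1, "a1", "b2"): 2.0, (1, "a2", "b1"): 3.0, (1, "a2", "b2"): 5.0,
            (2, "a1", "b1"): 2.0, (2, "a1", "b2"): 3.0, (2, "a2", "b1"): 4.0, (2, "a2", "b2"): 7.0,
        }
        rows = [{"participant": s, "A": a, "B": b, "df": 0.0 + v / 10} for (s, a, b), v in data.items()]
        res = abx_stats.rm_anova(pd.DataFrame(rows), within=["A", "B"])
        y = np.array([[[1, 2], [3, 5]], [[2, 3], [4, 7]]]) / 10.0  # (subject, A, B)
        grand = y.mean()
        ss_a = 4 * np.sum((y.mean(axis=(0, 2)) - grand) ** 2)
        ss_b = 4 * np.sum((y.mean(axis=(0, 1)) - grand) ** 2)
        a_eff = res.effect("A")
        b_eff = res.effect("B")
        assert a_eff["SS_effect"] == pytest.approx(ss_a)
        assert b_eff["SS_effect"] == pytest.approx(ss_b)
        # interaction SS by full inclusion-exclusion
        cell = y.mean(axis=0)
        ss_ab = 2 * np.sum((cell - y.mean(axis=(0, 2))[:, None] - y.mean(axis=(0, 1))[None, :] + grand) ** 2)
        assert res.effect("A x B")["SS_effect"] == pytest.approx(ss_ab)

    def test_matches_statsmodels_three_way(self, scored_responses):
        """F and p of every effect agree with statsmodels' AnovaRM."""
        from statsmodels.stats.anova import AnovaRM

        pairwise = (
            scored_responses.groupby(["participant", "configuration", "distance", "pair_i", "pair_j"], observed=True)["correct"]
            .mean().rename("df").reset_index()
        )
        per_tex = abx_stats.per_texture_df(pairwise, grouping=["participant", "configuration", "distance"])
        res = abx_stats.rm_anova(per_tex)
        sm = AnovaRM(per_tex, "df", "participant", within=["texture", "distance", "configuration"]).fit().anova_table
        for _, row in res.table.iterrows():
            key = row["effect"].replace(" x ", ":")
            assert row["F"] == pytest.approx(sm.loc[key, "F Value"], rel=1e-8)
            assert row["df_num"] == sm.loc[key, "Num DF"]
            assert row["df_den"] == sm.loc[key, "Den DF"]

    def test_sum_of_squares_partition(self, scored_responses):
        """All effect and error SS components add up to SS_total."""
        pairwise = (
            scored_responses.groupby(["participant", "configuration", "distance", "pair_i", "pair_j"], observed=True)["correct"]
            .mean().rename("df").reset_index()
        )
        per_tex = abx_stats.per_texture_df(pairwise, grouping=["participant", "configuration", "distance"])
        res = abx_stats.rm_anova(per_tex)
        y = per_tex["df"].to_numpy()
        ss_total = np.sum((y - y.mean()) ** 2)
        # SS_total = subject SS + sum over effects of (SS_effect + SS_error)
        pivot = per_tex.groupby("participant")["df"].mean()
        n_per_subject = len(per_tex) / len(pivot)
        ss_subject = n_per_subject * np.sum((pivot - y.mean()) ** 2)
        total = ss_subject + (res.table["SS_effect"] + res.table["SS_error"]).sum()
        assert total == pytest.approx(ss_total, rel=1e-9)

    def test_eta_ordering(self, scored_responses):
        pairwise = (
            scored_responses.groupby(["participant", "configuration", "distance", "pair_i", "pair_j"], observed=True)["correct"]
            .mean().rename("df").reset_index()
        )
        res = abx_stats.anova_from_pairwise(pairwise)
        assert (res.table["eta_sq"] <= res.table["partial_eta_sq"] + 1e-12).all()
        assert ((res.table["partial_eta_sq"] >= 0) & (res.table["partial_eta_sq"] <= 1)).all()

    def test_greenhouse_geisser_correction(self, scored_responses):
        """GG epsilon is 1 for two-level effects, bounded by 1/(k-1), and
        the adjusted p is never smaller than the uncorrected one."""
        pairwise = (
            scored_responses.groupby(["participant", "configuration", "distance", "pair_i", "pair_j"], observed=True)["correct"]
            .mean().rename("df").reset_index()
        )
        per_tex = abx_stats.per_texture_df(pairwise, grouping=["participant", "configuration", "distance"])
        res = abx_stats.rm_anova(per_tex, correction="gg")
        for _, row in res.table.iterrows():
            assert 0 < row["gg_epsilon"] <= 1.0
            if row["F"] > 1.0:  # the correction is conservative above F = 1
                assert row["p_gg"] >= row["p"] - 1e-12
        assert res.effect("distance")["gg_epsilon"] == pytest.approx(1.0)

    def test_unbalanced_raises_with_missing_cells(self):
        rows = [
            {"participant": s, "texture": t, "df": 0.5}
            for s in (1, 2) for t in ("x", "y")
        ][:-1]
        with pytest.raises(ValueError, match="missing cells"):
            abx_stats.rm_anova(pd.DataFrame(rows), within=["texture"])

    def test_report_formats_small_p(self):
        rng = np.random.default_rng(1)
        rows = [
            {"participant": s, "distance": d, "df": (0.9 if d > 1 else 0.5) + rng.normal(0, 0.01)}
            for s in range(8) for d in (0.8, 5.0)
        ]
        res = abx_stats.rm_anova(pd.DataFrame(rows), within=["distance"])
        assert "p < 0.001" in res.report()


class TestReaders:
    def test_df_table_roundtrip(self, tmp_path, scored_responses):
        from echowall.synthetic_data import pairwise_df_table

        pairwise = pairwise_df_table(scored_responses)
        path = tmp_path / "s1_synthetic.csv"
        pairwise.to_csv(path, index=False)
        again = abx_stats.read_df_table(path)
        pd.testing.assert_frame_equal(again, pairwise[abx_stats.S1_COLUMNS], check_dtype=False)

    def test_df_table_rejects_bad_columns(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"who": [1], "score": [0.5]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            abx_stats.read_df_table(path)

    def test_responses_roundtrip(self, tmp_path, scored_responses):
        path = tmp_path / "responses.csv"
        scored_responses[abx_stats.TRIAL_COLUMNS].to_csv(path, index=False)
        again = abx_stats.read_responses(path)
        assert len(again) == len(scored_responses)
        rescored = abx_stats.score_trials(again)
        assert rescored["correct"].sum() == scored_responses["correct"].sum()
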