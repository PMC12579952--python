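"""Wilcoxon preference tests, learning-model selection, test-phase ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from beetaste.behaviour import arcsine_sqrt, summarize_conditioning_log
from beetaste.behaviour_stats import (
    CHANCE_TRANSFORMED,
    LearningModelSet,
    fit_learning_models,
    letter_groupings,
    test_phase_anova as phase_anova,
    wilcoxon_vs_random,
)
from beetaste.synth import DesignSpec, ForagerParams, generate_cohort


def enumeration_p(diffs, w_obs):
    """Independent oracle: exact two-tailed p by brute-force enumeration of
    every sign assignment of the |difference| midranks."""
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(diffs))
    n = len(ranks)
    total = ranks.sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([0, 1], repeat=n)
    ]
    ws = np.array(ws)
    lo, hi = min(w_obs, total - w_obs), max(w_obs, total - w_obs)
    return ((ws >= hi).sum() + (ws <= lo).sum()) / len(ws)


class TestWilcoxon:
    def test_exact_p_matches_sign_enumeration(self):
        """n=5 rates all 0.6: W = 15 and the exact two-tailed p is 0.0625
        (2 of 32 equally likely sign assignments are as extreme)."""
        res = wilcoxon_vs_random([0.6] * 5)
        assert res.W == 15.0
        diffs = arcsine_sqrt(np.array([0.6] * 5)) - CHANCE_TRANSFORMED
        assert res.p == pytest.approx(enumeration_p(diffs, res.W))
        assert res.p == pytest.approx(0.0625)

    def test_exact_p_matches_enumeration_mixed_signs(self):
        rates = [0.3, 0.45, 0.55, 0.6, 0.65, 0.7, 0.35]
        res = wilcoxon_vs_random(rates)
        diffs = arcsine_sqrt(np.array(rates)) - CHANCE_TRANSFORMED
        assert res.p == pytest.approx(enumeration_p(diffs, res.W))

    def test_degenerate_all_at_baseline(self):
        res = wilcoxon_vs_random([0.5] * 12)
        assert res.degenerate and res.p == 1.0

    def test_permutation_invariance_and_w_bounds(self):
        rates = [0.4, 0.6, 0.55, 0.35, 0.7, 0.5, 0.65, 0.45, 0.62, 0.38, 0.58, 0.41]
        a = wilcoxon_vs_random(rates)
        b = wilcoxon_vs_random(rates[::-1])
        assert a.W == b.W and a.p == b.p
        n = len(rates)
        assert 0 <= a.W <= n * (n + 1) / 2
        assert a.median == pytest.approx(np.median(rates))

    def test_too_few_bees_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_vs_random([0.5, 0.6, 0.7])


def simulate_summaries(tastant, learn, salience, master_seed, n_bees=10):
    frames = []
    for i, (group, s) in enumerate(
        [("control", 0.0), (f"{tastant}_positive", salience), (f"{tastant}_negative", salience)]
    ):
        params = ForagerParams(learn_rate=learn if s > 0 else 0.0, cue_salience=s)
        log = generate_cohort(
            params, DesignSpec(group=group), n_bees=n_bees,
            master_seed=master_seed * 10 + i,
        )
        frames.append(summarize_conditioning_log(log))
    return pd.concat(frames, ignore_index=True)


class TestLearningModels:
    def test_aic_table_structure_and_parsimony(self):
        df = simulate_summaries("sucrose", 0.2, 1.0, 3)
        ms = fit_learning_models(df)
        assert (ms.table["delta_aic"] >= 0).all()
        sel = ms.table.set_index("model_id").loc[ms.selected]
        assert sel["delta_aic"] <= 2.0

    def test_row_order_invariance(self):
        df = simulate_summaries("nacl", 0.2, 1.0, 4)
        a = fit_learning_models(df).table.set_index("model_id")["aic"]
        b = fit_learning_models(df.sample(frac=1, random_state=0)).table.set_index(
            "model_id"
        )["aic"]
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_missing_group_rejected(self):
        df = simulate_summaries("quinine", 0.0, 0.0, 5)
        with pytest.raises(ValueError):
            fit_learning_models(df[df.group != "control"])

    def test_learning_generator_selects_group_experience_structure(self):
        hits = 0
        for seed in range(20):
            ms = fit_learning_models(simulate_summaries("sucrose", 0.2, 1.0, 100 + seed))
            hits += ms.delta_group_vs_same > 2
        assert hits >= 16

    def test_cue_blind_generator_selects_null_structure(self):
        hits = 0
        for seed in range(20):
            ms = fit_learning_models(simulate_summaries("sucrose", 0.0, 0.0, 200 + seed))
            hits += ms.selected == "null"
        assert hits >= 14


class TestTestPhaseAnova:
    def test_degrees_of_freedom_three_groups_of_ten(self):
        res = phase_anova(simulate_summaries("caffeine", 0.2, 1.0, 6))
        assert (res.df_between, res.df_within) == (2, 27)

    def test_constant_data_gives_zero_f(self):
        df = pd.DataFrame(
            {
                "bee_id": [f"b{i}" for i in range(9)],
                "group": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
                "test_t": 0.7,
            }
        )
        res = phase_anova(df)
        assert res.F == 0.0 and res.p == 1.0

    def test_small_group_rejected(self):
        df = pd.DataFrame(
            {"bee_id": ["b1", "b2", "b3"], "group": ["a", "a", "b"], "test_t": [0.5, 0.6, 0.7]}
        )
        with pytest.raises(ValueError):
            phase_anova(df)

    @pytest.mark.parametrize(
        "pmat, expected",
        [
            # chain: A~B ns, B~C ns, A-C significant -> a, ab, b
            ({("A", "B"): 0.3, ("B", "C"): 0.2, ("A", "C"): 0.01},
             {"A": "a", "B": "ab", "C": "b"}),
            # all different
            ({("A", "B"): 0.01, ("B", "C"): 0.01, ("A", "C"): 0.001},
             {"A": "a", "B": "b", "C": "c"}),
            # none different
            ({("A", "B"): 0.9, ("B", "C"): 0.9, ("A", "C"): 0.9},
             {"A": "a", "B": "a", "C": "a"}),
        ],
    )
    def test_letter_groupings_on_constructed_p_matrices(self, pmat, expected):
        labels = ["A", "B", "C"]
        m = pd.DataFrame(1.0, index=labels, columns=labels)
        for (a, b), p in pmat.items():
            m.loc[a, b] = m.loc[b, a] = p
        order = pd.Series({"A": 3.0, "B": 2.0, "C": 1.0})
        letters = letter_groupings(labels, m, order_by=order)
        assert letters == expected

    def test_letters_consistent_with_pairwise_significance(self):
        res = phase_anova(simulate_summaries("sucrose", 0.2, 1.0, 7))
        for _, row in res.tukey.iterrows():
            g1, g2 = row["contrast"].split(" - ")
            share = bool(set(res.letters[g1]) & set(res.letters[g2]))
            assert share == (row["p_adj"] >= 0.05)


class TestEndToEndPower:
    def test_conditioned_groups_detected_against_control(self):
        """Qualitative reproduction of the conditioning outcome: with
        learning on, Tukey separates both conditioned groups from control in
        >= 70% of replicates; with salience off the familywise false-alarm
        rate stays low."""
        hits = 0
        for seed in range(100):
            res = phase_anova(simulate_summaries("sucrose", 0.2, 1.0, 1000 + seed))
            tk = res.tukey.set_index("contrast")["p_adj"]
            control = [v for k, v in tk.items() if "control" in k]
            hits += all(v < 0.05 for v in control)
        assert hits >= 70

    def test_cue_blind_false_alarm_rate_low(self):
        false_alarms = 0
        for seed in range(100):
            res = phase_anova(simulate_summaries("sucrose", 0.0, 0.0, 2000 + seed))
            tk = res.tukey.set_index("contrast")["p_adj"]
            control = [v for k, v in tk.items() if "control" in k]
            false_alarms += any(v < 0.05 for v in control)
        assert false_alarms <= 10
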