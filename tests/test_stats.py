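"""Mixed-model ANOVA machinery: AICc, selection, per-term tests, Tukey letters."""

import numpy as np
import pandas as pd
import pytest

from photoacclim.anova import (
    ModelSpec,
    UndefinedAICcError,
    aicc,
    candidate_term_sets,
    compact_letter_display,
    repeated_measures_anova,
    select_fixed_effects,
    tukey_posthoc,
)

SPEC_TREES = ModelSpec(
    response="y", factors=("t_growth", "co2_growth"), group=None
)


def tree_table(rng, tg_effect=(0.0, 0.0), co2_effect=0.0, n_per=12, sd=1.0):
    eff = {"0T": 0.0, "4T": tg_effect[0], "8T": tg_effect[1]}
    rows = [
        {
            "t_growth": tg,
            "co2_growth": co2,
            "y": 10 + eff[tg] + (co2_effect if co2 == "EC" else 0) + rng.normal(0, sd),
        }
        for tg in ("0T", "4T", "8T")
        for co2 in ("AC", "EC")
        for _ in range(n_per)
    ]
    return pd.DataFrame(rows)


def repeated_table(rng, tg_effect=(0.0, 0.0), n_per=5, tree_sd=1.0, sd=1.0):
    rows = []
    eff = {"0T": 0.0, "4T": tg_effect[0], "8T": tg_effect[1]}
    t = 0
    for tg in ("0T", "4T", "8T"):
        for co2 in ("AC", "EC"):
            for _ in range(n_per):
                t += 1
                b = rng.normal(0, tree_sd)
                for tl in (10.0, 20.0, 30.0, 40.0):
                    rows.append(
                        {
                            "tree_id": f"t{t}",
                            "t_growth": tg,
                            "co2_growth": co2,
                            "t_leaf": tl,
                            "y": 10 + eff[tg] + b + rng.normal(0, sd),
                        }
                    )
    return pd.DataFrame(rows)


class TestAICc:
    def test_closed_forms(self):
        assert aicc(0.0, 2, 100) == pytest.approx(4 + 12 / 97)
        assert aicc(-10.0, 3, 10) == pytest.approx(30.0)

    def test_tends_to_aic(self):
        assert aicc(-5.0, 4, 10**7) == pytest.approx(10 + 8, rel=1e-5)

    def test_undefined_for_small_n(self):
        with pytest.raises(UndefinedAICcError):
            aicc(0.0, 5, 6)


class TestCandidates:
    def test_marginality_respected(self):
        spec = ModelSpec(response="y", factors=("a", "b", "c"), group=None)
        sets = candidate_term_sets(spec)
        assert len(sets) == 19  # hierarchical models on a 3-factor factorial
        for terms in sets:
            chosen = set(terms)
            for t in terms:
                if len(t) == 2:
                    assert all((f,) in chosen for f in t)
                if len(t) == 3:
                    assert all(
                        tuple(sorted(pair)) in chosen
                        for pair in [(t[0], t[1]), (t[0], t[2]), (t[1], t[2])]
                    )

    def test_invariant_to_factor_order(self):
        a = candidate_term_sets(ModelSpec(response="y", factors=("a", "b"), group=None))
        b = candidate_term_sets(ModelSpec(response="y", factors=("b", "a"), group=None))
        assert a == b


class TestSelection:
    def test_null_co2_usually_excluded(self):
        rng = np.random.default_rng(11)
        excluded = kept_tg = 0
        n = 80
        for _ in range(n):
            res = select_fixed_effects(tree_table(rng, tg_effect=(1.0, 2.0)), SPEC_TREES)
            excluded += ("co2_growth",) not in set(res.terms)
            kept_tg += ("t_growth",) in set(res.terms)
        assert kept_tg / n > 0.95
        assert excluded / n > 0.7

    def test_single_candidate_returned_unchanged(self):
        rng = np.random.default_rng(1)
        spec = ModelSpec(
            response="y", factors=("t_growth",), group=None, always_keep=("t_growth",)
        )
        res = select_fixed_effects(tree_table(rng), spec)
        assert res.terms == (("t_growth",),)

    def test_ladder_sorted_and_ties_prefer_small(self):
        rng = np.random.default_rng(2)
        res = select_fixed_effects(tree_table(rng), SPEC_TREES)
        assert res.ladder["aicc"].is_monotonic_increasing
        # pure-noise data: the intercept-only model should win
        assert res.terms == ()


class TestRepeatedMeasuresAnova:
    def test_constant_response(self):
        rng = np.random.default_rng(4)
        data = repeated_table(rng)
        data["y"] = 5.0
        tab = repeated_measures_anova(
            data, ModelSpec(response="y", factors=("t_growth", "co2_growth")),
            (("co2_growth",), ("t_growth",)),
        ).table
        assert tab.loc["t_growth", "F"] == pytest.approx(0.0, abs=1e-6)
        assert tab.loc["t_growth", "p"] == pytest.approx(1.0, abs=1e-6)

    def test_between_term_uses_between_df(self):
        rng = np.random.default_rng(5)
        spec = ModelSpec(
            response="y", factors=("t_leaf", "t_growth", "co2_growth"),
            continuous=("t_leaf",),
        )
        tab = repeated_measures_anova(
            repeated_table(rng), spec,
            (("co2_growth",), ("t_growth",), ("t_leaf",)),
        ).table
        # 30 trees, 4 between-subject parameters -> 26; within: 120-30-1 = 89
        assert tab.loc["t_growth", "den_df"] == 26
        assert tab.loc["t_leaf", "den_df"] == 89

    def test_dropped_terms_reported_absent(self):
        rng = np.random.default_rng(6)
        tab = repeated_measures_anova(
            tree_table(rng), SPEC_TREES, (("t_growth",),)
        ).table
        assert not tab.loc["co2_growth", "included"]
        assert np.isnan(tab.loc["co2_growth", "F"])

    def test_power_against_injected_warming_effect(self):
        # 30% capacity reduction at 8T, n=5 trees per cell, 10% lognormal CV
        rng = np.random.default_rng(7)
        hits = 0
        n = 60
        for _ in range(n):
            rows = [
                {
                    "t_growth": tg,
                    "co2_growth": co2,
                    "y": 80 * m * np.exp(rng.normal(-0.005, 0.1)),
                }
                for tg, m in (("0T", 1.0), ("4T", 0.9), ("8T", 0.7))
                for co2 in ("AC", "EC")
                for _ in range(5)
            ]
            tab = repeated_measures_anova(
                pd.DataFrame(rows), SPEC_TREES, (("co2_growth",), ("t_growth",))
            ).table
            hits += tab.loc["t_growth", "p"] < 0.05
        assert hits / n > 0.8

    def test_single_observation_per_tree_falls_back_to_ols(self):
        rng = np.random.default_rng(8)
        data = tree_table(rng, n_per=5)
        data["tree_id"] = [f"t{i}" for i in range(len(data))]
        spec = ModelSpec(
            response="y", factors=("t_growth", "co2_growth"), group="tree_id"
        )
        result = repeated_measures_anova(data, spec, (("co2_growth",), ("t_growth",)))
        assert result.method == "ols"


class TestTukey:
    def test_identical_means_single_letter(self):
        # identical group means with within-group spread: every mean difference
        # is exactly zero, so all adjusted p values sit at the top of the range
        pattern = [9.0, 10.0, 11.0, 10.5, 9.5, 10.0]
        rows = [
            {"t_growth": tg, "co2_growth": co2, "y": v}
            for tg in ("0T", "4T", "8T")
            for co2 in ("AC", "EC")
            for v in pattern
        ]
        pairs, letters = tukey_posthoc(pd.DataFrame(rows), "y")
        assert all(p > 0.89 for p in pairs["p-adj"])
        assert len(set(letters.values())) == 1

    def test_shifted_group_gets_unique_letter(self):
        data = tree_table(np.random.default_rng(1), n_per=6)
        data.loc[
            (data.t_growth == "8T") & (data.co2_growth == "EC"), "y"
        ] += 10.0
        _, letters = tukey_posthoc(data, "y")
        shifted = letters["8T-EC"]
        others = {v for k, v in letters.items() if k != "8T-EC"}
        assert all(set(shifted).isdisjoint(set(o)) for o in others)

    def test_letters_partition_consistently(self):
        data = tree_table(np.random.default_rng(2), tg_effect=(2.0, 5.0), n_per=6)
        pairs, letters = tukey_posthoc(data, "y")
        for _, row in pairs.iterrows():
            shared = set(letters[row["group1"]]) & set(letters[row["group2"]])
            if not shared:
                assert row["p-adj"] < 0.05
            else:
                assert row["p-adj"] >= 0.05

    def test_fewer_than_two_groups(self):
        data = tree_table(np.random.default_rng(3))
        data = data[(data.t_growth == "0T") & (data.co2_growth == "AC")]
        with pytest.raises(ValueError):
            tukey_posthoc(data, "y")

    def test_cld_definition(self):
        sig = {("a", "c"): True}
        letters = compact_letter_display(["a", "b", "c"], sig)
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])
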