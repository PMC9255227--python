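"""ANOVA against a sums-of-squares oracle, LSD letters, percent change."""

import math

import numpy as np
import pandas as pd
import pytest

from ojipkit import lsd_posthoc, one_way_anova, percent_change
from ojipkit.errors import StatisticsError
from ojipkit.stats import summarize_groups

from _oracles import anova_oracle


def tidy(rows):
    return pd.DataFrame(rows, columns=["sample_id", "group", "replicate",
                                       "parameter", "value"])


class TestAnova:
    def test_identical_groups(self):
        res = one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.f == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_complete_separation_flagged(self):
        res = one_way_anova({"a": [0, 0, 0], "b": [1, 1, 1]})
        assert math.isinf(res.f)
        assert res.p == 0.0
        assert any("degenerate" in f for f in res.flags)

    def test_no_variance_at_all(self):
        res = one_way_anova({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert res.f == 0.0 and res.p == 1.0
        assert res.flags

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            groups = {g: list(rng.normal(rng.uniform(0, 5), 1.0, 5))
                      for g in "abcd"}
            res = one_way_anova(groups)
            want = anova_oracle(groups)
            assert res.f == pytest.approx(want["f"], abs=1e-9 * max(1, want["f"]))
            assert res.mse == pytest.approx(want["mse"], rel=1e-9)
            assert res.df_err == want["df_e"]

    def test_needs_two_groups_of_two(self):
        with pytest.raises(StatisticsError):
            one_way_anova({"a": [1, 2, 3]})
        with pytest.raises(StatisticsError):
            one_way_anova({"a": [1, 2], "b": [5]})


class TestLsd:
    def test_close_groups_share_a_letter(self):
        groups = {"a": [10.0, 10.1, 9.9], "b": [10.05, 10.0, 10.1]}
        res = one_way_anova(groups)
        letters = lsd_posthoc(groups, 0.05, res.mse, res.df_err)
        assert letters["a"] == letters["b"] == "a"

    def test_separated_groups_get_distinct_letters(self):
        groups = {"lo": [1.0, 1.1, 0.9], "hi": [9.0, 9.2, 8.9]}
        res = one_way_anova(groups)
        letters = lsd_posthoc(groups, 0.05, res.mse, res.df_err, anova_p=res.p)
        assert letters["hi"] == "a" and letters["lo"] == "b"

    def test_protection_collapses_letters(self):
        groups = {"a": [1.0, 1.2], "b": [1.1, 1.3]}
        letters = lsd_posthoc(groups, 0.05, 0.01, 2, anova_p=0.9)
        assert set(letters.values()) == {"a"}

    def test_overlap_chain_can_share_letters(self):
        # middle group within LSD of both extremes -> letter overlap "ab"
        groups = {"hi": [10.0, 10.2, 9.8, 10.1], "mid": [9.0, 9.2, 8.8, 9.1],
                  "lo": [8.0, 8.2, 7.8, 8.1]}
        res = one_way_anova(groups)
        letters = lsd_posthoc(groups, 0.001, res.mse, res.df_err)
        assert len(letters["mid"]) >= 1  # assigned greedily, no crash
        assert letters["hi"][0] == "a"

    def test_df_err_guard(self):
        with pytest.raises(StatisticsError):
            lsd_posthoc({"a": [1, 2], "b": [3, 4]}, 0.05, 1.0, 0)

    def test_injected_effect_separates_control(self, rng):
        # strong injected effect >> LSD: control distinct in >= 95% of runs
        hits = 0
        for i in range(60):
            groups = {"CK": list(rng.normal(10, 0.3, 5)),
                      "D5": list(rng.normal(6, 0.3, 5)),
                      "D10": list(rng.normal(4, 0.3, 5)),
                      "D15": list(rng.normal(2, 0.3, 5))}
            res = one_way_anova(groups)
            letters = lsd_posthoc(groups, 0.05, res.mse, res.df_err, anova_p=res.p)
            others = {letters[g] for g in ("D5", "D10", "D15")}
            if all(letters["CK"] != o for o in others):
                hits += 1
        assert hits >= 57


class TestPercentChange:
    def test_halving_and_identity(self):
        table = tidy([("s1", "CK", 1, "x", 10.0), ("s2", "CK", 2, "x", 10.0),
                      ("s3", "T", 1, "x", 5.0), ("s4", "T", 2, "x", 5.0)])
        pct = percent_change(table, "CK").set_index("group")["percent_change"]
        assert pct["T"] == pytest.approx(-50.0)
        assert pct["CK"] == pytest.approx(0.0)

    def test_zero_control_mean_flagged(self):
        table = tidy([("s1", "CK", 1, "x", 1.0), ("s2", "CK", 2, "x", -1.0),
                      ("s3", "T", 1, "x", 5.0), ("s4", "T", 2, "x", 7.0)])
        pct = percent_change(table, "CK")
        row = pct[pct.group == "T"].iloc[0]
        assert math.isnan(row["percent_change"])
        assert "zero" in row["flag"]

    def test_scale_equivariance(self):
        rows = [(f"s{i}", g, i, "x", v) for i, (g, v) in enumerate(
            [("CK", 4.0), ("CK", 6.0), ("T", 2.0), ("T", 4.0)])]
        a = percent_change(tidy(rows), "CK")
        scaled = tidy([(s, g, r, p, v * 7.3) for s, g, r, p, v in rows])
        b = percent_change(scaled, "CK")
        pd.testing.assert_frame_equal(a, b)

    def test_missing_control_rejected(self):
        with pytest.raises(StatisticsError, match="control"):
            percent_change(tidy([("s", "T", 1, "x", 1.0),
                                 ("t", "U", 1, "x", 2.0)]), "CK")


class TestSummarize:
    def test_structure_and_counts(self, rng):
        rows = []
        for g, mu in [("CK", 10), ("D5", 8), ("D10", 5), ("D15", 2)]:
            for r in range(1, 6):
                for p in ("alpha", "beta"):
                    rows.append((f"{g}-r{r}", g, r, p, float(rng.normal(mu, 0.4))))
        summary = summarize_groups(tidy(rows), "CK", 0.05)
        assert len(summary) == 8  # 4 groups x 2 parameters
        ck = summary[(summary.group == "CK")]
        assert (ck["percent_change_vs_control"] == 0).all()
        assert set(summary["n"]) == {5}
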