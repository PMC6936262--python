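import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from plastiscope import (
    Pwm,
    ValidationError,
    association_screen,
    class_presence,
    classify_interaction,
    collapse_classes,
    cooccurrence_optimization,
    cumulative_effects,
    scan_pwm,
    stepwise_aic,
)
from plastiscope.motifs import MotifClass, pwm_hit_threshold, _log_odds


def indicator_pwm(word: str, motif_id: str = "ind") -> Pwm:
    """Near-degenerate PWM that only the exact word can match."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    matrix = np.full((len(word), 4), 1e-9)
    for i, ch in enumerate(word):
        matrix[i, idx[ch]] = 1.0 - 3e-9
    return Pwm(motif_id, matrix)


def brute_force_hits(pwm: Pwm, match_p: float):
    """All k-mers whose exact background tail probability is below match_p."""
    lom = _log_odds(pwm)
    bg = pwm.background
    words = list(itertools.product(range(4), repeat=pwm.width))
    scores = {w: sum(lom[i, b] for i, b in enumerate(w)) for w in words}
    probs = {w: np.prod([bg[b] for b in w]) for w in words}
    hits = set()
    for w, s in scores.items():
        tail = sum(p for w2, p in probs.items() if scores[w2] >= s - 1e-9)
        if tail < match_p:
            hits.add("".join("ACGT"[b] for b in w))
    return hits


class TestScanPwm:
    def test_exact_word_in_window_detected(self):
        pwm = indicator_pwm("TATAAA")
        seqs = {
            "hit": "GC" * 40 + "TATAAA" + "GC" * 40,
            "miss": "GC" * 43 + "GC" * 40,
        }
        occ = scan_pwm(seqs, [pwm], window=(-100, 66), match_p=1e-3,
                       offsets={g: -100 for g in seqs})
        assert occ.loc["hit", "ind"] == 1 and occ.loc["miss", "ind"] == 0

    def test_reverse_complement_detected(self):
        pwm = indicator_pwm("TATAAA")
        rc = "TTTATA"
        seqs = {"rc_only": "GC" * 30 + rc + "GC" * 30}
        occ = scan_pwm(seqs, [pwm], window=(-60, 66), match_p=1e-3,
                       offsets={"rc_only": -60})
        assert occ.loc["rc_only", "ind"] == 1

    def test_hit_set_matches_exhaustive_enumeration_width_two(self):
        matrix = np.array([[0.9, 0.1 / 3, 0.1 / 3, 0.1 / 3]] * 2)
        pwm = Pwm("w2", matrix)
        expected = brute_force_hits(pwm, 0.1)
        for word in ("".join(p) for p in itertools.product("ACGT", repeat=2)):
            occ = scan_pwm({"g": word}, [pwm], window=(0, 2), match_p=0.1,
                           offsets={"g": 0})
            assert bool(occ.loc["g", "w2"]) == (
                word in expected or word[::-1].translate(
                    str.maketrans("ACGT", "TGCA")) in expected
            ), word

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_small_pwms_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        matrix = rng.dirichlet(np.ones(4), size=3)
        pwm = Pwm("r", matrix)
        match_p = 0.05
        expected = brute_force_hits(pwm, match_p)
        rc_map = str.maketrans("ACGT", "TGCA")
        for word in ("".join(p) for p in itertools.product("ACGT", repeat=3)):
            occ = scan_pwm({"g": word}, [pwm], window=(0, 3), match_p=match_p,
                           offsets={"g": 0})
            rc = word.translate(rc_map)[::-1]
            assert bool(occ.loc["g", "r"]) == (word in expected or rc in expected)

    def test_gene_with_too_many_ns_skipped(self):
        pwm = indicator_pwm("TA")
        with pytest.warns(UserWarning, match="skipped"):
            occ = scan_pwm({"bad": "N" * 50}, [pwm], window=(0, 50),
                           offsets={"bad": 0})
        assert "bad" not in occ.index

    def test_threshold_unreachable_yields_no_hits(self):
        pwm = indicator_pwm("TA")
        assert pwm_hit_threshold(pwm, 1e-12) == np.inf
        occ = scan_pwm({"g": "TATATA"}, [pwm], window=(0, 6), match_p=1e-12,
                       offsets={"g": 0})
        assert occ.loc["g", "ind"] == 0


class TestAssociationScreen:
    @staticmethod
    def planted(seed=0, n_genes=1200, shift=0.8):
        rng = np.random.default_rng(seed)
        presence = pd.DataFrame(
            (rng.random((n_genes, 3)) < 0.3).astype(int),
            index=[f"g{i}" for i in range(n_genes)],
            columns=["planted", "null1", "null2"],
        )
        gep = pd.DataFrame(
            {"gep": rng.normal(0, 1, n_genes) + shift * presence["planted"]},
            index=presence.index,
        )
        return presence, gep

    def test_planted_effect_recovered_with_direction(self):
        presence, gep = self.planted()
        res = association_screen(presence, gep)
        assert res.loc["planted", "significant"]
        assert res.loc["planted", "direction_label"] == "promoting"

    def test_ubiquitous_feature_untested(self):
        presence, gep = self.planted()
        presence["everywhere"] = 1
        res = association_screen(presence, gep)
        assert not res.loc["everywhere", "tested"]
        assert np.isnan(res.loc["everywhere", "p"])

    def test_constant_response_rejected(self):
        presence, gep = self.planted()
        gep["gep"] = 1.0
        with pytest.raises(ValidationError):
            association_screen(presence, gep)

    def test_multi_sample_mode_uses_consistency_rule(self):
        rng = np.random.default_rng(3)
        n = 600
        presence = pd.DataFrame(
            {"f": (rng.random(n) < 0.4).astype(int)},
            index=[f"g{i}" for i in range(n)],
        )
        base = rng.normal(0, 1, n) + 1.0 * presence["f"]
        samples = pd.DataFrame(
            {f"s{j}": base + rng.normal(0, 0.2, n) for j in range(5)},
            index=presence.index,
        )
        res = association_screen(presence, samples)
        assert res.loc["f", "significant"]
        assert res.loc["f", "direction_label"] == "promoting"
        assert res.loc["f", "n_samples"] == 5


class TestCollapseClasses:
    @staticmethod
    def screen_table(motifs, labels):
        return pd.DataFrame(
            {
                "significant": [lab != "none" for lab in labels],
                "direction_label": labels,
            },
            index=pd.Index(motifs, name="feature"),
        )

    def test_same_cluster_same_sign_merges(self):
        results = {"human": self.screen_table(["A", "B"], ["promoting", "promoting"])}
        classes = collapse_classes(results, {("v", "c1"): ["A", "B"]})
        assert len(classes) == 1
        assert classes[0].member_motifs == {"A", "B"}
        assert classes[0].direction() == "promoting"

    def test_opposite_signs_marked_inconsistent(self):
        results = {"human": self.screen_table(["A", "B"], ["promoting", "repressing"])}
        (cls,) = collapse_classes(results, {("v", "c1"): ["A", "B"]})
        assert cls.directions["human"] == "inconsistent"

    def test_transitive_merge_across_groups(self):
        results = {
            "human": self.screen_table(["A", "B", "C"], ["promoting"] * 3)
        }
        classes = collapse_classes(
            results, {("v", "c1"): ["A", "B"], ("p", "c2"): ["B", "C"]}
        )
        assert len(classes) == 1 and classes[0].member_motifs == {"A", "B", "C"}

    def test_unclustered_motifs_become_singletons(self):
        results = {"human": self.screen_table(["A", "B"], ["promoting", "repressing"])}
        classes = collapse_classes(results, {})
        assert {frozenset(c.member_motifs) for c in classes} == {
            frozenset({"A"}),
            frozenset({"B"}),
        }

    def test_class_presence_is_or_of_members(self):
        rng = np.random.default_rng(0)
        occ = pd.DataFrame(
            rng.integers(0, 2, (50, 3)), columns=["A", "B", "C"],
            index=[f"g{i}" for i in range(50)],
        )
        cls = MotifClass("C1", frozenset({"A", "C"}), {"human": "promoting"})
        cp = class_presence(occ, [cls])
        expected = ((occ["A"] > 0) | (occ["C"] > 0)).astype(int)
        assert (cp["C1"] == expected).all()


class TestStepwiseAic:
    def test_three_point_regression_matches_closed_form(self):
        # y = [0, 1, 3] on x = [0, 0, 1]: full model RSS = 0.5, n = 3, k = 1
        gep = pd.DataFrame({"gep": [0.0, 1.0, 3.0]}, index=list("abc"))
        presence = pd.DataFrame({"x": [0, 0, 1]}, index=list("abc"))
        kept, coef = stepwise_aic(gep, presence)
        n, rss_full, rss_null = 3, 0.5, np.var([0, 1, 3]) * 3
        aic_full = n * np.log(rss_full / n) + 2 * 2
        aic_null = n * np.log(rss_null / n) + 2 * 1
        expected_aic = min(aic_full, aic_null)
        assert coef.attrs["aic"] == pytest.approx(expected_aic)
        if aic_full < aic_null:
            assert kept == ["x"]

    @pytest.mark.parametrize("effect,expect_kept,min_rate", [
        # AIC drops a truly null predictor with probability P(chi2_1 < 2) ~ 0.84
        (0.0, False, 0.7),
        (1.0, True, 0.99),
    ])
    def test_null_dropped_and_effect_retained(self, effect, expect_kept, min_rate):
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 1000
            x = (rng.random(n) < 0.3).astype(float)
            y = rng.normal(0, 1, n) + effect * x
            gep = pd.DataFrame({"gep": y}, index=[f"g{i}" for i in range(n)])
            presence = pd.DataFrame({"m": x}, index=gep.index)
            kept, _ = stepwise_aic(gep, presence)
            hits += ("m" in kept) == expect_kept
        assert hits / n_seeds >= min_rate

    def test_duplicate_indicator_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        x = (rng.random(100) < 0.5).astype(int)
        gep = pd.DataFrame({"gep": rng.normal(0, 1, 100) + x},
                           index=[f"g{i}" for i in range(100)])
        presence = pd.DataFrame({"a": x, "b": x}, index=gep.index)
        with pytest.warns(UserWarning, match="duplicate"):
            kept, _ = stepwise_aic(gep, presence)
        assert "b" not in kept

    def test_too_few_genes_rejected(self):
        gep = pd.DataFrame({"gep": [1.0, 2.0, 3.0]}, index=list("abc"))
        presence = pd.DataFrame(
            {"a": [0, 1, 0], "b": [1, 0, 0]}, index=list("abc")
        )
        with pytest.raises(ValidationError):
            stepwise_aic(gep, presence)


class TestCumulativeEffects:
    @staticmethod
    def setup_classes(n=2000, seed=0, effect=0.6, n_classes=3):
        rng = np.random.default_rng(seed)
        presence = pd.DataFrame(
            (rng.random((n, n_classes)) < 0.3).astype(int),
            index=[f"g{i}" for i in range(n)],
            columns=[f"C{i}" for i in range(n_classes)],
        )
        gep = pd.DataFrame(
            {"gep": rng.normal(0, 1, n) + effect * presence.sum(axis=1)},
            index=presence.index,
        )
        classes = [
            MotifClass(c, frozenset({c}), {"human": "promoting"})
            for c in presence.columns
        ]
        return gep, presence, classes

    def test_additive_planting_gives_increasing_medians(self):
        gep, presence, classes = self.setup_classes()
        table = cumulative_effects(gep, presence, classes, "promoting", max_count=2)
        medians = table["median_gep"].to_numpy()
        assert (np.diff(medians) > 0).all()
        assert all(p < 0.05 for p in table.attrs["adjacent_trend_p"])

    def test_groups_limited_to_observed_counts(self):
        gep, presence, classes = self.setup_classes(n=30, n_classes=1)
        table = cumulative_effects(gep, presence, classes, "promoting")
        assert set(table.index) <= {0, 1}

    def test_direction_without_classes_rejected(self):
        gep, presence, classes = self.setup_classes()
        with pytest.raises(ValidationError):
            cumulative_effects(gep, presence, classes, "repressing")


class TestCooccurrence:
    def test_perfect_cooccurrence_hand_p(self):
        # [[10, 0], [0, 10]]: two-sided Fisher p = 2 / C(20, 10)
        genes = [f"g{i}" for i in range(20)]
        presence = pd.DataFrame(
            {"A": [1] * 10 + [0] * 10, "B": [1] * 10 + [0] * 10}, index=genes
        )
        pairs, _ = cooccurrence_optimization(
            presence, {"A": "promoting", "B": "promoting"}
        )
        row = pairs.iloc[0]
        assert row["call"] == "enriched"
        assert row["p"] == pytest.approx(2 / comb(20, 10))

    def test_independent_occurrences_rarely_called(self):
        rng = np.random.default_rng(7)
        n = 400
        presence = pd.DataFrame(
            (rng.random((n, 8)) < 0.4).astype(int),
            columns=[f"C{i}" for i in range(8)],
            index=[f"g{i}" for i in range(n)],
        )
        dirs = {f"C{i}": ("promoting" if i % 2 else "repressing") for i in range(8)}
        pairs, _ = cooccurrence_optimization(presence, dirs)
        assert (pairs["call"] != "neither").mean() < 0.2

    def test_single_pair_ratio_undetermined(self):
        genes = [f"g{i}" for i in range(20)]
        presence = pd.DataFrame(
            {"A": [1] * 10 + [0] * 10, "B": [0] * 10 + [1] * 10}, index=genes
        )
        _, report = cooccurrence_optimization(
            presence, {"A": "promoting", "B": "repressing"}
        )
        assert report["same_vs_opposite_p"] is None

    def test_needs_two_directed_classes(self):
        presence = pd.DataFrame({"A": [1, 0]}, index=["g0", "g1"])
        with pytest.raises(ValidationError):
            cooccurrence_optimization(presence, {"A": "promoting"})


class TestClassifyInteraction:
    @staticmethod
    def build(e1, e2, both_shift, n=300, seed=0, sd=1.0):
        """Four strata of n genes each with controlled median shifts."""
        rng = np.random.default_rng(seed)
        base = rng.normal(0, sd, 4 * n)
        shifts = np.r_[
            np.zeros(n), np.full(n, e1), np.full(n, e2), np.full(n, both_shift)
        ]
        genes = [f"g{i}" for i in range(4 * n)]
        gep = pd.DataFrame({"gep": base + shifts}, index=genes)
        presence = pd.DataFrame(
            {
                "c1": [0] * n + [1] * n + [0] * n + [1] * n,
                "c2": [0] * n + [0] * n + [1] * n + [1] * n,
            },
            index=genes,
        )
        return gep, presence

    def test_exact_sum_is_additive(self):
        gep, presence = self.build(0.8, 0.6, both_shift=1.4)
        call = classify_interaction(gep, presence, ("c1", "c2"))
        assert call.call == "additive"

    def test_doubled_joint_effect_is_enhancement(self):
        gep, presence = self.build(0.8, 0.6, both_shift=2.8)
        call = classify_interaction(gep, presence, ("c1", "c2"))
        assert call.call == "enhancement"

    def test_opposite_pair_matching_winner_is_dominance(self):
        gep, presence = self.build(0.8, -0.6, both_shift=0.8)
        call = classify_interaction(gep, presence, ("c1", "c2"))
        assert call.call == "dominance_of_1"

    def test_small_stratum_skipped(self):
        gep, presence = self.build(0.5, 0.5, both_shift=1.0, n=10)
        call = classify_interaction(gep, presence, ("c1", "c2"), min_group=20)
        assert call.call == "skipped"

    def test_same_direction_undershoot_is_undetermined(self):
        gep, presence = self.build(0.8, 0.8, both_shift=0.2)
        call = classify_interaction(gep, presence, ("c1", "c2"))
        assert call.call == "undetermined"
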