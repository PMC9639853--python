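"""RPM normalisation, depletion/enrichment scores and selection rules."""

import statistics

import numpy as np
import pandas as pd
import pytest

from pptscreen import (CountMatrix, ScreenConfig, depletion_score,
                       enrichment_score, rpm_normalize, score_screen,
                       select_depleted, select_enriched, stronger_at_5x)
from pptscreen.countmatrix import make_populations


def brute_force_sets(counts: dict[str, list[int]], cfg: ScreenConfig):
    """Independent first-principles recomputation of the selected sets.

    Plain python: RPM by hand, medians via statistics.median, thresholds
    applied literally as the screen describes them.
    """
    pops = ["init", "a1", "a2", "a3", "b1", "b2", "b3"]
    sums = {p: sum(counts[s][i] for s in counts)
            for i, p in enumerate(pops)}
    rpm = {s: [counts[s][i] * 1e6 / sums[p] for i, p in enumerate(pops)]
           for s in counts}
    depleted, e1x, e5x, both, stronger = [], [], [], [], []
    for s in counts:
        init_rpm = rpm[s][0]
        med1 = statistics.median(rpm[s][1:4])
        med5 = statistics.median(rpm[s][4:7])
        d1 = init_rpm / (med1 + cfg.pseudocount)
        d5 = init_rpm / (med5 + cfg.pseudocount)
        n1 = med1 / (init_rpm + cfg.pseudocount)
        n5 = med5 / (init_rpm + cfg.pseudocount)
        if counts[s][0] >= cfg.min_initial_reads and \
                d1 >= cfg.fold_threshold and d5 >= cfg.fold_threshold:
            depleted.append(s)
        gate = counts[s][0] >= cfg.min_initial_reads \
            if cfg.apply_initial_filter_to_enriched else True
        is1 = n1 >= cfg.fold_threshold and gate
        is5 = n5 >= cfg.fold_threshold and gate
        if is1:
            e1x.append(s)
        if is5:
            e5x.append(s)
        if is1 and is5 and (med5 >= med1 or not cfg.ordering_rule_5x_ge_1x):
            both.append(s)
        if (is1 or is5) and n5 >= cfg.stronger_factor * n1:
            stronger.append(s)
    return depleted, e1x, e5x, both, stronger


def random_matrix(rng, n_inserts: int) -> CountMatrix:
    inserts = set()
    while len(inserts) < n_inserts:
        inserts.add("".join(rng.choice(list("ACGT"), 11)))
    counts = pd.DataFrame(
        rng.integers(0, 60, size=(n_inserts, 7)),
        index=pd.Index(sorted(inserts), name="insert"),
        columns=["init", "a1", "a2", "a3", "b1", "b2", "b3"])
    counts.iloc[0] += 1  # keep every column sum positive
    pops = make_populations(3)
    pops["population"] = counts.columns
    return CountMatrix(counts, pops)


class TestRpmNormalize:
    def test_single_insert_is_one_million(self):
        pops = pd.DataFrame({"population": ["init"], "condition": ["initial"],
                             "replicate": [0]})
        cm = CountMatrix(pd.DataFrame({"init": [5]},
                                      index=pd.Index(["AAA"], name="insert")),
                         pops)
        assert rpm_normalize(cm)["init"].iloc[0] == pytest.approx(1e6)

    def test_simple_proportions(self):
        pops = pd.DataFrame({"population": ["init"], "condition": ["initial"],
                             "replicate": [0]})
        cm = CountMatrix(pd.DataFrame({"init": [1, 3]},
                                      index=pd.Index(["AAA", "CCC"],
                                                     name="insert")), pops)
        assert list(rpm_normalize(cm)["init"]) == [250_000.0, 750_000.0]

    def test_columns_sum_to_one_million(self, rng):
        for _ in range(20):
            cm = random_matrix(rng, 15)
            sums = rpm_normalize(cm).sum(axis=0)
            assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_empty_population_named_in_error(self, toy_count_matrix):
        counts = toy_count_matrix.counts.copy()
        counts["5x_c"] = 0
        cm = CountMatrix(counts, toy_count_matrix.populations)
        with pytest.raises(ValueError, match="5x_c"):
            rpm_normalize(cm)


class TestScores:
    def test_depletion_quoted_formula(self):
        assert depletion_score(120, [2, 4, 6]) == pytest.approx(24.0)

    def test_depletion_pseudocount_limit(self):
        assert depletion_score(120, [0, 0, 0]) == pytest.approx(120.0)
        assert depletion_score(0, [5, 5, 5]) == 0.0

    def test_enrichment_mirrored_formula(self):
        assert enrichment_score(4, [20, 25, 30]) == pytest.approx(5.0)

    def test_enrichment_limits(self):
        assert enrichment_score(7, [0, 0, 0]) == 0.0
        assert enrichment_score(0, [10, 10, 10]) == pytest.approx(10.0)

    def test_even_replicate_count_uses_midpoint_median(self):
        assert enrichment_score(0, [10, 20]) == pytest.approx(15.0)


class TestToyScreen:
    """Every value here is hand-checkable: column sums are 1000 everywhere,
    so RPM = 1000 x count."""

    def test_scores(self, toy_count_matrix):
        rec = score_screen(toy_count_matrix)
        t11 = rec.loc["TTTTTTTTTTT"]
        assert t11["rpm_initial"] == pytest.approx(10_000)
        assert t11["median_rpm_1x"] == pytest.approx(250_000)
        assert t11["enrichment_1x"] == pytest.approx(250_000 / 10_001)
        assert t11["enrichment_5x"] == pytest.approx(450_000 / 10_001)
        g11 = rec.loc["GGGGGGGGGGG"]
        assert g11["depletion_1x"] == pytest.approx(500_000 / 5_001)
        assert g11["depletion_5x"] == pytest.approx(500_000 / 1)

    def test_selected_sets(self, toy_count_matrix):
        rec = score_screen(toy_count_matrix)
        assert select_depleted(rec) == ["GGGGGGGGGGG"]
        enriched = select_enriched(rec)
        expected = ["CCCAGTGTGGC", "TTTTTTTTTTT"]
        assert sorted(enriched["1x"]) == expected
        assert sorted(enriched["5x"]) == expected
        assert sorted(enriched["both"]) == expected
        # 280000/20001 >= 2 * 120000/20001 but 450000/10001 < 2 * 250000/10001
        assert stronger_at_5x(rec) == ["CCCAGTGTGGC"]

    def test_initial_read_gate_excludes_scarce_insert(self, toy_count_matrix):
        # AAAAAAAAAAA: depletion scores 5000 but only 5 initial reads
        rec = score_screen(toy_count_matrix)
        assert rec.loc["AAAAAAAAAAA", "depletion_1x"] == pytest.approx(5000)
        assert "AAAAAAAAAAA" not in select_depleted(rec)


class TestSelectionRules:
    def _records(self, **cols):
        defaults = dict(raw_initial=100, rpm_initial=1.0, median_rpm_1x=1.0,
                        median_rpm_5x=1.0, depletion_1x=0.0, depletion_5x=0.0,
                        enrichment_1x=0.0, enrichment_5x=0.0)
        defaults.update(cols)
        return pd.DataFrame(defaults, index=pd.Index(["X"], name="insert"))

    def test_threshold_is_at_least(self):
        rec = self._records(enrichment_1x=5.0, enrichment_5x=5.0)
        assert select_enriched(rec)["1x"] == ["X"]

    def test_both_conditions_rule_for_depletion(self):
        rec = self._records(depletion_1x=6.0, depletion_5x=4.0)
        assert select_depleted(rec) == []

    def test_ordering_rule_excludes_unordered(self):
        rec = self._records(enrichment_1x=6.0, enrichment_5x=6.0,
                            median_rpm_1x=10.0, median_rpm_5x=9.0)
        sets = select_enriched(rec)
        assert sets["1x"] == ["X"] and sets["5x"] == ["X"]
        assert sets["both"] == []
        relaxed = select_enriched(rec, ScreenConfig(ordering_rule_5x_ge_1x=False))
        assert relaxed["both"] == ["X"]

    def test_stronger_at_5x_factor(self):
        rec = self._records(enrichment_1x=4.0, enrichment_5x=10.0)
        assert stronger_at_5x(rec) == ["X"]
        rec = self._records(enrichment_1x=4.0, enrichment_5x=7.0)
        assert stronger_at_5x(rec) == []

    def test_stronger_factor_one_is_superset_of_two(self, rng):
        cm = random_matrix(rng, 20)
        rec = score_screen(cm)
        assert set(stronger_at_5x(rec, 2.0)) <= set(stronger_at_5x(rec, 1.0))


class TestInvariants:
    def test_lower_fold_threshold_never_shrinks_sets(self, rng):
        for _ in range(10):
            cm = random_matrix(rng, 20)
            rec = score_screen(cm)
            loose, tight = ScreenConfig(fold_threshold=2), ScreenConfig()
            assert set(select_depleted(rec, tight)) <= \
                set(select_depleted(rec, loose))
            for key in ("1x", "5x", "both"):
                assert set(select_enriched(rec, tight)[key]) <= \
                    set(select_enriched(rec, loose)[key])

    def test_raising_initial_gate_never_grows_depleted_set(self, rng):
        cm = random_matrix(rng, 20)
        rec = score_screen(cm)
        assert set(select_depleted(rec, ScreenConfig(min_initial_reads=20))) \
            <= set(select_depleted(rec, ScreenConfig(min_initial_reads=5)))

    def test_scale_invariance_of_scores_and_sets(self, rng):
        cm = random_matrix(rng, 20)
        scaled_counts = cm.counts.copy()
        scaled_counts["a2"] *= 17  # library-size change in one population
        scaled = CountMatrix(scaled_counts, cm.populations)
        pd.testing.assert_frame_equal(score_screen(cm), score_screen(scaled))

    def test_matches_brute_force_oracle(self, rng):
        cfg = ScreenConfig()
        for _ in range(25):
            cm = random_matrix(rng, 12)
            rec = score_screen(cm)
            counts = {s: list(cm.counts.loc[s]) for s in cm.counts.index}
            dep, e1, e5, both, stronger = brute_force_sets(counts, cfg)
            assert sorted(select_depleted(rec, cfg)) == sorted(dep)
            sets = select_enriched(rec, cfg)
            assert sorted(sets["1x"]) == sorted(e1)
            assert sorted(sets["5x"]) == sorted(e5)
            assert sorted(sets["both"]) == sorted(both)
            assert sorted(stronger_at_5x(rec, cfg.stronger_factor, cfg)) == \
                sorted(stronger)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"fold_threshold": 1.0},
        {"pseudocount": 0.0},
        {"stronger_universe": "none"},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScreenConfig(**kwargs)
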