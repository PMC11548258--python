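"""Relevance screening: Wilcoxon, dynamics, max-correlation, selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gazefatigue.characteristics import CATALOGUE_KEYS
from gazefatigue.recording import GazeDataError, InvalidParameterError
from gazefatigue.relevance import (
    compile_relevance_table,
    inner_session_dynamics,
    label_by_mental_performance,
    landolt_wilcoxon,
    max_abs_correlation_over_diameters,
    select_characteristics,
    wilcoxon_rank_p,
)
from gazefatigue.simulate import FatigueEffectConfig, StudyDesign, simulate_study
from gazefatigue.events import EventConfig


class TestLabel:
    @pytest.mark.parametrize(
        "au,expected",
        [(1.5, "high"), (1.49, "low"), (4.0, "high"), (-0.5, "low"), (None, None)],
    )
    def test_threshold_dichotomy(self, au, expected):
        assert label_by_mental_performance(au) == expected


class TestWilcoxon:
    def test_null_groups_give_large_p(self, rng):
        for _ in range(5):
            pooled = rng.normal(size=24)
            a, b = pooled[:12], pooled[12:]
            assert wilcoxon_rank_p(a, b) >= 0.05

    def test_strong_shift_is_detected(self, rng):
        detected = 0
        for _ in range(30):
            a = rng.normal(0, 1, 20)
            b = rng.normal(3, 1, 20)  # 3 pooled SDs apart
            detected += wilcoxon_rank_p(a, b) < 0.05
        assert detected >= 29

    def test_matches_exact_enumeration_for_small_groups(self, rng):
        """Oracle: enumerate all C(8,4) group assignments of the pooled
        values; the two-sided p is the share of assignments whose rank-sum
        statistic is at least as extreme as the observed one."""
        a = rng.normal(size=4)
        b = rng.normal(size=4) + 0.8
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        obs = ranks[:4].sum()
        n = len(pooled)
        mean = 4 * (n + 1) / 2.0
        sums = [
            ranks[list(idx)].sum() for idx in itertools.combinations(range(n), 4)
        ]
        p_exact = np.mean([abs(s - mean) >= abs(obs - mean) - 1e-12 for s in sums])
        assert wilcoxon_rank_p(a, b) == pytest.approx(p_exact, abs=1e-12)

    def test_all_tied_values_give_p_one(self):
        assert wilcoxon_rank_p(np.ones(5), np.ones(7)) == 1.0

    def test_invariance_under_label_swap_and_monotone_transform(self, rng):
        a, b = rng.normal(size=10), rng.normal(0.5, 1, size=12)
        p = wilcoxon_rank_p(a, b)
        assert wilcoxon_rank_p(b, a) == pytest.approx(p)
        assert wilcoxon_rank_p(np.exp(a), np.exp(b)) == pytest.approx(p)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            wilcoxon_rank_p(np.array([]), np.ones(3))

    def test_landolt_wilcoxon_per_column(self, rng):
        m = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        m.loc[:9, "b"] += 5.0
        labels = ["high"] * 10 + ["low"] * 10
        p = landolt_wilcoxon(m, labels)
        assert p["b"] < 0.01 < p["a"]


class TestDynamics:
    def test_worked_61_19_pattern(self, rng):
        start = np.zeros(100)
        end = np.zeros(100)
        end[:61] = 1.0
        end[61:80] = -1.0
        up, down, score = inner_session_dynamics(start, end)
        assert (up, down, score) == (0.61, 0.19, 0.61)

    def test_all_increasing(self):
        up, down, score = inner_session_dynamics([1, 2, 3], [2, 3, 4])
        assert (up, down, score) == (1.0, 0.0, 1.0)

    def test_ties_count_in_neither(self):
        up, down, score = inner_session_dynamics([1.0, 1.0], [1.0, 1.0])
        assert (up, down, score) == (0.0, 0.0, 0.0)

    def test_up_plus_down_at_most_one(self, rng):
        a = rng.normal(size=50)
        b = a + rng.normal(size=50)
        up, down, _ = inner_session_dynamics(a, b)
        assert up + down <= 1.0


class TestMaxCorrelation:
    def test_perfect_correlation_at_one_diameter(self, rng):
        target = rng.normal(size=30)
        values = {
            0.5: rng.normal(size=30),
            1.0: 2.0 * target + 1.0,
            1.5: rng.normal(size=30),
        }
        corr, diam = max_abs_correlation_over_diameters(values, target)
        assert corr == pytest.approx(1.0)
        assert diam == 1.0

    def test_single_diameter_equals_plain_spearman(self, rng):
        target = rng.normal(size=25)
        vals = rng.normal(size=25)
        corr, diam = max_abs_correlation_over_diameters({0.7: vals}, target)
        assert corr == pytest.approx(stats.spearmanr(vals, target).statistic)
        assert diam == 0.7

    def test_max_dominates_every_single_diameter(self, rng):
        target = rng.normal(size=40)
        values = {d: rng.normal(size=40) + d * target for d in (0.5, 1.0, 1.5, 2.0)}
        best, _ = max_abs_correlation_over_diameters(values, target)
        for d, v in values.items():
            assert abs(best) >= abs(stats.spearmanr(v, target).statistic) - 1e-12

    def test_constant_diameters_skipped(self, rng):
        target = rng.normal(size=10)
        out = max_abs_correlation_over_diameters(
            {0.5: np.ones(10), 1.0: np.arange(10.0)}, target
        )
        assert out is not None and out[1] == 1.0
        assert (
            max_abs_correlation_over_diameters({0.5: np.ones(10)}, target) is None
        )


@pytest.fixture(scope="module")
def small_study():
    design = StudyDesign(
        n_participants=7, n_days=1, sessions_per_day=2,
        session_duration=40.0, seed=17,
        fatigue_schedule=lambda d, s: 0.6 * s,
    )
    return simulate_study(design, FatigueEffectConfig())


class TestCompileAndSelect:
    def test_table_covers_catalogue_sorted_by_p(self, small_study):
        table = compile_relevance_table(
            small_study, EventConfig(), diameter_grid=(1.0,)
        )
        assert len(table) == len(CATALOGUE_KEYS)
        p = table["wilcoxon_p"].to_numpy()
        assert np.all(np.diff(p[np.isfinite(p)]) >= 0)
        assert (table["dynamics_score"] <= 1.0).all()
        assert (table["crt_corr"].abs().dropna() <= 1.0).all()

    def test_alpha_one_selects_whole_catalogue(self, small_study):
        table = compile_relevance_table(
            small_study, EventConfig(), diameter_grid=None
        )
        sel = select_characteristics(
            table, alpha=1.01, expert_additions=(), head_size=len(CATALOGUE_KEYS)
        )
        assert set(sel.selected) == set(CATALOGUE_KEYS)

    def test_published_configuration_yields_seven(self, small_study):
        table = compile_relevance_table(
            small_study, EventConfig(), diameter_grid=None
        )
        sel = select_characteristics(table)
        assert len(sel.selected) == 7
        assert "fixation_speed_mean" in sel.selected

    def test_empty_filter_without_additions_errors(self):
        table = pd.DataFrame(
            {
                "wilcoxon_p": np.ones(len(CATALOGUE_KEYS)),
                "dynamics_score": 0.0,
                "crt_corr": np.nan,
            },
            index=list(CATALOGUE_KEYS),
        )
        with pytest.raises(GazeDataError):
            select_characteristics(table, expert_additions=())

    def test_unknown_expert_addition_rejected(self, small_study):
        table = compile_relevance_table(small_study, EventConfig(), None)
        with pytest.raises(InvalidParameterError):
            select_characteristics(table, expert_additions=("not_a_key",))
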