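"""Outcome classification, interval-censored durations, sub-area summaries."""

import math

import pytest

from nsikit.errors import NonMonotoneSeriesError
from nsikit.records_io import StageCounts
from nsikit.succession_stages import (
    SuccessionOutcome,
    classify_plot,
    nsi_time_correlation,
    stage_durations,
    summarize_subarea,
)

from conftest import F, G, S, make_plot


class TestClassifyPlot:
    @pytest.mark.parametrize(
        "stages,outcome",
        [
            ([G] * 7, SuccessionOutcome.NON_SUCCESSION),
            ([G, G, S, S, S, S, S], SuccessionOutcome.HARD_SUCCESSION),
            ([G, S, S, F, F, F, F], SuccessionOutcome.ACCESSIBLE_SUCCESSION),
            ([G, F, F, F, F, F, F], SuccessionOutcome.ACCESSIBLE_SUCCESSION),
        ],
    )
    def test_final_census_determines_outcome(self, stages, outcome):
        assert classify_plot(make_plot(stages)) is outcome

    def test_regression_rejected_by_default(self):
        plot = make_plot([G, S, G, S, S, S, S])
        with pytest.raises(NonMonotoneSeriesError):
            classify_plot(plot)

    def test_lenient_mode_uses_final_stage(self):
        plot = make_plot([G, S, G, S, S, S, S])
        assert classify_plot(plot, on_nonmonotone="final") is SuccessionOutcome.HARD_SUCCESSION


class TestStageDurations:
    def test_midpoint_brackets_worked_example(self, grass_to_forest_plot):
        d = stage_durations(grass_to_forest_plot)  # [G,G,G,S,S,F,F]
        assert (d.grassland.lower, d.grassland.upper) == (10, 15)
        assert d.grassland.point == 12.5
        assert (d.time_to_forest.lower, d.time_to_forest.upper) == (20, 25)
        assert d.time_to_forest.point == 22.5
        assert d.forest_tenure == 30 - 22.5
        assert d.shrub.point == 10.0  # 22.5 - 12.5
        assert not d.time_to_forest.censored

    def test_all_grassland_is_fully_censored(self, all_grass_plot):
        d = stage_durations(all_grass_plot)
        assert d.grassland.censored and d.shrub.censored and d.time_to_forest.censored
        assert d.grassland.lower == 30 and d.grassland.upper == math.inf
        assert d.forest_tenure is None

    def test_shrub_without_forest_right_censored(self):
        d = stage_durations(make_plot([G, S, S, S, S, S, S]))
        assert not d.grassland.censored
        assert d.shrub.censored and d.time_to_forest.censored

    def test_first_observation_estimator_returns_upper_bracket(self):
        d = stage_durations(make_plot([G, F, F, F, F, F, F]), estimator="first_observation")
        assert d.time_to_forest.point == 5

    def test_last_previous_estimator_returns_lower_bracket(self):
        d = stage_durations(make_plot([G, F, F, F, F, F, F]), estimator="last_previous")
        assert d.time_to_forest.point == 0

    def test_point_lies_within_bracket(self, grass_to_forest_plot):
        for est in ("midpoint", "first_observation", "last_previous"):
            d = stage_durations(grass_to_forest_plot, estimator=est)
            for dur in (d.grassland, d.time_to_forest):
                assert dur.lower <= dur.point <= dur.upper

    def test_finer_grid_shrinks_bracket(self):
        coarse = stage_durations(make_plot([G, G, G, S, S, F, F]))
        fine = stage_durations(
            make_plot(
                [G, G, G, G, G, G, S, S, S, S, F, F, F],
                years=tuple(range(1987, 2018, 2))[:13],
            )
        )
        coarse_width = coarse.grassland.upper - coarse.grassland.lower
        fine_width = fine.grassland.upper - fine.grassland.lower
        assert fine_width < coarse_width

    def test_unknown_estimator_rejected(self, all_grass_plot):
        with pytest.raises(ValueError, match="estimator"):
            stage_durations(all_grass_plot, estimator="mode")


class TestSummarizeSubarea:
    def test_counts_one_of_each_outcome(self):
        plots = [
            make_plot([G] * 7, plot_id="P1"),
            make_plot([G, S, S, S, S, S, S], plot_id="P2"),
            make_plot([G, S, F, F, F, F, F], plot_id="P3"),
        ]
        sub_of = {p.plot_id: "X-I" for p in plots}
        summary = summarize_subarea(plots, sub_of)["X-I"]
        assert summary.counts == StageCounts(1, 1, 1)
        assert summary.counts.N == 3

    def test_means_match_hand_computation(self):
        # forest entries bracketed at (5,10] and (20,25] -> points 7.5, 22.5
        plots = [
            make_plot([G, S, F, F, F, F, F], plot_id="P1"),
            make_plot([G, G, G, S, S, F, F], plot_id="P2"),
            make_plot([G] * 7, plot_id="P3"),  # censored, excluded from means
        ]
        sub_of = {p.plot_id: "X-I" for p in plots}
        summary = summarize_subarea(plots, sub_of)["X-I"]
        assert summary.mean_time_to_forest == pytest.approx((7.5 + 22.5) / 2)
        assert summary.mean_forest_tenure == pytest.approx((22.5 + 7.5) / 2)
        assert summary.log10_mean_forest_tenure == pytest.approx(math.log10(15.0))

    def test_log_of_mean_not_mean_of_logs(self):
        plots = [
            make_plot([G, F, F, F, F, F, F], plot_id="P1"),  # tenure 27.5
            make_plot([G, G, G, G, G, F, F], plot_id="P2"),  # tenure 7.5
        ]
        sub_of = {p.plot_id: "X-I" for p in plots}
        summary = summarize_subarea(plots, sub_of)["X-I"]
        mean_of_logs = (math.log10(27.5) + math.log10(7.5)) / 2
        assert summary.log10_mean_forest_tenure == pytest.approx(math.log10(17.5))
        assert summary.log10_mean_forest_tenure != pytest.approx(mean_of_logs)


class TestNsiTimeCorrelation:
    def test_comonotone_is_plus_one(self):
        nsi = {"A": 0.2, "B": 0.5, "C": 0.9}
        tenure = {"A": 0.5, "B": 0.8, "C": 1.2}
        assert nsi_time_correlation(nsi, tenure) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        nsi = {"A": 0.2, "B": 0.5, "C": 0.9}
        tenure = {"A": 1.2, "B": 0.8, "C": 0.5}
        assert nsi_time_correlation(nsi, tenure) == pytest.approx(-1.0)

    def test_constant_input_reported_undefined(self):
        nsi = {"A": 0.5, "B": 0.5, "C": 0.5}
        tenure = {"A": 1.0, "B": 2.0, "C": 3.0}
        assert math.isnan(nsi_time_correlation(nsi, tenure))

    def test_fewer_than_three_subareas_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            nsi_time_correlation({"A": 0.1, "B": 0.2}, {"A": 1.0, "B": 2.0})


def test_forest_final_iff_time_to_forest_uncensored():
    cases = [
        [G] * 7,
        [G, G, S, S, S, S, S],
        [G, S, S, F, F, F, F],
        [G, F, F, F, F, F, F],
    ]
    for stages in cases:
        plot = make_plot(stages)
        reached_forest = classify_plot(plot) is SuccessionOutcome.ACCESSIBLE_SUCCESSION
        assert reached_forest == (not stage_durations(plot).time_to_forest.censored)
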