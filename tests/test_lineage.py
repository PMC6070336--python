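import numpy as np
import pytest

from hss import lineage, simulate
from hss.lineage import (
    TraceNormalizer,
    crossing_fractions,
    detect_events,
    filter_cells,
    normalize_traces,
    onset_order,
    trace_heatmap,
)
from hss.rng import substream

from conftest import make_trace


@pytest.fixture()
def unit_reference():
    """Reference cohort whose channel/red ratios are exactly 1 (zero bg)."""
    t = np.arange(0, 10.5, 0.5)
    return [make_trace(t, np.ones_like(t), green=np.ones_like(t), cell_id="ref")]


class TestNormalizeTraces:
    def test_reference_normalizes_to_one(self, unit_reference):
        out = normalize_traces(unit_reference, unit_reference)
        assert np.allclose(out[0].orange_norm, 1.0)
        assert np.allclose(out[0].green_norm, 1.0)

    def test_zero_signal_trace_is_zero(self, unit_reference):
        t = np.arange(0, 5.5, 0.5)
        tr = make_trace(t, np.zeros_like(t))
        out = normalize_traces([tr], unit_reference)
        assert np.allclose(out[0].orange_norm, 0.0)

    def test_background_subtraction_arithmetic(self):
        """With background equal to half the signal and constant red, the
        normalized value is exactly halved... relative to the red signal that
        is also background-subtracted."""
        t = np.arange(0, 5.5, 0.5)
        red = 1000.0
        bg = 100.0
        ref = [simulate.CellTrace(cell_id="r", times_hr=t,
                                  green_raw=np.full_like(t, red - bg + bg),
                                  orange_raw=np.full_like(t, red),
                                  red_raw=np.full_like(t, red))]
        sig = make_trace(t, np.full_like(t, 0.2))  # orange = 200
        no_sub = normalize_traces([sig], ref, background=0.0)[0]
        sub = normalize_traces([sig], ref, background=bg)[0]
        # analytic: ((200-100)/(1000-100)) / ((1000-100)/(1000-100)) = 1/9
        assert np.allclose(sub.orange_norm, (200 - bg) / (red - bg))
        assert np.allclose(no_sub.orange_norm, 0.2)

    def test_nonpositive_red_masks_point_not_cell(self, unit_reference):
        t = np.arange(0, 2.5, 0.5)
        tr = simulate.CellTrace(cell_id="x", times_hr=t,
                                green_raw=np.zeros_like(t),
                                orange_raw=np.full_like(t, 500.0),
                                red_raw=np.array([1000, 0.0, 1000, 1000, 1000]))
        out = normalize_traces([tr], unit_reference)[0]
        assert out.orange_norm.mask[1]
        assert not out.orange_norm.mask[0]
        assert out.orange_norm.count() == 4

    def test_normalization_commutes_with_time_restriction(self, unit_reference):
        t = np.arange(0, 20.5, 0.5)
        rng = np.random.default_rng(5)
        raw = make_trace(t, rng.uniform(0, 1, len(t)))
        full = normalize_traces([raw], unit_reference)[0]
        half_raw = simulate.CellTrace(cell_id="h", times_hr=t[:21],
                                      green_raw=raw.green_raw[:21],
                                      orange_raw=raw.orange_raw[:21],
                                      red_raw=raw.red_raw[:21])
        half = normalize_traces([half_raw], unit_reference)[0]
        np.testing.assert_allclose(full.orange_norm[:21], half.orange_norm)


class TestFilterCells:
    def test_early_death_flag_excludes(self, unit_reference):
        t = np.arange(0, 5.5, 0.5)
        traces = [make_trace(t, np.zeros_like(t), cell_id=f"c{i}") for i in range(10)]
        raw = traces
        for i in range(3):
            raw[i].died_or_ejected_before_12h = True
        out = filter_cells(normalize_traces(raw, unit_reference), clamp_threshold=0.5)
        assert len(out) == 7

    def test_green_excursion_breaks_maintained_nucleation(self, unit_reference):
        t = np.arange(0, 5.5, 0.5)
        green = np.zeros_like(t)
        green[4] = 0.9  # one excursion above the clamp level
        tr = make_trace(t, np.zeros_like(t), green=green)
        out = filter_cells(normalize_traces([tr], unit_reference), clamp_threshold=0.5)
        assert out[0].maintained_nucleation is False

    def test_all_off_trace_is_maintained(self, unit_reference):
        t = np.arange(0, 5.5, 0.5)
        tr = make_trace(t, np.zeros_like(t))
        out = filter_cells(normalize_traces([tr], unit_reference), clamp_threshold=0.5)
        assert out[0].maintained_nucleation is True


class TestCrossingFractions:
    def test_direct_count(self, unit_reference):
        t = np.arange(0, 5.5, 0.5)
        maxima = [0.2, 0.4, 0.7, 0.9]
        traces = [make_trace(t, np.linspace(0, m, len(t)), cell_id=f"c{m}") for m in maxima]
        out = crossing_fractions(normalize_traces(traces, unit_reference))
        assert out["fraction_half_maximal"] == pytest.approx(0.5)

    def test_zero_half_level_returns_one(self, unit_reference):
        t = np.arange(0, 5.5, 0.5)
        traces = [make_trace(t, np.zeros_like(t))]
        out = crossing_fractions(normalize_traces(traces, unit_reference), half_level=0.0)
        assert out["fraction_half_maximal"] == 1.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            crossing_fractions([])

    def test_agrees_with_event_detection(self):
        """Fraction with >= 1 event at threshold equals fraction with
        max_orange >= threshold when min_duration is one sample."""
        traces = simulate.simulate_traces("dREIII", 40, 30.0, 0.5, substream(21, "tr"))
        clr4 = simulate.simulate_traces("clr4_null", 20, 30.0, 0.5, substream(21, "c"),
                                        early_death_fraction=0.0)
        cohort = filter_cells(normalize_traces(traces, clr4, background=20.0), 0.5)
        frac_cross = crossing_fractions(cohort, half_level=0.5, maintained_only=False)[
            "fraction_half_maximal"
        ]
        frac_event = np.mean([len(detect_events(t, 0.5)) > 0 for t in cohort])
        assert frac_cross == pytest.approx(frac_event)


class TestDetectEvents:
    def test_constant_zero_trace_has_no_events(self, unit_reference):
        t = np.arange(0, 10.5, 0.5)
        tr = normalize_traces([make_trace(t, np.zeros_like(t))], unit_reference)[0]
        assert detect_events(tr) == []

    def test_transient_plateau(self, unit_reference):
        t = np.arange(0, 20.5, 0.5)
        orange = np.zeros_like(t)
        orange[(t >= 5) & (t <= 10)] = 0.7
        tr = normalize_traces([make_trace(t, orange)], unit_reference)[0]
        events = detect_events(tr)
        assert len(events) == 1
        assert events[0].transient
        assert events[0].peak_value == pytest.approx(0.7)
        assert events[0].start_hr == pytest.approx(5.0)
        assert events[0].end_hr == pytest.approx(10.0)

    def test_terminal_run_is_not_transient(self, unit_reference):
        t = np.arange(0, 10.5, 0.5)
        orange = np.where(t >= 6, 0.8, 0.0)
        tr = normalize_traces([make_trace(t, orange)], unit_reference)[0]
        events = detect_events(tr)
        assert len(events) == 1
        assert not events[0].transient

    def test_min_duration_filters_blips(self, unit_reference):
        t = np.arange(0, 10.5, 0.5)
        orange = np.zeros_like(t)
        orange[4] = 0.9  # single-sample blip
        tr = normalize_traces([make_trace(t, orange)], unit_reference)[0]
        assert len(detect_events(tr, min_duration_hr=0.0)) == 1
        assert len(detect_events(tr, min_duration_hr=1.0)) == 0


class TestOnsetOrder:
    def test_identical_series_give_zero_delta(self, unit_reference):
        t = np.arange(0, 10.5, 0.5)
        series = np.linspace(1, 0, len(t))
        tr = normalize_traces([make_trace(t, series, green=series)], unit_reference)
        out = onset_order(tr)
        assert out["median_delta_t_hr"] == 0.0

    def test_constructed_two_hour_lag(self, unit_reference):
        t = np.arange(0, 20.5, 0.5)
        green = np.where(t >= 4, 0.0, 1.0)
        orange = np.where(t >= 6, 0.0, 1.0)
        tr = normalize_traces([make_trace(t, orange, green=green)], unit_reference)
        out = onset_order(tr)
        assert out["median_delta_t_hr"] == pytest.approx(2.0)

    def test_never_crossing_cells_are_censored(self, unit_reference):
        t = np.arange(0, 10.5, 0.5)
        tr = normalize_traces(
            [make_trace(t, np.ones_like(t), green=np.linspace(1, 0, len(t)))],
            unit_reference,
        )
        out = onset_order(tr)
        assert out["n_censored"] == 1
        assert len(out["delta_t_hr"]) == 0

    def test_establishment_cohort_green_anticipates_orange(self):
        """Starting fully de-repressed, proximal (green) repression precedes
        distal (orange) repression in the ectopic spreading model."""
        traces = simulate.simulate_traces(
            "ectopic_dh_3kb", 150, 60.0, 0.5, substream(23, "est"), start="derepressed"
        )
        clr4 = simulate.simulate_traces("clr4_null", 20, 60.0, 0.5, substream(23, "c"),
                                        early_death_fraction=0.0)
        cohort = normalize_traces(traces, clr4, background=20.0)
        out = onset_order(cohort)
        assert out["median_delta_t_hr"] > 0
        assert out["sign_test_p"] < 0.01


class TestHeatmap:
    def test_constant_trace_fills_matrix(self, unit_reference):
        t = np.arange(0, 36.5, 0.5)
        tr = normalize_traces([make_trace(t, np.full_like(t, 0.5))], unit_reference)
        mat, grid = trace_heatmap(tr, t_max_hr=36.0)
        assert mat.shape == (1, 73)
        assert np.allclose(mat, 0.5)

    def test_values_above_one_clipped(self, unit_reference):
        t = np.arange(0, 36.5, 0.5)
        tr = normalize_traces([make_trace(t, np.full_like(t, 1.7))], unit_reference)
        mat, _ = trace_heatmap(tr)
        assert np.nanmax(mat) == 1.0

    def test_cohort_matrix_shape(self):
        traces = simulate.simulate_traces("dREIII", 30, 60.0, 0.5, substream(25, "hm"))
        clr4 = simulate.simulate_traces("clr4_null", 10, 60.0, 0.5, substream(25, "c"),
                                        early_death_fraction=0.0)
        cohort = normalize_traces(traces, clr4, background=20.0)
        mat, grid = trace_heatmap(cohort, t_max_hr=36.0)
        assert mat.shape == (30, int(36.0 / 0.5) + 1)
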