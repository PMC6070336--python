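"""Multigenerational single-cell trace analytics.

Per-cell time series from microfluidic trapping are background-subtracted,
red-ratio normalized, and scaled to the Δclr4-derived maximum so that full
de-repression sits at 1. Cohort statistics follow the conventions of the
max-value scatter analysis: cells that died or were ejected before 12 hr are
excluded; cells must maintain nucleation (green below the clamp threshold at
every observed timepoint) to enter spreading statistics; crossing fractions
are reported against the half-maximal (0.5) line and against an ON cutoff
derived as mean − 3 SD of a matched Δclr4 cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CellTrace

__all__ = [
    "NormalizedTrace",
    "DerepressionEvent",
    "TraceNormalizer",
    "normalize_traces",
    "clr4_trace_scale",
    "filter_cells",
    "crossing_fractions",
    "detect_events",
    "onset_order",
    "trace_heatmap",
]


@dataclass
class NormalizedTrace:
    """One cell's normalized (Δclr4-max-scaled) green/orange time series."""

    cell_id: str
    times_hr: np.ndarray
    green_norm: np.ma.MaskedArray
    orange_norm: np.ma.MaskedArray
    maintained_nucleation: bool = True
    exclusion_reason: str | None = None

    @property
    def max_green(self) -> float:
        return float(self.green_norm.max())

    @property
    def max_orange(self) -> float:
        return float(self.orange_norm.max())


@dataclass(frozen=True)
class DerepressionEvent:
    start_hr: float
    end_hr: float
    peak_value: float
    transient: bool

    def __post_init__(self) -> None:
        if not self.start_hr < self.end_hr:
            raise ValueError("event must have start < end")


def _ratio(channel: np.ndarray, red: np.ndarray, background: float | np.ndarray) -> np.ma.MaskedArray:
    sig = np.maximum(np.asarray(channel, dtype=float) - background, 0.0)
    red_sig = np.asarray(red, dtype=float) - background
    masked = red_sig <= 0
    red_safe = np.where(masked, 1.0, red_sig)
    return np.ma.masked_array(sig / red_safe, mask=masked)


def clr4_trace_scale(
    clr4_traces: list[CellTrace], background: float = 0.0
) -> dict[str, float]:
    """Δclr4-derived maxima: the mean background-subtracted ratio per channel.

    Pools every timepoint of the Δclr4 cohort; the resulting scale maps fully
    de-repressed signal to ≈ 1.
    """
    g, o = [], []
    for tr in clr4_traces:
        g.append(_ratio(tr.green_raw, tr.red_raw, background).compressed())
        o.append(_ratio(tr.orange_raw, tr.red_raw, background).compressed())
    g_all, o_all = np.concatenate(g), np.concatenate(o)
    if len(g_all) == 0:
        raise ValueError("empty Δclr4 trace reference")
    scale = {"green": float(g_all.mean()), "orange": float(o_all.mean())}
    if scale["green"] <= 0 or scale["orange"] <= 0:
        raise ValueError("non-positive Δclr4 trace maxima")
    return scale


class TraceNormalizer:
    """Normalize raw traces: subtract background, ratio to red, scale to Δclr4.

    The estimator-style surface mirrors the snapshot normalizer: ``fit`` on
    the Δclr4 trace cohort learns the per-channel maxima (``scale_``);
    ``transform`` maps raw traces to :class:`NormalizedTrace`. Timepoints
    where the background-subtracted red signal is non-positive are masked,
    not dropped.
    """

    def __init__(self, background: float = 0.0):
        self.background = background

    def fit(self, clr4_traces: list[CellTrace]):
        self.scale_ = clr4_trace_scale(clr4_traces, background=self.background)
        return self

    def transform(self, traces: list[CellTrace]) -> list[NormalizedTrace]:
        out = []
        for tr in traces:
            g = _ratio(tr.green_raw, tr.red_raw, self.background) / self.scale_["green"]
            o = _ratio(tr.orange_raw, tr.red_raw, self.background) / self.scale_["orange"]
            reason = "died_or_ejected_before_12h" if tr.died_or_ejected_before_12h else None
            out.append(
                NormalizedTrace(
                    cell_id=tr.cell_id,
                    times_hr=np.asarray(tr.times_hr, dtype=float),
                    green_norm=g,
                    orange_norm=o,
                    exclusion_reason=reason,
                )
            )
        return out


def normalize_traces(
    traces: list[CellTrace],
    clr4_trace_reference: list[CellTrace],
    background: float = 0.0,
) -> list[NormalizedTrace]:
    """Background-subtract, red-ratio, and Δclr4-max scale a trace cohort."""
    return TraceNormalizer(background=background).fit(clr4_trace_reference).transform(traces)


def filter_cells(
    traces: list[NormalizedTrace], clamp_threshold: float
) -> list[NormalizedTrace]:
    """Retain analyzable cells and mark maintained nucleation.

    Drops cells flagged as dying/ejected before 12 hr. A cell maintains
    nucleation when its normalized green stays below ``clamp_threshold`` at
    every observed (unmasked) timepoint; only maintained cells enter the
    spreading statistics.
    """
    retained = []
    for tr in traces:
        if tr.exclusion_reason is not None:
            continue
        tr.maintained_nucleation = bool(np.all(tr.green_norm.compressed() < clamp_threshold))
        retained.append(tr)
    return retained


def crossing_fractions(
    traces: list[NormalizedTrace],
    half_level: float = 0.5,
    on_cutoff: float | None = None,
    maintained_only: bool = True,
) -> dict:
    """Fractions of cells whose max orange crosses the half-maximal / ON lines.

    Also returns the (max_green, max_orange) point set for scatter export.
    """
    cohort = [t for t in traces if t.maintained_nucleation] if maintained_only else list(traces)
    if not cohort:
        raise ValueError("empty trace cohort")
    max_o = np.array([t.max_orange for t in cohort])
    max_g = np.array([t.max_green for t in cohort])
    out = {
        "n_cells": len(cohort),
        "fraction_half_maximal": float(np.mean(max_o >= half_level)),
        "max_points": pd.DataFrame(
            {"cell_id": [t.cell_id for t in cohort], "max_green": max_g, "max_orange": max_o}
        ),
    }
    if on_cutoff is not None:
        out["fraction_on"] = float(np.mean(max_o >= on_cutoff))
    return out


def detect_events(
    trace: NormalizedTrace,
    threshold: float = 0.5,
    min_duration_hr: float = 0.0,
) -> list[DerepressionEvent]:
    """Maximal runs of orange de-repression at or above ``threshold``.

    A run lasting at least ``min_duration_hr`` (default: a single sample)
    becomes an event; it is *transient* if it ends before the trace does.
    Masked timepoints (focus loss) are ignored.
    """
    t = trace.times_hr
    o = trace.orange_norm
    valid = ~np.ma.getmaskarray(o)
    above = np.asarray(o.filled(-np.inf) >= threshold) & valid
    events: list[DerepressionEvent] = []
    i, n = 0, len(t)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            duration = t[j] - t[i]
            if duration >= min_duration_hr or (min_duration_hr <= 0 and j >= i):
                # last valid sample index overall
                last_valid = np.flatnonzero(valid)[-1]
                events.append(
                    DerepressionEvent(
                        start_hr=float(t[i]),
                        end_hr=float(t[j]) if j > i else float(t[i]) + 1e-9,
                        peak_value=float(o[i : j + 1].max()),
                        transient=j < last_valid,
                    )
                )
            i = j + 1
        else:
            i += 1
    return events


def onset_order(
    traces: list[NormalizedTrace], half_repression_level: float = 0.5
) -> dict:
    """Per-cell repression-onset delay between the proximal and distal reporter.

    For each cell starting de-repressed in both channels, finds the first
    time each channel falls to ``half_repression_level`` or below; reports
    Δt = t_orange − t_green per cell, the cohort median, and a sign test
    against Δt = 0. Cells never reaching the level in one of the channels are
    censored (counted, excluded from Δt). A positive median means proximal
    ("green") repression anticipates distal ("orange") repression.
    """
    deltas, censored = [], 0
    for tr in traces:
        def first_crossing(series):
            vals = series.filled(np.inf)
            idx = np.flatnonzero(vals <= half_repression_level)
            return tr.times_hr[idx[0]] if len(idx) else None

        tg, to = first_crossing(tr.green_norm), first_crossing(tr.orange_norm)
        if tg is None or to is None:
            censored += 1
            continue
        deltas.append(float(to - tg))
    deltas = np.asarray(deltas)
    result = {"delta_t_hr": deltas, "n_censored": censored, "n_cells": len(traces)}
    if len(deltas):
        result["median_delta_t_hr"] = float(np.median(deltas))
        nonzero = deltas[deltas != 0]
        if len(nonzero):
            k = int(np.sum(nonzero > 0))
            result["sign_test_p"] = float(stats.binomtest(k, len(nonzero), 0.5).pvalue)
        else:
            result["sign_test_p"] = 1.0
    return result


def trace_heatmap(
    traces: list[NormalizedTrace],
    t_max_hr: float = 36.0,
    sample_interval_hr: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cells × timepoints matrix of orange_norm clipped to [0, 1].

    Traces are aligned to a common grid by nearest-sample lookup (no
    interpolation, so no manufactured intermediate values); masked or
    missing samples become NaN. Returns ``(matrix, grid_times_hr)``.
    """
    if not traces:
        raise ValueError("need at least one trace")
    if sample_interval_hr is None:
        diffs = np.diff(traces[0].times_hr)
        sample_interval_hr = float(np.min(diffs)) if len(diffs) else 1.0
    grid = np.arange(0.0, t_max_hr + 1e-9, sample_interval_hr)
    mat = np.full((len(traces), len(grid)), np.nan)
    for i, tr in enumerate(traces):
        idx = np.abs(tr.times_hr[None, :] - grid[:, None]).argmin(axis=1)
        near = np.abs(tr.times_hr[idx] - grid) <= sample_interval_hr / 2 + 1e-9
        vals = np.clip(tr.orange_norm.astype(float).filled(np.nan), 0.0, 1.0)
        mat[i, near] = vals[idx[near]]
    return mat, grid
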