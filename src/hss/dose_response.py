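"""Memory and resistance quantification from TSA dose-response experiments.

A dose-response experiment measures, for each concentration of the HDAC
inhibitor trichostatin A (TSA), the fraction of nucleated (green-OFF) cells
that fully silence the distal "orange" reporter, for two ancestries: cells
whose heterochromatin was erased by TSA pretreatment, and untreated cells.
Curves are normalized to the untreated 0 µM point; *half-resistance* is the
concentration at which the normalized untreated curve declines to 0.5, read
off by monotone log-linear interpolation (with a 4-parameter log-logistic
fit as fallback); *memory* is the separation between the two ancestry
curves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseCurve",
    "MemoryResistanceResult",
    "normalize_curve",
    "half_resistance",
    "memory_score",
    "analyze_experiment",
]


@dataclass(frozen=True)
class DoseResponseCurve:
    """Per-concentration orange-OFF counts for one ancestral condition."""

    conc_uM: np.ndarray
    n_total: np.ndarray
    n_orange_off: np.ndarray
    n_green_off: np.ndarray | None = None
    ancestry: str = "untreated"
    condition: str = ""
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.conc_uM, dtype=float)
        if len(conc) != len(self.n_total) or len(conc) != len(self.n_orange_off):
            raise ValueError("curve arrays must share length")
        if len(conc) > 1 and not np.all(np.diff(conc) > 0):
            raise ValueError("conc_uM must be strictly increasing")
        if np.any(np.asarray(self.n_orange_off) > np.asarray(self.n_total)):
            raise ValueError("successes exceed totals")

    @property
    def frac_orange_off(self) -> np.ndarray:
        return np.asarray(self.n_orange_off, dtype=float) / np.asarray(self.n_total, dtype=float)


@dataclass(frozen=True)
class MemoryResistanceResult:
    half_resistance_uM: float
    memory_score: float
    convergence_conc_uM: float | None
    half_resistance_extrapolated: bool = False
    per_concentration_difference: np.ndarray | None = None


def normalize_curve(curve: DoseResponseCurve, anchor: float | None = None) -> DoseResponseCurve:
    """Normalize a curve to the (untreated-ancestry) 0 µM anchor fraction.

    ``anchor`` overrides the anchor fraction; by default the curve's own
    0 µM point is used, which is correct for untreated-ancestry curves. For
    pretreated curves pass the matched untreated curve's 0 µM fraction.
    """
    frac = curve.frac_orange_off
    if anchor is None:
        at_zero = np.flatnonzero(curve.conc_uM == 0.0)
        if len(at_zero) == 0:
            raise ValueError("curve has no 0 µM point; pass anchor= explicitly")
        anchor = float(frac[at_zero[0]])
    if anchor <= 0:
        raise ValueError(
            "zero anchor fraction: no orange-OFF cells at 0 µM; "
            "normalize against the matched untreated curve's anchor instead"
        )
    return replace(curve, normalized=frac / anchor)


def _pseudo_log_conc(conc: np.ndarray) -> np.ndarray:
    """Concentrations for log-axis work; 0 is floored at half the smallest nonzero."""
    conc = np.asarray(conc, dtype=float)
    nonzero = conc[conc > 0]
    if len(nonzero) == 0:
        raise ValueError("curve has no nonzero concentrations")
    floor = nonzero.min() / 2.0
    return np.where(conc > 0, conc, floor)


def _loglogistic(c, lower, upper, log_mid, hill):
    return lower + (upper - lower) / (1.0 + np.exp(hill * (np.log(c) - log_mid)))


def half_resistance(
    curve: DoseResponseCurve,
    level: float = 0.5,
    method: str = "interpolate",
) -> tuple[float, bool]:
    """Concentration at which the normalized curve declines to ``level``.

    Primary method: monotone log-linear interpolation between the two
    measured concentrations bracketing the level (the curve is first made
    non-increasing by a running minimum to suppress count noise). Fallback
    ``method='fit'``: 4-parameter log-logistic least squares, solved for the
    level. Returns ``(concentration_uM, extrapolated)``; if the curve never
    crosses the level, the largest measured concentration is returned with
    ``extrapolated=True``.
    """
    if curve.normalized is None:
        curve = normalize_curve(curve)
    y = np.asarray(curve.normalized, dtype=float)
    c = _pseudo_log_conc(curve.conc_uM)
    logc = np.log10(c)

    if method == "fit":
        p0 = (float(y.min()), float(y.max()), float(np.log(np.median(c))), 1.5)
        bounds = ([-0.5, 0.5, np.log(c.min()) - 3, 0.1], [0.5, 2.0, np.log(c.max()) + 3, 10.0])
        popt, _ = curve_fit(_loglogistic, c, y, p0=p0, bounds=bounds, maxfev=20000)
        lower, upper, log_mid, hill = popt
        if not (min(lower, upper) < level < max(lower, upper)):
            return float(curve.conc_uM.max()), True
        inner = (upper - lower) / (level - lower) - 1.0
        if inner <= 0:
            return float(curve.conc_uM.max()), True
        return float(np.exp(log_mid + np.log(inner) / hill)), False
    if method != "interpolate":
        raise ValueError(f"unknown method {method!r}")

    y_mono = np.minimum.accumulate(y)  # enforce non-increasing
    below = np.flatnonzero(y_mono <= level)
    if len(below) == 0:
        return float(curve.conc_uM.max()), True
    j = below[0]
    if j == 0 or y_mono[j] == level:
        return float(curve.conc_uM[j]), j == 0 and y_mono[j] > level
    y0, y1 = y_mono[j - 1], y_mono[j]
    t = (y0 - level) / (y0 - y1)
    return float(10 ** (logc[j - 1] + t * (logc[j] - logc[j - 1]))), False


def memory_score(
    pretreated: DoseResponseCurve,
    untreated: DoseResponseCurve,
    epsilon: float = 0.05,
) -> tuple[float, float | None, np.ndarray]:
    """Mean normalized separation (untreated − pretreated) across the gradient.

    Returns ``(score, convergence_conc_uM, per_concentration_differences)``
    where convergence is the smallest concentration beyond which every
    difference stays below ``epsilon`` (None if the curves never converge).
    """
    if not np.array_equal(pretreated.conc_uM, untreated.conc_uM):
        raise ValueError("curves must share the concentration grid")
    u = untreated.normalized if untreated.normalized is not None else normalize_curve(untreated).normalized
    if pretreated.normalized is not None:
        p = pretreated.normalized
    else:
        anchor_frac = untreated.frac_orange_off[np.flatnonzero(untreated.conc_uM == 0.0)[0]]
        p = normalize_curve(pretreated, anchor=float(anchor_frac)).normalized
    diff = np.asarray(u) - np.asarray(p)
    score = float(np.mean(diff))
    conv = None
    small = np.abs(diff) < epsilon
    for i in range(len(diff)):
        if small[i:].all():
            conv = float(untreated.conc_uM[i])
            break
    return score, conv, diff


def analyze_experiment(
    pretreated: DoseResponseCurve,
    untreated: DoseResponseCurve,
    epsilon: float = 0.05,
) -> MemoryResistanceResult:
    """Full memory/resistance readout for one experiment (both ancestries)."""
    untreated_n = normalize_curve(untreated)
    anchor = float(untreated.frac_orange_off[np.flatnonzero(untreated.conc_uM == 0.0)[0]])
    pretreated_n = normalize_curve(pretreated, anchor=anchor)
    hr, extrap = half_resistance(untreated_n)
    score, conv, diff = memory_score(pretreated_n, untreated_n, epsilon=epsilon)
    return MemoryResistanceResult(
        half_resistance_uM=hr,
        memory_score=score,
        convergence_conc_uM=conv,
        half_resistance_extrapolated=extrap,
        per_concentration_difference=diff,
    )
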