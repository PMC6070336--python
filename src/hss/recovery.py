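"""Heat-stress recovery kinetics: 32°C normalization, sigmoid fit, t1/2.

After transient growth at 38°C, the fraction of cells with full spreading
recovers over ~96 hr at 32°C. Each strain's 38°C arm is normalized to its
32°C control arm per timepoint; a 4-parameter logistic in time

    y(t) = L + (U - L) / (1 + exp(-k (t - m)))

is fit by least squares with multi-start initialization, and t1/2 is the
time at which the fitted curve reaches absolute 0.5 on the normalized scale
(the inflection point m is also reported). Δt1/2 between strains is reported
in hours and generations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "RecoveryFit",
    "LogisticRecoveryModel",
    "normalize_recovery",
    "fit_recovery",
    "delta_t_half",
]


@dataclass(frozen=True)
class RecoveryFit:
    t_half_hr: float
    lower_asymptote: float
    upper_asymptote: float
    slope_param: float
    midpoint_hr: float
    rss: float
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if self.lower_asymptote > self.upper_asymptote:
            raise ValueError("lower asymptote exceeds upper")


def _logistic4(t, lower, upper, slope, midpoint):
    return lower + (upper - lower) / (1.0 + np.exp(-slope * (t - midpoint)))


class LogisticRecoveryModel(BaseEstimator, RegressorMixin):
    """4-parameter logistic-in-time recovery model.

    ``fit(t, y)`` estimates (L, U, k, m) by least squares from ``n_starts``
    quantile-derived initializations with small fixed-seed jitter, keeping
    the best-RSS convergent solution. Fitted attributes: ``params_``,
    ``t_half_hr_`` (time where the curve reaches ``level`` absolute, flagged
    ``t_half_extrapolated_`` when outside the data span), ``rss_``.
    """

    def __init__(self, level: float = 0.5, n_starts: int = 5, jitter_seed: int = 0):
        self.level = level
        self.n_starts = n_starts
        self.jitter_seed = jitter_seed

    def fit(self, t, y):
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        ok = np.isfinite(t) & np.isfinite(y)
        t, y = t[ok], y[ok]
        if len(t) < 4:
            raise ValueError("need at least 4 timepoints to fit a 4PL curve")
        order = np.argsort(t)
        t, y = t[order], y[order]
        span = float(np.ptp(y))
        if span < 1e-3:
            raise ValueError("no transition: response is flat")

        rng = np.random.default_rng(self.jitter_seed)
        t_span = max(float(np.ptp(t)), 1e-9)
        q25, q75 = np.quantile(t, [0.25, 0.75])
        best = None
        lo = [min(y.min(), 0.0) - 0.5, y.min(), 1e-4, t.min() - 2 * t_span]
        hi = [y.max(), max(y.max(), 1.0) + 0.5, 10.0 / t_span * 4, t.max() + 2 * t_span]
        starts = [
            (y.min(), y.max(), 4.0 / t_span, float(np.median(t))),
            (y.min(), y.max(), 8.0 / t_span, float(q25)),
            (y.min(), y.max(), 8.0 / t_span, float(q75)),
            (y.min(), y.max(), 2.0 / t_span, float(np.median(t))),
            (0.0, 1.0, 4.0 / t_span, float(np.median(t))),
        ][: self.n_starts]
        diagnostics = []
        for p0 in starts:
            p0 = np.clip(
                np.asarray(p0) * (1.0 + 0.02 * rng.standard_normal(4)), lo, hi
            )
            try:
                popt, _ = curve_fit(
                    _logistic4, t, y, p0=p0, bounds=(lo, hi), maxfev=20000
                )
            except RuntimeError as exc:  # non-convergence for this start
                diagnostics.append(str(exc))
                continue
            rss = float(np.sum((y - _logistic4(t, *popt)) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
        if best is None:
            raise RuntimeError(
                "4PL fit failed to converge from all starts: " + "; ".join(diagnostics)
            )
        popt, rss = best
        lower, upper, slope, midpoint = (float(v) for v in popt)
        self.params_ = {"lower": lower, "upper": upper, "slope": slope, "midpoint": midpoint}
        self.rss_ = rss

        level = self.level
        if lower < level < upper:
            t_half = midpoint - np.log((upper - lower) / (level - lower) - 1.0) / slope
            extrapolated = not (t.min() <= t_half <= t.max())
        else:
            t_half = t.min() if lower >= level else t.max()
            extrapolated = True
        self.t_half_hr_ = float(t_half)
        self.t_half_extrapolated_ = bool(extrapolated)
        return self

    def predict(self, t) -> np.ndarray:
        p = self.params_
        return _logistic4(np.asarray(t, dtype=float), p["lower"], p["upper"], p["slope"], p["midpoint"])

    def result(self) -> RecoveryFit:
        p = self.params_
        return RecoveryFit(
            t_half_hr=self.t_half_hr_,
            lower_asymptote=p["lower"],
            upper_asymptote=p["upper"],
            slope_param=p["slope"],
            midpoint_hr=p["midpoint"],
            rss=self.rss_,
            extrapolated=self.t_half_extrapolated_,
        )


def normalize_recovery(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize each strain's 38°C arm to its 32°C arm, per timepoint.

    Input columns: ``strain, arm, time_hr, n_total, n_full_spreading`` with
    arms ``"32C"`` and ``"38C"``. Returns ``strain, time_hr, normalized``;
    timepoints whose 32°C fraction is zero are masked (NaN) with a warning.
    """
    required = {"strain", "arm", "time_hr", "n_total", "n_full_spreading"}
    missing = required - set(table.columns)
    if missing:
        raise KeyError(f"recovery table missing columns: {sorted(missing)}")
    out = []
    for strain, grp in table.groupby("strain", sort=False):
        frac = (
            grp.assign(frac=grp["n_full_spreading"] / grp["n_total"])
            .pivot_table(index="time_hr", columns="arm", values="frac")
        )
        if "32C" not in frac or "38C" not in frac:
            raise ValueError(f"strain {strain!r}: both 32C and 38C arms are required")
        control = frac["32C"].to_numpy()
        heat = frac["38C"].to_numpy()
        zero = control <= 0
        if zero.any():
            import warnings

            warnings.warn(f"strain {strain!r}: {int(zero.sum())} timepoints with zero 32C fraction masked")
        norm = np.where(zero, np.nan, heat / np.where(zero, 1.0, control))
        out.append(pd.DataFrame({"strain": strain, "time_hr": frac.index.to_numpy(), "normalized": norm}))
    return pd.concat(out, ignore_index=True)


def fit_recovery(times_hr, normalized_values, level: float = 0.5) -> RecoveryFit:
    """Fit the 4PL recovery curve and report t1/2 (absolute ``level`` crossing)."""
    model = LogisticRecoveryModel(level=level).fit(times_hr, normalized_values)
    return model.result()


def delta_t_half(fit_a: RecoveryFit, fit_b: RecoveryFit, doubling_time_hr: float = 2.3) -> dict:
    """Δt1/2 = t1/2(b) − t1/2(a), in hours and generations."""
    delta = fit_b.t_half_hr - fit_a.t_half_hr
    return {
        "delta_t_half_hr": float(delta),
        "delta_generations": float(delta / doubling_time_hr),
        "extrapolated": bool(fit_a.extrapolated or fit_b.extrapolated),
    }
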