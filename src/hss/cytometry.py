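"""Gating, normalization, nucleation clamp, and repression-state classification.

Flow-cytometry-style analysis of population snapshots. The stages compose as
scikit-learn estimators:

* :class:`SizeGate` — rectangular percentile window on (FSC, SSC), selecting
  small, recently divided cells.
* :class:`RedRatioNormalizer` — divides the heterochromatic "green" and
  "orange" channels by the euchromatic "red" noise filter and scales so that
  the matched Δclr4 (no heterochromatin) population is centered at 1.
* :class:`NucleationClamp` — retains cells whose green signal is below the
  median + 2 SD of a no-XFP control, i.e. cells that successfully nucleated.
* :class:`StateClassifier` — OFF / INTERMEDIATE / ON calls per channel, with
  the OFF bound from the unstained control and the ON bound at
  mean − 3 SD of the matched Δclr4 normalized values.

Module-level functions wrap the estimators under the pipeline's operation
names.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "SizeGate",
    "RedRatioNormalizer",
    "NucleationClamp",
    "StateClassifier",
    "apply_size_gate",
    "normalize",
    "clamp_threshold",
    "classify_state",
    "population_summary",
    "distance_decline_fit",
    "hexbin_density",
]

STATES = ("OFF", "INTERMEDIATE", "ON")


def _require_columns(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"snapshots table missing columns: {missing}")


class SizeGate(BaseEstimator, TransformerMixin):
    """Rectangular percentile gate on forward/side scatter.

    ``fit`` learns the percentile box bounds from a reference population
    (typically the sample itself); ``transform`` adds a ``passes_size_gate``
    flag. The default 5th–35th percentile window targets small, recently
    divided cells.
    """

    def __init__(self, lo_pct: float = 5.0, hi_pct: float = 35.0, channels=("fsc", "ssc")):
        self.lo_pct = lo_pct
        self.hi_pct = hi_pct
        self.channels = channels

    def fit(self, X: pd.DataFrame, y=None):
        if not 0 <= self.lo_pct < self.hi_pct <= 100:
            raise ValueError("need 0 <= lo_pct < hi_pct <= 100")
        _require_columns(X, self.channels)
        self.bounds_ = {
            ch: (
                float(np.percentile(X[ch], self.lo_pct)),
                float(np.percentile(X[ch], self.hi_pct)),
            )
            for ch in self.channels
        }
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        mask = np.ones(len(X), dtype=bool)
        for ch, (lo, hi) in self.bounds_.items():
            mask &= (X[ch].to_numpy() >= lo) & (X[ch].to_numpy() <= hi)
        out = X.copy()
        out["passes_size_gate"] = mask
        if len(out) and not mask.any():
            warnings.warn("size gate retained no cells", stacklevel=2)
        return out


class RedRatioNormalizer(BaseEstimator, TransformerMixin):
    """Red-ratio normalization scaled to the Δclr4 (fully de-repressed) state.

    ``fit`` takes the matched Δclr4 reference snapshots and stores the median
    green/red and orange/red ratios; ``transform`` computes
    ``green_norm = (green_raw/red_raw) / median_ratio`` (likewise orange), so
    the Δclr4 population is centered at 1. Cells with ``red_raw <= 0`` are
    dropped and counted in the log.
    """

    def __init__(self, center: str = "median"):
        self.center = center

    def fit(self, X: pd.DataFrame, y=None):
        _require_columns(X, ("green_raw", "orange_raw", "red_raw"))
        ref = X[X["red_raw"] > 0]
        if len(ref) == 0:
            raise ValueError("empty Δclr4 reference after excluding red_raw <= 0")
        agg = np.median if self.center == "median" else np.mean
        self.green_ratio_center_ = float(agg(ref["green_raw"] / ref["red_raw"]))
        self.orange_ratio_center_ = float(agg(ref["orange_raw"] / ref["red_raw"]))
        if self.green_ratio_center_ <= 0 or self.orange_ratio_center_ <= 0:
            raise ValueError("non-positive reference ratio center")
        # normalized-scale reference statistics (feed the ON cutoff)
        gn = (ref["green_raw"] / ref["red_raw"]) / self.green_ratio_center_
        on = (ref["orange_raw"] / ref["red_raw"]) / self.orange_ratio_center_
        self.clr4_norm_mean_ = {"green": float(gn.mean()), "orange": float(on.mean())}
        self.clr4_norm_sd_ = {"green": float(gn.std(ddof=1)), "orange": float(on.std(ddof=1))}
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        _require_columns(X, ("green_raw", "orange_raw", "red_raw"))
        ok = X["red_raw"].to_numpy() > 0
        n_dropped = int((~ok).sum())
        if n_dropped:
            logger.info("normalize: excluded %d cells with red_raw <= 0", n_dropped)
        out = X.loc[ok].copy()
        out["green_norm"] = (out["green_raw"] / out["red_raw"]) / self.green_ratio_center_
        out["orange_norm"] = (out["orange_raw"] / out["red_raw"]) / self.orange_ratio_center_
        return out


class NucleationClamp(BaseEstimator, TransformerMixin):
    """Computational nucleation clamp on the raw green (nucleation) channel.

    ``fit`` takes green values from a matched no-XFP control and stores
    ``threshold_ = median + 2 * sample SD``; ``transform`` flags cells with
    green below the threshold as nucleated ("green-OFF", ``passes_clamp``).
    """

    def __init__(self, n_sd: float = 2.0, channel: str = "green_raw"):
        self.n_sd = n_sd
        self.channel = channel

    def fit(self, X, y=None):
        values = np.asarray(X[self.channel] if isinstance(X, pd.DataFrame) else X, dtype=float)
        if values.ndim == 2 and values.shape[1] == 1:
            values = values[:, 0]
        if values.size < 2:
            raise ValueError("clamp threshold needs at least 2 control values")
        self.noxfp_median_ = float(np.median(values))
        self.noxfp_sd_ = float(np.std(values, ddof=1))
        self.threshold_ = self.noxfp_median_ + self.n_sd * self.noxfp_sd_
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        out["passes_clamp"] = out[self.channel].to_numpy() < self.threshold_
        return out

    def predict(self, X) -> np.ndarray:
        values = np.asarray(X[self.channel] if isinstance(X, pd.DataFrame) else X, dtype=float)
        return values < self.threshold_


class StateClassifier(BaseEstimator):
    """Three-state OFF / INTERMEDIATE / ON classifier for normalized signal.

    The OFF bound (``unstained_upper``) encompasses signal overlapping an
    unstained (no-XFP) control; the ON bound (``on_lower``) defaults to
    mean − 3 SD of the matched Δclr4 normalized values. When both bounds are
    data-derived, a guard gap of 2% of the full range is enforced between
    them.
    """

    def __init__(
        self,
        unstained_upper: float | None = None,
        on_lower: float | None = None,
        gap_fraction: float = 0.02,
        full_range: float = 1.5,
    ):
        self.unstained_upper = unstained_upper
        self.on_lower = on_lower
        self.gap_fraction = gap_fraction
        self.full_range = full_range

    def fit(self, unstained_values=None, clr4_values=None):
        """Derive bounds from control samples (either may be pre-set)."""
        if self.unstained_upper is not None:
            self.unstained_upper_ = float(self.unstained_upper)
        else:
            if unstained_values is None:
                raise ValueError("need unstained_values or an explicit unstained_upper")
            v = np.asarray(unstained_values, dtype=float)
            self.unstained_upper_ = float(np.median(v) + 2.0 * np.std(v, ddof=1))
        if self.on_lower is not None:
            self.on_lower_ = float(self.on_lower)
        else:
            if clr4_values is None:
                raise ValueError("need clr4_values or an explicit on_lower")
            v = np.asarray(clr4_values, dtype=float)
            self.on_lower_ = float(np.mean(v) - 3.0 * np.std(v, ddof=1))
        if self.unstained_upper is None and self.on_lower is None:
            gap = self.gap_fraction * self.full_range
            if self.on_lower_ - self.unstained_upper_ < gap:
                mid = 0.5 * (self.on_lower_ + self.unstained_upper_)
                self.unstained_upper_ = mid - gap / 2.0
                self.on_lower_ = mid + gap / 2.0
        if self.unstained_upper_ >= self.on_lower_:
            raise ValueError(
                f"inverted state bounds: unstained_upper={self.unstained_upper_:.4g} "
                f">= on_lower={self.on_lower_:.4g}"
            )
        return self

    def predict(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        out = np.full(values.shape, "INTERMEDIATE", dtype=object)
        out[values <= self.unstained_upper_] = "OFF"
        out[values >= self.on_lower_] = "ON"
        return out


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def apply_size_gate(snapshots: pd.DataFrame, lo_pct: float = 5.0, hi_pct: float = 35.0,
                    reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Flag cells inside a rectangular FSC/SSC percentile window."""
    gate = SizeGate(lo_pct=lo_pct, hi_pct=hi_pct)
    gate.fit(reference if reference is not None else snapshots)
    return gate.transform(snapshots)


def normalize(snapshots: pd.DataFrame, clr4_reference: pd.DataFrame) -> pd.DataFrame:
    """Red-ratio normalize against a Δclr4 reference (Δclr4 centered at 1)."""
    return RedRatioNormalizer().fit(clr4_reference).transform(snapshots)


def clamp_threshold(noxfp_green_values, n_sd: float = 2.0) -> float:
    """Nucleation-clamp threshold: median + ``n_sd`` · sample SD of no-XFP green."""
    clamp = NucleationClamp(n_sd=n_sd)
    clamp.fit(np.asarray(noxfp_green_values, dtype=float))
    return clamp.threshold_


def classify_state(values, unstained_upper: float, on_lower: float) -> np.ndarray:
    """OFF / INTERMEDIATE / ON calls for normalized values with fixed bounds."""
    clf = StateClassifier(unstained_upper=unstained_upper, on_lower=on_lower).fit()
    result = clf.predict(np.atleast_1d(values))
    return result if np.ndim(values) else result[0]


def unstained_upper_from_controls(
    noxfp_orange_raw,
    clr4_red_raw,
    orange_ratio_center: float,
    q_bg: float = 99.5,
    q_red: float = 10.0,
) -> float:
    """OFF bound on the normalized scale, derived from the unstained control.

    Converts an upper quantile of the no-XFP orange autofluorescence into
    normalized units by dividing by a low quantile of the reference red
    signal (so the bound remains generous for dim cells) and the Δclr4
    orange/red ratio center.
    """
    bg_upper = float(np.percentile(np.asarray(noxfp_orange_raw, dtype=float), q_bg))
    red_low = float(np.percentile(np.asarray(clr4_red_raw, dtype=float), q_red))
    if red_low <= 0 or orange_ratio_center <= 0:
        raise ValueError("reference red and ratio center must be positive")
    return bg_upper / red_low / orange_ratio_center


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def hexbin_density(
    x, y, gridsize: int = 30, extent: tuple[float, float, float, float] = (0.0, 1.5, 0.0, 1.5)
) -> np.ndarray:
    """Counts on a fixed hexagonal lattice over the (x, y) plane.

    Pointy-top hexagonal binning on a ``gridsize`` × ``gridsize`` offset
    lattice spanning ``extent`` (points outside are clipped to the border
    bins). Returns an integer matrix (rows = y index, cols = x index) whose
    total equals the number of input points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x0, x1, y0, y1 = extent
    nx = ny = gridsize
    dx = (x1 - x0) / nx
    dy = (y1 - y0) / ny
    px = np.clip((x - x0) / dx, 0, nx - 1e-9)
    py = np.clip((y - y0) / dy, 0, ny - 1e-9)
    # candidate A: centers at integer lattice; candidate B: offset by half-cell
    ix_a = np.clip(np.round(px).astype(int), 0, nx - 1)
    iy_a = np.clip(np.round(py).astype(int), 0, ny - 1)
    ix_b = np.clip(np.floor(px).astype(int), 0, nx - 1)
    iy_b = np.clip(np.floor(py).astype(int), 0, ny - 1)
    d_a = (px - ix_a) ** 2 + 3.0 * (py - iy_a) ** 2
    d_b = (px - (ix_b + 0.5)) ** 2 + 3.0 * (py - (iy_b + 0.5)) ** 2
    use_a = d_a <= d_b
    grid = np.zeros((ny, nx), dtype=int)
    np.add.at(grid, (iy_a[use_a], ix_a[use_a]), 1)
    np.add.at(grid, (iy_b[~use_a], ix_b[~use_a]), 1)
    return grid


def population_summary(
    normalized: pd.DataFrame,
    classifier: StateClassifier,
    histogram_bins: int = 50,
    gridsize: int = 30,
) -> dict:
    """Population-level readout of a normalized, clamped snapshot table.

    Reports, among clamped (green-OFF) cells, the fraction in each orange
    state; a histogram of orange_norm among green-OFF cells; and a hexagonal
    density matrix over (green_norm, orange_norm) for all cells.
    """
    _require_columns(normalized, ("green_norm", "orange_norm"))
    clamped = normalized[normalized["passes_clamp"]] if "passes_clamp" in normalized else normalized
    if len(clamped) == 0:
        raise ValueError("no clamped cells to summarize")
    states = classifier.predict(clamped["orange_norm"].to_numpy())
    fractions = {st: float(np.mean(states == st)) for st in STATES}
    hist, edges = np.histogram(
        np.clip(clamped["orange_norm"].to_numpy(), 0, 1.5), bins=histogram_bins, range=(0, 1.5)
    )
    density = hexbin_density(
        normalized["green_norm"].to_numpy(), normalized["orange_norm"].to_numpy(), gridsize=gridsize
    )
    return {
        "n_cells": int(len(normalized)),
        "n_clamped": int(len(clamped)),
        "orange_state_fractions": fractions,
        "orange_histogram": hist,
        "orange_histogram_edges": edges,
        "density_matrix": density,
    }


def distance_decline_fit(distances_kb, fractions) -> tuple[float, float, float]:
    """OLS line of fully-repressed fraction versus reporter distance.

    Returns ``(slope, intercept, r_squared)``; the slope is expected to be
    negative for spreading that attenuates with distance.
    """
    d = np.asarray(distances_kb, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if len(np.unique(d)) < 3:
        raise ValueError("need at least 3 distinct distances")
    res = stats.linregress(d, f)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
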