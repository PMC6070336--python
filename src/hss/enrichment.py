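"""ChIP, RT-qPCR, RITE-turnover, and qPCR standard-curve arithmetic.

All quantities are ratio-scale: ChIP enrichment is IP/input scaled to 1 at a
positive-control locus (dh repeat for H3K9me2, act1 promoter for H3K4me3),
RT expression is the actin-normalized reporter quantity divided by the
Δclr4 maximum, and RITE turnover is the 4 hr / 0 hr T7 IP-over-input ratio
(1 = no replication-independent histone exchange). Technical replicates are
summarized as mean ± sample SD.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "chip_enrichment",
    "clr4_background_normalize",
    "rite_turnover",
    "rt_expression",
    "rt_expression_table",
    "standard_curve_quantify",
]

_RECORD_COLS = ("amplicon", "ip", "input")


def _ip_over_input(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _RECORD_COLS if c not in records.columns]
    if missing:
        raise KeyError(f"enrichment records missing columns: {missing}")
    bad = records["input"] <= 0
    if bad.any():
        logger.warning("rejecting %d records with non-positive input", int(bad.sum()))
    rec = records[~bad].copy()
    rec["ratio"] = rec["ip"] / rec["input"]
    return rec


def chip_enrichment(records: pd.DataFrame, positive_control_amplicon: str) -> pd.DataFrame:
    """IP/input enrichment scaled to 1 at the positive-control amplicon.

    Replicates are paired by the ``replicate`` column when present (each
    replicate normalized by its own control measurement), then summarized as
    mean ± sample SD per amplicon. Returns columns
    ``amplicon, enrichment, enrichment_sd, n_replicates``.
    """
    rec = _ip_over_input(records)
    ctrl = rec[rec["amplicon"] == positive_control_amplicon]
    if len(ctrl) == 0:
        raise ValueError(f"positive-control amplicon {positive_control_amplicon!r} not found")
    if "replicate" in rec.columns:
        ctrl_by_rep = ctrl.set_index("replicate")["ratio"]
        rec = rec[rec["replicate"].isin(ctrl_by_rep.index)].copy()
        rec["enrichment"] = rec["ratio"] / rec["replicate"].map(ctrl_by_rep)
    else:
        rec["enrichment"] = rec["ratio"] / ctrl["ratio"].mean()
    out = (
        rec.groupby("amplicon")["enrichment"]
        .agg(enrichment="mean", enrichment_sd=lambda v: v.std(ddof=1), n_replicates="count")
        .reset_index()
    )
    return out


def clr4_background_normalize(
    enrichment: pd.DataFrame, clr4_enrichment: pd.DataFrame
) -> pd.DataFrame:
    """Divide per-amplicon enrichment by a matched Δclr4 strain's enrichment.

    Amplicons absent from the background table are skipped with a warning.
    """
    bg = clr4_enrichment.set_index("amplicon")["enrichment"]
    rows = []
    for _, row in enrichment.iterrows():
        amp = row["amplicon"]
        if amp not in bg.index or bg[amp] == 0:
            logger.warning("no Δclr4 background for amplicon %r; skipped", amp)
            continue
        rows.append({"amplicon": amp, "ratio_over_clr4": row["enrichment"] / bg[amp]})
    return pd.DataFrame(rows)


def rite_turnover(records_4h: pd.DataFrame, records_0h: pd.DataFrame) -> pd.DataFrame:
    """Replication-independent turnover: (IP/input at 4 hr) / (IP/input at 0 hr).

    Ratios are formed per amplicon from replicate-mean IP/input at each
    timepoint; 1.0 means no enrichment of the new tag over the 0 hr baseline.
    """
    r4 = _ip_over_input(records_4h).groupby("amplicon")["ratio"].mean()
    r0 = _ip_over_input(records_0h).groupby("amplicon")["ratio"].mean()
    common = r4.index.intersection(r0.index)
    if len(common) == 0:
        raise ValueError("no amplicons shared between 4 hr and 0 hr records")
    missing = set(r4.index).symmetric_difference(r0.index)
    if missing:
        raise ValueError(f"amplicons missing at one timepoint: {sorted(missing)}")
    out = pd.DataFrame(
        {"amplicon": common, "turnover_ratio": (r4[common] / r0[common]).to_numpy()}
    ).reset_index(drop=True)
    return out


def rt_expression(target_qty: float, actin_qty: float, clr4_max: float) -> float:
    """Actin-normalized expression scaled to the Δclr4 maximum (Δclr4 ≡ 1)."""
    if actin_qty <= 0 or clr4_max <= 0:
        raise ValueError("actin quantity and Δclr4 maximum must be positive")
    return (target_qty / actin_qty) / clr4_max


def rt_expression_table(
    records: pd.DataFrame,
    target_amplicon: str = "mKO2",
    reference_amplicon: str = "act1",
    clr4_population: str = "clr4_null",
) -> pd.DataFrame:
    """Per-population normalized expression from a tidy RT record table.

    Expects columns ``population, amplicon, assay, ip, replicate`` with RT
    rows carrying quantities in ``ip``. The Δclr4 maximum is the replicate
    mean of target/actin in ``clr4_population``. Returns
    ``population, expression, expression_sd``.
    """
    rt = records[records["assay"] == "RT"]
    if len(rt) == 0:
        raise ValueError("no RT rows in records")

    def per_replicate(pop_df: pd.DataFrame) -> pd.Series:
        wide = pop_df.pivot_table(index="replicate", columns="amplicon", values="ip")
        for amp in (target_amplicon, reference_amplicon):
            if amp not in wide:
                raise ValueError(f"missing amplicon {amp!r} in RT records")
        return wide[target_amplicon] / wide[reference_amplicon]

    clr4_rows = rt[rt["population"] == clr4_population]
    if len(clr4_rows) == 0:
        raise ValueError(f"no RT rows for Δclr4 reference population {clr4_population!r}")
    clr4_max = float(per_replicate(clr4_rows).mean())
    rows = []
    for pop, grp in rt.groupby("population", sort=False):
        ratios = per_replicate(grp) / clr4_max
        rows.append(
            {
                "population": pop,
                "expression": float(ratios.mean()),
                "expression_sd": float(ratios.std(ddof=1)) if len(ratios) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def standard_curve_quantify(cq_values, standards) -> dict:
    """Quantify sample Cq values through a qPCR dilution standard curve.

    ``standards`` is a sequence of ``(quantity, cq)`` pairs (e.g. five-fold
    dilutions of genomic DNA). Fits Cq = a·log10(quantity) + b, inverts the
    fit for each sample, and reports amplification efficiency from the slope
    (``10^(-1/slope) - 1``; −3.32 cycles per decade ≡ 100%).
    """
    standards = np.asarray(standards, dtype=float)
    if standards.ndim != 2 or standards.shape[1] != 2 or standards.shape[0] < 3:
        raise ValueError("need >= 3 (quantity, cq) standards")
    qty, cq = standards[:, 0], standards[:, 1]
    if np.any(qty <= 0):
        raise ValueError("standard quantities must be positive")
    order = np.argsort(qty)
    if not (np.all(np.diff(cq[order]) < 0)):
        raise ValueError("standards non-monotone: Cq must strictly decrease with quantity")
    slope, intercept = np.polyfit(np.log10(qty), cq, 1)
    samples = np.asarray(cq_values, dtype=float)
    quantities = 10.0 ** ((samples - intercept) / slope)
    return {
        "quantities": quantities,
        "slope": float(slope),
        "intercept": float(intercept),
        "efficiency": float(10.0 ** (-1.0 / slope) - 1.0),
    }
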