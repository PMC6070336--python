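"""Generative single-cell model of heterochromatin spreading and fluorescence.

The epigenetic state of a cell is a pair ``(nucleated, s)``: a binary
nucleation flag and a continuous spreading de-repression level ``s`` in
[0, 1] at the distal reporter (0 = fully spread/repressed, 1 = fully
de-repressed, the Δclr4 level). Per generation, ``s`` performs a clamped
Gaussian random walk:

* nucleated:      ``s' = clip(s - k_restore * s + sigma_s * eps, 0, 1)``,
  nucleation lost with probability ``k_denuc``;
* not nucleated:  ``s' = clip(s + k_loss * (1 - s) + sigma_s * eps, 0, 1)``,
  nucleation gained with probability ``k_nuc``;

with ``eps ~ N(0, 1)``. The noise scale ``sigma_s`` is the histone-turnover
proxy: strains with near-euchromatic replication-independent H3 exchange get
a large ``sigma_s`` and fluctuate, strains with repressed turnover get
``sigma_s ~ 0`` and are absorbing at ``s = 0``.

Fluorescence rendering maps a state to three reporter channels sharing one
multiplicative lognormal extrinsic factor per cell (the euchromatic "red"
channel reports this factor, which is why red-ratio normalization cancels
cell-to-cell noise), with independent per-channel lognormal noise and
additive lognormal autofluorescence background.

Experiment-level generators emulate each dataset the analysis stages
consume: equilibrium population snapshots, multigenerational time-lapse
traces, TSA dose-response tables, heat-recovery time courses, and
RT-qPCR / ChIP / RITE enrichment tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import DoseResponseCurve
from .presets import BinPreset, NoiseModel, StrainParams, default_config
from .rng import as_generator

__all__ = [
    "CellState",
    "CellSnapshot",
    "CellTrace",
    "step_cell",
    "render_fluorescence",
    "simulate_population",
    "simulate_traces",
    "traces_to_frame",
    "generate_tsa_gradient",
    "generate_heat_recovery",
    "generate_enrichment_dataset",
    "generate_rite_dataset",
    "TSA_CONCENTRATIONS_UM",
]

#: The 12-point TSA gradient: 0 µM (DMSO) plus 11 two-fold dilutions from 50 µM.
TSA_CONCENTRATIONS_UM = np.concatenate([[0.0], 50.0 / 2.0 ** np.arange(10, -1, -1)])

#: Hill exponent of the phenomenological log-logistic dose-response curve.
TSA_HILL = 1.5

#: Logistic slope (1/hr) of the heat-recovery time course.
RECOVERY_SLOPE = 0.09

#: Fraction of nucleated (green-OFF) cells in dose-response experiments.
NUCLEATED_FRACTION = 0.85


@dataclass
class CellState:
    """Epigenetic state of one cell."""

    nucleated: bool
    s_level: float
    generation: int = 0

    def __post_init__(self) -> None:
        self.s_level = float(np.clip(self.s_level, 0.0, 1.0))


@dataclass(frozen=True)
class CellSnapshot:
    """Raw three-channel fluorescence plus size scatter for one cell."""

    green_raw: float
    orange_raw: float
    red_raw: float
    fsc: float
    ssc: float
    strain: str = ""
    condition: str = ""


@dataclass
class CellTrace:
    """Time-lapse three-channel intensities for one trapped cell."""

    cell_id: str
    times_hr: np.ndarray
    green_raw: np.ndarray
    orange_raw: np.ndarray
    red_raw: np.ndarray
    entry_time_hr: float = 0.0
    exit_time_hr: float = np.nan
    died_or_ejected_before_12h: bool = False
    strain: str = ""

    def __post_init__(self) -> None:
        n = len(self.times_hr)
        if not (len(self.green_raw) == len(self.orange_raw) == len(self.red_raw) == n):
            raise ValueError("trace channel sequences must align with times_hr")
        if n > 1 and not np.all(np.diff(self.times_hr) > 0):
            raise ValueError("times_hr must be strictly increasing")


# ---------------------------------------------------------------------------
# state stepping
# ---------------------------------------------------------------------------

def _step_arrays(
    nucleated: np.ndarray,
    s: np.ndarray,
    params: StrainParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance arrays of cell states by one generation (vectorized)."""
    eps = rng.standard_normal(s.shape)
    drift = np.where(nucleated, -params.k_restore * s, params.k_loss * (1.0 - s))
    s_new = np.clip(s + drift + params.sigma_s * eps, 0.0, 1.0)
    u = rng.random(s.shape)
    flip = np.where(nucleated, u < params.k_denuc, u < params.k_nuc)
    return nucleated ^ flip, s_new


def step_cell(
    state: CellState, params: StrainParams, rng: np.random.Generator | int | None
) -> CellState:
    """Advance one cell by one generation of the spreading random walk."""
    rng = as_generator(rng)
    nuc, s = _step_arrays(
        np.array([state.nucleated]), np.array([state.s_level], dtype=float), params, rng
    )
    return CellState(nucleated=bool(nuc[0]), s_level=float(s[0]), generation=state.generation + 1)


# ---------------------------------------------------------------------------
# fluorescence rendering
# ---------------------------------------------------------------------------

def _lognormal_factor(rng: np.random.Generator, sd: float, size) -> np.ndarray:
    if sd == 0:
        return np.ones(size)
    # median-1 convention: factor = exp(sd * z)
    return np.exp(sd * rng.standard_normal(size))


def _render_arrays(
    nucleated: np.ndarray,
    s: np.ndarray,
    noise: NoiseModel,
    rng: np.random.Generator,
    xfp_free: bool = False,
) -> dict[str, np.ndarray]:
    n = s.shape[0]
    extrinsic = _lognormal_factor(rng, noise.extrinsic_sd, n)
    bg = {
        ch: np.maximum(
            rng.lognormal(
                np.log(max(noise.bg_mean, 1e-12)), noise.bg_sd / max(noise.bg_mean, 1e-12), n
            ),
            0.0,
        )
        for ch in ("green", "orange", "red")
    }
    leak = noise.leak
    if xfp_free:
        g_level = np.zeros(n)
        o_level = np.zeros(n)
        r_level = np.zeros(n)
    else:
        g_level = leak + (1.0 - leak) * (~nucleated).astype(float)
        o_level = leak + (1.0 - leak) * s
        r_level = np.ones(n)
    out = {}
    for ch, amp, level in (
        ("green", noise.amp_green, g_level),
        ("orange", noise.amp_orange, o_level),
        ("red", noise.amp_red, r_level),
    ):
        raw = amp * extrinsic * level * _lognormal_factor(rng, noise.channel_sd, n) + bg[ch]
        out[f"{ch}_raw"] = np.clip(raw, 0.0, None)
    # size scatter positively correlated with the extrinsic factor
    out["fsc"] = noise.fsc_scale * np.sqrt(extrinsic) * _lognormal_factor(rng, noise.scatter_sd, n)
    out["ssc"] = noise.ssc_scale * np.sqrt(extrinsic) * _lognormal_factor(rng, noise.scatter_sd, n)
    return out


def render_fluorescence(
    state: CellState,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | int | None = None,
    strain: str = "",
    condition: str = "",
    xfp_free: bool = False,
) -> CellSnapshot:
    """Render one cell state into a raw three-channel snapshot."""
    noise = noise or default_config().noise
    rng = as_generator(rng)
    arrs = _render_arrays(
        np.array([state.nucleated]), np.array([state.s_level], dtype=float), noise, rng, xfp_free
    )
    return CellSnapshot(
        green_raw=float(arrs["green_raw"][0]),
        orange_raw=float(arrs["orange_raw"][0]),
        red_raw=float(arrs["red_raw"][0]),
        fsc=float(arrs["fsc"][0]),
        ssc=float(arrs["ssc"][0]),
        strain=strain,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# population snapshots
# ---------------------------------------------------------------------------

def _burn_in(
    params: StrainParams,
    n_cells: int,
    burn_in_generations: int,
    rng: np.random.Generator,
    start: str = "derepressed",
) -> tuple[np.ndarray, np.ndarray]:
    if start == "derepressed":
        nucleated = np.zeros(n_cells, dtype=bool)
        s = np.ones(n_cells)
    elif start == "repressed":
        nucleated = np.ones(n_cells, dtype=bool)
        s = np.zeros(n_cells)
    else:
        raise ValueError(f"unknown start state {start!r}")
    for _ in range(burn_in_generations):
        nucleated, s = _step_arrays(nucleated, s, params, rng)
    return nucleated, s


def simulate_population(
    params: StrainParams | str,
    n_cells: int,
    burn_in_generations: int = 100,
    rng: np.random.Generator | int | None = None,
    noise: NoiseModel | None = None,
    condition: str = "steady_state",
) -> pd.DataFrame:
    """Simulate an equilibrium population and render flow-cytometry snapshots.

    Each cell starts fully de-repressed and is stepped ``burn_in_generations``
    generations (default 100, comfortably past the ~25 generations needed to
    establish a domain) before rendering. Returns a snapshots table with
    columns ``strain, condition, green_raw, orange_raw, red_raw, fsc, ssc``.
    """
    if isinstance(params, str):
        params = default_config().preset(params)
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if burn_in_generations < 0:
        raise ValueError("burn_in_generations must be >= 0")
    noise = noise or default_config().noise
    rng = as_generator(rng)
    nucleated, s = _burn_in(params, n_cells, burn_in_generations, rng)
    arrs = _render_arrays(nucleated, s, noise, rng, xfp_free=params.xfp_free)
    return pd.DataFrame(
        {
            "strain": params.name,
            "condition": condition,
            "green_raw": arrs["green_raw"],
            "orange_raw": arrs["orange_raw"],
            "red_raw": arrs["red_raw"],
            "fsc": arrs["fsc"],
            "ssc": arrs["ssc"],
        }
    )


# ---------------------------------------------------------------------------
# time-lapse traces
# ---------------------------------------------------------------------------

def simulate_traces(
    params: StrainParams | str,
    n_cells: int,
    duration_hr: float = 60.0,
    sample_interval_hr: float = 0.5,
    rng: np.random.Generator | int | None = None,
    noise: NoiseModel | None = None,
    start: str = "equilibrium",
    early_death_fraction: float = 0.05,
    equilibrium_generations: int = 100,
) -> list[CellTrace]:
    """Simulate multigenerational single-cell traces (microfluidic imaging).

    The epigenetic state advances once per ``doubling_time_hr``; fluorescence
    relaxes first-order (time constant ``noise.trace_tau_hr``) toward the
    state-implied level between samples, emulating fluorophore maturation and
    dilution, and is sampled every ``sample_interval_hr`` with small
    per-sample measurement noise. ``start='equilibrium'`` draws initial states
    from the strain's steady state; ``start='derepressed'`` begins fully
    de-repressed (establishment cohorts). A configurable fraction of cells is
    flagged as dying or being ejected before 12 hr.
    """
    if isinstance(params, str):
        params = default_config().preset(params)
    noise = noise or default_config().noise
    rng = as_generator(rng)

    times = np.arange(0.0, duration_hr + 1e-9, sample_interval_hr)
    n_t = len(times)
    if start == "equilibrium":
        nucleated, s = _burn_in(params, n_cells, equilibrium_generations, rng)
    else:
        nucleated, s = _burn_in(params, n_cells, 0, rng, start=start)

    extrinsic = _lognormal_factor(rng, noise.extrinsic_sd, n_cells)
    leak = noise.leak
    g_level = leak + (1.0 - leak) * (~nucleated).astype(float)
    o_level = leak + (1.0 - leak) * s
    # rendered levels start at the state-implied value
    g_obs, o_obs = g_level.copy(), o_level.copy()

    alpha = 1.0 - np.exp(-sample_interval_hr / max(noise.trace_tau_hr, 1e-9))
    next_division = rng.uniform(0.0, params.doubling_time_hr, n_cells)

    green = np.empty((n_cells, n_t))
    orange = np.empty((n_cells, n_t))
    red = np.empty((n_cells, n_t))
    for j, t in enumerate(times):
        due = t >= next_division
        while np.any(due):
            nuc_d, s_d = _step_arrays(nucleated[due], s[due], params, rng)
            nucleated[due], s[due] = nuc_d, s_d
            next_division[due] += params.doubling_time_hr
            due = t >= next_division
        g_target = leak + (1.0 - leak) * (~nucleated).astype(float)
        o_target = leak + (1.0 - leak) * s
        g_obs += alpha * (g_target - g_obs)
        o_obs += alpha * (o_target - o_obs)
        sd = noise.trace_channel_sd
        green[:, j] = noise.amp_green * extrinsic * g_obs * _lognormal_factor(rng, sd, n_cells) + noise.bg_mean
        orange[:, j] = noise.amp_orange * extrinsic * o_obs * _lognormal_factor(rng, sd, n_cells) + noise.bg_mean
        red[:, j] = noise.amp_red * extrinsic * _lognormal_factor(rng, sd, n_cells) + noise.bg_mean

    died = rng.random(n_cells) < early_death_fraction
    traces = []
    for i in range(n_cells):
        traces.append(
            CellTrace(
                cell_id=f"{params.name}_{i:04d}",
                times_hr=times.copy(),
                green_raw=green[i],
                orange_raw=orange[i],
                red_raw=red[i],
                entry_time_hr=0.0,
                exit_time_hr=float(times[-1]),
                died_or_ejected_before_12h=bool(died[i]),
                strain=params.name,
            )
        )
    return traces


def traces_to_frame(traces: list[CellTrace]) -> pd.DataFrame:
    """Flatten traces to a tidy table (cell_id, time_hr, three channels)."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "time_hr": tr.times_hr,
                    "green_raw": tr.green_raw,
                    "orange_raw": tr.orange_raw,
                    "red_raw": tr.red_raw,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# TSA dose response
# ---------------------------------------------------------------------------

def tsa_logistic(conc_uM: np.ndarray, half_resistance_uM: float, hill: float = TSA_HILL) -> np.ndarray:
    """Normalized orange-OFF mean: decreasing log-logistic, 0.5 at the midpoint."""
    conc = np.asarray(conc_uM, dtype=float)
    return 1.0 / (1.0 + (conc / half_resistance_uM) ** hill)


def generate_tsa_gradient(
    params: StrainParams | str,
    n_per_point: int,
    rng: np.random.Generator | int | None = None,
) -> tuple[DoseResponseCurve, DoseResponseCurve]:
    """Generate one TSA-gradient experiment: (pretreated, untreated) curves.

    The untreated-ancestry orange-OFF fraction follows
    ``off_fraction_0uM * S(c)`` with ``S`` a decreasing log-logistic whose
    midpoint is the preset's ``half_resistance_uM``; the TSA-pretreated arm is
    suppressed by ``memory_offset`` on the normalized scale (its separation
    from the untreated arm at 0 µM), decaying with the curve so the two arms
    converge at high concentration. Presets that cannot re-nucleate after
    erasure yield an essentially empty pretreated arm. Counts are binomial.
    """
    if isinstance(params, str):
        params = default_config().preset(params)
    if n_per_point < 1:
        raise ValueError("n_per_point must be >= 1")
    rng = as_generator(rng)
    conc = TSA_CONCENTRATIONS_UM
    s_curve = tsa_logistic(conc, params.half_resistance_uM)
    mean_untreated = np.clip(params.off_fraction_0uM * s_curve, 0.0, 1.0)
    if params.renucleates_after_erasure:
        mean_pre = np.clip((1.0 - params.memory_offset) * mean_untreated, 0.0, 1.0)
        green_off_pre = NUCLEATED_FRACTION
    else:
        mean_pre = np.full_like(conc, 0.002)
        green_off_pre = 0.02

    curves = []
    for ancestry, mean, g_off in (
        ("pretreated", mean_pre, green_off_pre),
        ("untreated", mean_untreated, NUCLEATED_FRACTION),
    ):
        n_total = np.full(conc.shape, n_per_point, dtype=int)
        n_orange_off = rng.binomial(n_total, mean)
        n_green_off = rng.binomial(n_total, g_off)
        curves.append(
            DoseResponseCurve(
                conc_uM=conc.copy(),
                n_total=n_total,
                n_orange_off=n_orange_off,
                n_green_off=n_green_off,
                ancestry=ancestry,
                condition=params.name,
            )
        )
    return curves[0], curves[1]


# ---------------------------------------------------------------------------
# heat recovery
# ---------------------------------------------------------------------------

def generate_heat_recovery(
    params: StrainParams | str,
    timepoints_hr=None,
    n_per_point: int = 2000,
    rng: np.random.Generator | int | None = None,
    baseline_full_spreading: float = 0.85,
) -> pd.DataFrame:
    """Generate a heat-stress recovery time course for one strain.

    Two arms: a 32°C control with a constant full-spreading fraction, and a
    38°C-exposed arm whose fraction recovers along an increasing logistic in
    time. The normalized (38°C / 32°C) curve crosses 0.5 at the preset's
    ``recovery_t_half_hr`` and has lower asymptote ``recovery_floor``
    (fraction of spreading retained through the perturbation). Counts are
    binomial. Columns: ``strain, arm, time_hr, n_total, n_full_spreading``.
    """
    if isinstance(params, str):
        params = default_config().preset(params)
    t = np.asarray(
        timepoints_hr if timepoints_hr is not None else np.arange(0.0, 96.0 + 1e-9, 12.0),
        dtype=float,
    )
    if np.any(t < 0) or np.any(t > 96):
        raise ValueError("timepoints must lie within [0, 96] hr")
    rng = as_generator(rng)
    floor, t_half = params.recovery_floor, params.recovery_t_half_hr
    if floor < 0.5:
        # solve the logistic midpoint so the curve crosses 0.5 at t_half
        frac = (0.5 - floor) / (1.0 - floor)
        midpoint = t_half + np.log(frac / (1.0 - frac)) / RECOVERY_SLOPE
    else:
        midpoint = t_half
    g = floor + (1.0 - floor) / (1.0 + np.exp(-RECOVERY_SLOPE * (t - midpoint)))
    rows = []
    for arm, mean in (("32C", np.full_like(t, baseline_full_spreading)),
                      ("38C", np.clip(baseline_full_spreading * g, 0.0, 1.0))):
        n_full = rng.binomial(n_per_point, mean)
        for ti, ni in zip(t, n_full):
            rows.append(
                {
                    "strain": params.name,
                    "arm": arm,
                    "time_hr": ti,
                    "n_total": n_per_point,
                    "n_full_spreading": int(ni),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# enrichment tables (RT-qPCR / ChIP / RITE)
# ---------------------------------------------------------------------------

_CHIP_CONTROL = {"H3K9me2": "dh", "H3K4me3": "act1_pro"}
_CONTROL_IP_OVER_INPUT = 0.10
_ENRICH_NOISE_SD = 0.04


def generate_enrichment_dataset(
    bin_presets: dict[str, BinPreset] | None = None,
    rng: np.random.Generator | int | None = None,
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Emulate the FACS-sorted-bin RT-qPCR and ChIP quantification tables.

    For each orange bin (low / intermediate / high) plus the Δclr4 reference
    population, emits RT quantities for the reporter (mKO2) and the actin
    reference, and ChIP IP/input pairs for the reporter amplicon alongside
    each antibody's positive-control amplicon, with multiplicative lognormal
    noise across technical replicates. Columns:
    ``population, amplicon, assay, ip, input, replicate``.
    """
    cfg = default_config()
    bins = dict(bin_presets) if bin_presets is not None else dict(cfg.bins)
    rng = as_generator(rng)
    rows = []

    def lognoise() -> float:
        return float(np.exp(_ENRICH_NOISE_SD * rng.standard_normal()))

    populations = {**bins, "clr4_null": BinPreset("clr4_null", 1.0, 0.02, 0.5)}
    actin_qty = 50.0
    for pop, preset in populations.items():
        for rep in range(1, n_replicates + 1):
            rows.append(
                {"population": pop, "amplicon": "act1", "assay": "RT",
                 "ip": actin_qty * lognoise(), "input": 1.0, "replicate": rep}
            )
            rows.append(
                {"population": pop, "amplicon": "mKO2", "assay": "RT",
                 "ip": actin_qty * preset.expression * lognoise(), "input": 1.0,
                 "replicate": rep}
            )
            for antibody, level in (("H3K9me2", preset.h3k9me2), ("H3K4me3", preset.h3k4me3)):
                inp_ctrl, inp_tgt = 100.0 * lognoise(), 100.0 * lognoise()
                rows.append(
                    {"population": pop, "amplicon": _CHIP_CONTROL[antibody],
                     "assay": antibody,
                     "ip": _CONTROL_IP_OVER_INPUT * inp_ctrl * lognoise(),
                     "input": inp_ctrl, "replicate": rep}
                )
                rows.append(
                    {"population": pop, "amplicon": "mKO2", "assay": antibody,
                     "ip": _CONTROL_IP_OVER_INPUT * level * inp_tgt * lognoise(),
                     "input": inp_tgt, "replicate": rep}
                )
    return pd.DataFrame(rows)


def generate_rite_dataset(
    strain: str,
    rng: np.random.Generator | int | None = None,
    n_replicates: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emulate a RITE tag-exchange ChIP experiment: (records_0h, records_4h).

    True 4 hr / 0 hr T7 enrichment ratios per amplicon come from the packaged
    ``rite`` preset table (1.0 = no replication-independent turnover).
    """
    cfg = default_config()
    if strain not in cfg.rite:
        raise KeyError(f"no RITE preset for strain {strain!r}; available: {sorted(cfg.rite)}")
    ratios = cfg.rite[strain]
    rng = as_generator(rng)
    base_ip_over_input = 0.05
    rows0, rows4 = [], []
    for amplicon, ratio in ratios.items():
        for rep in range(1, n_replicates + 1):
            inp0 = 100.0 * float(np.exp(_ENRICH_NOISE_SD * rng.standard_normal()))
            inp4 = 100.0 * float(np.exp(_ENRICH_NOISE_SD * rng.standard_normal()))
            noise0 = float(np.exp(_ENRICH_NOISE_SD * rng.standard_normal()))
            noise4 = float(np.exp(_ENRICH_NOISE_SD * rng.standard_normal()))
            rows0.append(
                {"population": strain, "amplicon": amplicon, "assay": "T7",
                 "ip": base_ip_over_input * inp0 * noise0, "input": inp0, "replicate": rep}
            )
            rows4.append(
                {"population": strain, "amplicon": amplicon, "assay": "T7",
                 "ip": base_ip_over_input * ratio * inp4 * noise4, "input": inp4,
                 "replicate": rep}
            )
    return pd.DataFrame(rows0), pd.DataFrame(rows4)
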