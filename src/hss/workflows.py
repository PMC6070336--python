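"""End-to-end analysis workflows chaining the simulation and analysis stages.

Each workflow regenerates its synthetic experiment from a root seed and runs
the full analysis path a real dataset would take: simulate → gate/normalize
→ clamp/classify (populations), or simulate → background-subtract/normalize
→ filter → cohort statistics (traces), etc. They are the single source of
truth for the package's benchmark numbers.
"""

from __future__ import annotations

import numpy as np

from . import cytometry, dose_response as dr, lineage, recovery as rec, simulate
from .presets import default_config
from .rng import substream

__all__ = [
    "population_state_analysis",
    "distance_series_analysis",
    "trace_cohort_analysis",
    "tsa_resistance_analysis",
    "heat_recovery_analysis",
    "red_green_rank_correlation",
]


def population_state_analysis(
    preset: str,
    n_cells: int = 10000,
    burn_in: int = 100,
    seed: int = 0,
    size_gate: bool = False,
) -> dict:
    """Equilibrium population snapshot → clamped orange-state fractions.

    Simulates the strain alongside its matched Δclr4 and no-XFP controls,
    red-ratio normalizes, applies the nucleation clamp (no-XFP green
    median + 2 SD), classifies orange states (OFF bound from the unstained
    control, ON bound at Δclr4 mean − 3 SD), and summarizes.
    """
    cfg = default_config()
    pop = simulate.simulate_population(
        preset, n_cells, burn_in, substream(seed, "population", preset), noise=cfg.noise
    )
    clr4 = simulate.simulate_population(
        "clr4_null", n_cells, burn_in, substream(seed, "population", "clr4_null"), noise=cfg.noise
    )
    noxfp = simulate.simulate_population(
        "no_xfp", max(n_cells // 2, 1000), 0, substream(seed, "population", "no_xfp"), noise=cfg.noise
    )
    if size_gate:
        gate = cytometry.SizeGate().fit(pop)
        pop = gate.transform(pop)
        pop = pop[pop["passes_size_gate"]]
        clr4 = gate.transform(clr4)
        clr4 = clr4[clr4["passes_size_gate"]]

    normalizer = cytometry.RedRatioNormalizer().fit(clr4)
    snaps = normalizer.transform(pop)
    clamp = cytometry.NucleationClamp().fit(noxfp["green_raw"].to_numpy())
    snaps = clamp.transform(snaps)
    unstained_upper = cytometry.unstained_upper_from_controls(
        noxfp["orange_raw"], clr4["red_raw"], normalizer.orange_ratio_center_
    )
    on_lower = max(
        normalizer.clr4_norm_mean_["orange"] - 3.0 * normalizer.clr4_norm_sd_["orange"],
        unstained_upper + 0.1,
    )
    classifier = cytometry.StateClassifier(unstained_upper=unstained_upper, on_lower=on_lower).fit()
    summary = cytometry.population_summary(snaps, classifier)
    summary["clamp_threshold"] = clamp.threshold_
    summary["unstained_upper"] = unstained_upper
    summary["on_lower"] = on_lower
    summary["fully_repressed_fraction"] = summary["orange_state_fractions"]["OFF"]
    return summary


def distance_series_analysis(
    distances_kb=(1.0, 3.0, 5.0, 7.0),
    n_cells: int = 10000,
    seed: int = 0,
) -> dict:
    """Fully-repressed fraction versus reporter distance, with the OLS line."""
    fractions = []
    for d in distances_kb:
        preset = f"ectopic_dh_{int(d)}kb"
        res = population_state_analysis(preset, n_cells=n_cells, seed=seed)
        fractions.append(res["fully_repressed_fraction"])
    slope, intercept, r2 = cytometry.distance_decline_fit(distances_kb, fractions)
    return {
        "distances_kb": list(distances_kb),
        "fractions": fractions,
        "slope": slope,
        "intercept": intercept,
        "r_squared": r2,
    }


def trace_cohort_analysis(
    preset: str,
    n_cells: int = 100,
    duration_hr: float = 60.0,
    sample_interval_hr: float = 0.5,
    seed: int = 0,
    clr4_seed: int | None = None,
    n_clr4: int = 50,
    clamp_level: float = 0.5,
    start: str = "equilibrium",
) -> dict:
    """Time-lapse cohort → crossing fractions, ON transits, transient events.

    Normalizes against a matched Δclr4 trace cohort (which also sets the ON
    cutoff at mean − 3 SD of its normalized orange values), retains cells
    that survived past 12 hr and maintained nucleation, and reports the
    fraction reaching half-maximal de-repression, the fraction transiting
    the fully-ON cutoff, and the fraction with at least one transient
    de-repression event.
    """
    cfg = default_config()
    traces = simulate.simulate_traces(
        preset, n_cells, duration_hr, sample_interval_hr,
        substream(seed, "traces", preset), noise=cfg.noise, start=start,
    )
    clr4 = simulate.simulate_traces(
        "clr4_null", n_clr4, duration_hr, sample_interval_hr,
        substream(clr4_seed if clr4_seed is not None else seed, "traces", "clr4_null"),
        noise=cfg.noise, early_death_fraction=0.0,
    )
    normalizer = lineage.TraceNormalizer(background=cfg.noise.bg_mean).fit(clr4)
    clr4_norm = normalizer.transform(clr4)
    clr4_vals = np.concatenate([t.orange_norm.compressed() for t in clr4_norm])
    on_cutoff = float(clr4_vals.mean() - 3.0 * clr4_vals.std(ddof=1))

    cohort = lineage.filter_cells(normalizer.transform(traces), clamp_threshold=clamp_level)
    fractions = lineage.crossing_fractions(cohort, half_level=0.5, on_cutoff=on_cutoff)
    maintained = [t for t in cohort if t.maintained_nucleation]
    transient = float(
        np.mean([any(e.transient for e in lineage.detect_events(t)) for t in maintained])
    )
    return {
        "n_retained": len(cohort),
        "n_maintained": len(maintained),
        "on_cutoff": on_cutoff,
        "fraction_half_maximal": fractions["fraction_half_maximal"],
        "fraction_on": fractions["fraction_on"],
        "fraction_transient_loss": transient,
        "max_points": fractions["max_points"],
    }


def tsa_resistance_analysis(preset: str, n_per_point: int = 5000, seed: int = 0) -> dict:
    """TSA gradient experiment → half-resistance and memory readout."""
    pre, unt = simulate.generate_tsa_gradient(
        preset, n_per_point, substream(seed, "tsa", preset)
    )
    result = dr.analyze_experiment(pre, unt)
    return {
        "half_resistance_uM": result.half_resistance_uM,
        "memory_score": result.memory_score,
        "convergence_conc_uM": result.convergence_conc_uM,
        "extrapolated": result.half_resistance_extrapolated,
    }


def heat_recovery_analysis(
    presets=("WT_MAT", "dREIII"),
    timepoints_hr=None,
    n_per_point: int = 2000,
    seed: int = 0,
) -> dict:
    """Heat-recovery time courses → per-strain t1/2 fits and Δt1/2.

    Δt1/2 is reported between the first two presets (second minus first).
    """
    fits = {}
    for name in presets:
        table = simulate.generate_heat_recovery(
            name, timepoints_hr, n_per_point, substream(seed, "recovery", name)
        )
        norm = rec.normalize_recovery(table)
        fits[name] = rec.fit_recovery(norm["time_hr"], norm["normalized"])
    out = {"fits": fits}
    if len(presets) >= 2:
        a, b = presets[0], presets[1]
        out["delta"] = rec.delta_t_half(fits[a], fits[b])
    return out


def red_green_rank_correlation(n_cells: int = 20000, seed: int = 0) -> float:
    """Spearman correlation of raw green vs red in a heterochromatin-null
    population, with no size gate (the noise-filter validation statistic)."""
    from scipy.stats import spearmanr

    cfg = default_config()
    pop = simulate.simulate_population(
        "clr4_null", n_cells, 100, substream(seed, "population", "clr4_null"), noise=cfg.noise
    )
    return float(spearmanr(pop["green_raw"], pop["red_raw"]).statistic)
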