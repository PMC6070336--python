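import numpy as np
import pandas as pd
import pytest

from hss import simulate
from hss.presets import NoiseModel, StrainParams
from hss.rng import substream
from hss.simulate import CellState, step_cell, render_fluorescence, tsa_logistic


def preset(**kw):
    defaults = dict(name="test", k_nuc=0.1, k_denuc=0.02, k_restore=0.2,
                    sigma_s=0.2, k_loss=0.3)
    defaults.update(kw)
    return StrainParams(**defaults)


class TestStepCell:
    def test_zero_noise_repressed_state_is_absorbing(self):
        """sigma_s = 0 with s = 0 while nucleated never leaves 0 (ΔK-OFF regime)."""
        p = preset(sigma_s=0.0, k_denuc=0.0)
        state = CellState(nucleated=True, s_level=0.0)
        rng = substream(0, "step")
        for _ in range(200):
            state = step_cell(state, p, rng)
            assert state.s_level == 0.0

    def test_derepressed_boundary_absorbs_without_noise(self):
        p = preset(sigma_s=0.0, k_nuc=0.0, k_loss=0.4)
        state = CellState(nucleated=False, s_level=1.0)
        state = step_cell(state, p, substream(1, "step"))
        assert state.s_level == 1.0
        assert state.generation == 1

    def test_full_restore_drift_reaches_zero_in_one_generation(self):
        p = preset(sigma_s=0.0, k_restore=1.0, k_denuc=0.0)
        state = step_cell(CellState(nucleated=True, s_level=0.5), p, substream(2, "step"))
        assert state.s_level == 0.0

    def test_state_always_clamped_to_unit_interval(self):
        p = preset(sigma_s=1.5)
        rng = substream(3, "step")
        state = CellState(nucleated=True, s_level=0.5)
        for _ in range(100):
            state = step_cell(state, p, rng)
            assert 0.0 <= state.s_level <= 1.0


class TestRenderFluorescence:
    def quiet_noise(self, **kw):
        defaults = dict(extrinsic_sd=0.0, channel_sd=0.0, bg_mean=0.0, bg_sd=0.0,
                        scatter_sd=0.0, leak=0.002)
        defaults.update(kw)
        return NoiseModel(**defaults)

    def test_noiseless_repressed_orange_is_amplitude_times_leak(self):
        noise = self.quiet_noise()
        snap = render_fluorescence(CellState(True, 0.0), noise, substream(0, "r"))
        assert snap.orange_raw == pytest.approx(noise.amp_orange * noise.leak)
        assert snap.green_raw == pytest.approx(noise.amp_green * noise.leak)
        assert snap.red_raw == pytest.approx(noise.amp_red)

    def test_shared_extrinsic_factor_scales_all_channels(self):
        """Two identical states with extrinsic factors differing 2x give raw
        channels differing exactly 2x when all other noise is off."""
        noise = self.quiet_noise(extrinsic_sd=0.0)
        state = np.array([True]), np.array([0.4])
        a = simulate._render_arrays(*state, noise, substream(1, "r"))
        doubled = NoiseModel(**{**noise.__dict__, "amp_green": 2 * noise.amp_green,
                                "amp_orange": 2 * noise.amp_orange, "amp_red": 2 * noise.amp_red})
        b = simulate._render_arrays(*state, doubled, substream(1, "r"))
        for ch in ("green_raw", "orange_raw", "red_raw"):
            assert b[ch][0] == pytest.approx(2 * a[ch][0])

    def test_rendered_values_are_finite_and_nonnegative(self):
        pop = simulate.simulate_population("dREIII", 500, 50, substream(4, "pop"))
        for col in ("green_raw", "orange_raw", "red_raw", "fsc", "ssc"):
            assert np.isfinite(pop[col]).all()
            assert (pop[col] >= 0).all()


class TestSimulatePopulation:
    def test_clr4_null_self_normalizes_to_one(self, clr4_population):
        ratios_g = clr4_population["green_raw"] / clr4_population["red_raw"]
        med = np.median(ratios_g)
        assert np.median(ratios_g / med) == pytest.approx(1.0)
        # green and orange are expressed at the red level (no repression)
        assert np.median(ratios_g) == pytest.approx(1.0, rel=0.1)

    def test_seeded_simulation_is_bit_reproducible(self):
        a = simulate.simulate_population("WT_MAT", 300, 30, substream(7, "x"))
        b = simulate.simulate_population("WT_MAT", 300, 30, substream(7, "x"))
        pd.testing.assert_frame_equal(a, b)

    def test_equilibrium_matches_long_chain_oracle(self):
        """The default burn-in reaches the walk's stationary repressed mass:
        a 10x longer, 10x larger independent chain gives the same fraction
        of nucleated cells at the repressed boundary within sampling error."""
        p = preset(k_restore=0.18, sigma_s=0.22)

        def repressed_fraction(n, gens, seed):
            nuc, s = simulate._burn_in(p, n, gens, substream(seed, "mc"))
            return float(np.mean(s[nuc] < 0.05)), int(nuc.sum())

        f_short, n_short = repressed_fraction(3000, 100, 11)
        f_long, n_long = repressed_fraction(30000, 1000, 12)
        se = np.sqrt(f_long * (1 - f_long) * (1 / n_short + 1 / n_long))
        assert abs(f_short - f_long) < 4 * se

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            simulate.simulate_population("WT_MAT", 0)
        with pytest.raises(ValueError):
            simulate.simulate_population("WT_MAT", 10, burn_in_generations=-1)


class TestSimulateTraces:
    def test_trace_shapes_and_monotone_times(self):
        traces = simulate.simulate_traces("WT_MAT", 5, 12.0, 0.5, substream(9, "tr"))
        assert len(traces) == 5
        for tr in traces:
            assert len(tr.times_hr) == 25
            assert np.all(np.diff(tr.times_hr) > 0)
            assert len(tr.green_raw) == len(tr.times_hr)

    def test_dk_off_orange_never_rises(self):
        """With sigma_s = 0, repressed traces stay at the leak level exactly:
        no normalized orange excursion is possible, not merely rare."""
        traces = simulate.simulate_traces(
            "dK_OFF", 30, 60.0, 0.5, substream(10, "tr"), start="repressed"
        )
        noise = simulate.default_config().noise
        # raw orange stays within background + leak signal at every sample
        ceiling = noise.amp_orange * noise.leak * 5 + noise.bg_mean * 3
        for tr in traces:
            assert tr.orange_raw.max() < ceiling

    def test_early_death_fraction_flags_cells(self):
        traces = simulate.simulate_traces(
            "WT_MAT", 200, 6.0, 1.0, substream(11, "tr"), early_death_fraction=0.5
        )
        frac = np.mean([t.died_or_ejected_before_12h for t in traces])
        assert 0.3 < frac < 0.7


class TestTsaGradient:
    def test_gradient_is_twelve_points_from_dmso_to_50uM(self):
        pre, unt = simulate.generate_tsa_gradient("WT_MAT", 100, substream(12, "tsa"))
        assert len(unt.conc_uM) == 12
        assert unt.conc_uM[0] == 0.0
        assert unt.conc_uM[-1] == pytest.approx(50.0)
        assert unt.conc_uM[1] == pytest.approx(50.0 / 2**10)

    def test_zero_memory_offset_gives_indistinguishable_curves(self):
        p = preset(memory_offset=0.0, half_resistance_uM=1.0, off_fraction_0uM=0.5)
        pre, unt = simulate.generate_tsa_gradient(p, 20000, substream(13, "tsa"))
        diff = np.abs(pre.frac_orange_off - unt.frac_orange_off)
        se = np.sqrt(2 * 0.5 * 0.5 / 20000)
        assert np.all(diff < 5 * se)

    def test_monte_carlo_mean_matches_logistic_closed_form(self):
        """Replicate-averaged OFF fractions agree with the generating
        log-logistic within 3 standard errors at every concentration."""
        p = preset(half_resistance_uM=2.0, off_fraction_0uM=0.8, memory_offset=0.3)
        n_rep, n_per = 100, 200
        acc = np.zeros(12)
        for i in range(n_rep):
            _, unt = simulate.generate_tsa_gradient(p, n_per, substream(i, "mc_tsa"))
            acc += unt.frac_orange_off
        mean = acc / n_rep
        expected = 0.8 * tsa_logistic(simulate.TSA_CONCENTRATIONS_UM, 2.0)
        se = np.sqrt(expected * (1 - expected) / (n_rep * n_per))
        assert np.all(np.abs(mean - expected) < 3 * np.maximum(se, 1e-4))

    def test_non_renucleating_preset_has_empty_pretreated_arm(self):
        pre, _ = simulate.generate_tsa_gradient("dK_OFF", 5000, substream(14, "tsa"))
        assert pre.frac_orange_off.max() < 0.02
        assert (pre.n_green_off / pre.n_total).max() < 0.05


class TestHeatRecovery:
    def test_midpoint_definition(self):
        """At t = recovery_t_half_hr the normalized mean is exactly 0.5."""
        p = preset(recovery_t_half_hr=30.0, recovery_floor=0.0)
        table = simulate.generate_heat_recovery(
            p, timepoints_hr=[30.0], n_per_point=400000, rng=substream(15, "rec")
        )
        wide = table.pivot_table(index="time_hr", columns="arm", values="n_full_spreading")
        assert (wide["38C"] / wide["32C"]).iloc[0] == pytest.approx(0.5, abs=0.01)

    def test_dk_preset_barely_perturbed(self):
        table = simulate.generate_heat_recovery("dK_OFF", n_per_point=5000, rng=substream(16, "rec"))
        frac = table.pivot_table(index="time_hr", columns="arm",
                                 values="n_full_spreading", aggfunc="sum")
        normalized = frac["38C"] / frac["32C"]
        assert (normalized >= 0.88).all()

    def test_timepoints_outside_protocol_rejected(self):
        with pytest.raises(ValueError):
            simulate.generate_heat_recovery("WT_MAT", timepoints_hr=[0, 120])
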