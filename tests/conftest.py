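import numpy as np
import pytest

from hss import simulate
from hss.presets import default_config
from hss.rng import substream


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def noise(config):
    return config.noise


@pytest.fixture(scope="session")
def clr4_population(noise):
    """Simulated Δclr4 (heterochromatin-null) snapshot population."""
    return simulate.simulate_population(
        "clr4_null", 8000, 100, substream(101, "clr4"), noise=noise
    )


@pytest.fixture(scope="session")
def noxfp_population(noise):
    """Simulated no-XFP (autofluorescence-only) control population."""
    return simulate.simulate_population(
        "no_xfp", 4000, 0, substream(101, "noxfp"), noise=noise
    )


@pytest.fixture(scope="session")
def clr4_traces(noise):
    """Δclr4 trace cohort used as the trace-normalization reference."""
    return simulate.simulate_traces(
        "clr4_null", 40, 60.0, 0.5, substream(101, "clr4tr"),
        noise=noise, early_death_fraction=0.0,
    )


def make_trace(times, orange, green=None, red_level=1000.0, cell_id="cell"):
    """Hand-built raw trace whose normalized orange ≈ the given values
    (red constant, zero background, unit Δclr4 scale implied by caller)."""
    times = np.asarray(times, dtype=float)
    orange = np.asarray(orange, dtype=float)
    green = np.zeros_like(orange) if green is None else np.asarray(green, dtype=float)
    return simulate.CellTrace(
        cell_id=cell_id,
        times_hr=times,
        green_raw=green * red_level,
        orange_raw=orange * red_level,
        red_raw=np.full_like(orange, red_level),
    )
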