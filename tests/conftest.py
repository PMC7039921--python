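import numpy as np
import pytest

from isoniche.core import WhiskerSeries


@pytest.fixture
def make_sinusoid():
    """Factory for sinusoidal δ13C whisker series on a 5 mm grid."""

    def _make(
        period_mm=35.0,
        n_segments=60,
        amplitude=1.0,
        noise_sd=0.0,
        slope_per_mm=0.0,
        phase=0.0,
        seed=0,
        d15n=9.0,
        sex="male",
        seal_id="w1",
    ):
        rng = np.random.default_rng(seed)
        x = np.arange(n_segments) * 5.0
        d13c = (
            -21.0
            + slope_per_mm * x
            + amplitude * np.sin(2 * np.pi * x / period_mm + phase)
            + rng.normal(0.0, noise_sd, n_segments)
        )
        return WhiskerSeries(seal_id, sex, x, d13c, np.full(n_segments, d15n))

    return _make


@pytest.fixture(scope="session")
def default_population():
    """One default synthetic colony, shared across tests (read-only)."""
    from isoniche.synthetic import SimConfig, simulate_population

    return simulate_population(SimConfig(seed=42))
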