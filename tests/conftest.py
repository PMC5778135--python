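import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pm25burden import GriddedField, GridSpec, HotspotSpec, IERCoefficients, SyntheticConfig
from pm25burden.synth import AGE_BINS, AGE_SPECIFIC_DISEASES

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_coeffs(alpha=1.0, gamma=0.07, delta=0.6, counterfactual=5.8) -> IERCoefficients:
    """One shared exposure-response triple for every disease and age bin."""
    triples = {("COPD", None): (alpha, gamma, delta), ("LC", None): (alpha, gamma, delta)}
    for disease in AGE_SPECIFIC_DISEASES:
        for age_bin in AGE_BINS:
            triples[(disease, age_bin)] = (alpha, gamma, delta)
    return IERCoefficients(triples, counterfactual)


SMALL_GRID = GridSpec(16.5, 26.5, 72.5, 82.5, 0.5)  # 20 x 20 cells
SMALL_HOTSPOT = HotspotSpec(lat=21.5, lon=77.5, radius_deg=2.0, amplitude=30.0)


@pytest.fixture
def config_factory():
    """Small, fast study configuration with overridable knobs."""

    def make(**overrides) -> SyntheticConfig:
        defaults = dict(
            seed=11, grid=SMALL_GRID, n_models=5,
            hotspot=SMALL_HOTSPOT, noise_sd=0.05, bias_sd=0.2,
        )
        defaults.update(overrides)
        return SyntheticConfig(**defaults)

    return make


@pytest.fixture
def quiet_config(config_factory):
    """Noise-free variant: planted signals are exactly recoverable."""
    return config_factory(noise_sd=0.0)


@pytest.fixture
def uniform_field():
    """Factory for spatially uniform fields on an all-land small grid."""

    def make(value: float, grid: GridSpec | None = None, units: str = "ug m-3") -> GriddedField:
        grid = grid or GridSpec(20.0, 22.0, 75.0, 77.0, 0.5)
        return GriddedField(
            np.full(grid.shape, float(value)), units,
            np.ones(grid.shape, dtype=bool), grid,
        )

    return make
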