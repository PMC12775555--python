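import numpy as np
import pytest

from pinkfoot.config import AnalysisConfig
from pinkfoot.synthetic import (
    DEFAULT_SITES, Itinerary, ScenarioConfig, Stay, default_scenario,
)


@pytest.fixture(scope="session")
def acfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def noiseless_scenario():
    """Small single-year scenario with zero temperature/index noise."""
    return default_scenario(11, years=[2022], n_individuals=4,
                            temp_sd_c=0.0, index_sd=0.0, gps_sd_m=0.0)


def breeding_only_scenario(
    seed: int,
    n: int,
    propensity: float = 0.6,
    success_prob: float = 0.5,
    attendance: float = 0.9,
    gps_sd_m: float = 15.0,
    fixed_nest_days: int | None = None,
) -> ScenarioConfig:
    """Goose-years that only occupy the Svalbard breeding area — fast nest tests."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4242]))
    cfg = ScenarioConfig(seed=seed, years=[2022], sites=dict(DEFAULT_SITES),
                         n_individuals=n, gps_sd_m=gps_sd_m)
    for i in range(n):
        arr = int(rng.integers(130, 140))
        breeds = bool(rng.random() < propensity)
        laying = nd = None
        if breeds:
            laying = arr + int(rng.integers(5, 15))
            if fixed_nest_days is not None:
                nd = fixed_nest_days
            elif rng.random() < success_prob:
                nd = int(rng.integers(28, 36))
            else:
                nd = int(rng.integers(4, 21))
        cfg.itineraries[(f"g{i:03d}", 2022)] = Itinerary(
            stays=[Stay("svalbard", arr, arr + 80)], breeds=breeds,
            laying_day=laying, attendance_prob=attendance, nest_days=nd,
            track_end_day=arr + 80)
    return cfg
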