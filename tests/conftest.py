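import numpy as np
import pandas as pd
import pytest

from pollencast.io_core import DailyPollenSeries
from pollencast.synthetic_data import GeneratorConfig, generate_study


@pytest.fixture
def toy_pollen_year() -> DailyPollenSeries:
    """Ten-day toy season: days 100-109 = [1,2,5,40,30,15,5,1,1,0], total 100."""
    values = pd.Series(
        [1.0, 2.0, 5.0, 40.0, 30.0, 15.0, 5.0, 1.0, 1.0, 0.0],
        index=range(100, 110),
    )
    return DailyPollenSeries(1995, values)


def random_pollen_series(rng: np.random.Generator, year: int = 2001) -> DailyPollenSeries:
    """Short random series for oracle comparisons (length <= 120 days)."""
    n = int(rng.integers(5, 121))
    offset = int(rng.integers(1, 200))
    values = rng.choice([0.0, 0.0, 1.0, 2.0, 5.0, 10.0, 50.0], size=n) * rng.random(n)
    if values.sum() == 0.0:
        values[int(rng.integers(0, n))] = 1.0
    return DailyPollenSeries(year, pd.Series(values, index=range(offset, offset + n)))


@pytest.fixture(scope="session")
def default_study():
    """An 18-year synthetic study under the default conditions."""
    config = GeneratorConfig(n_years=18, seed=20)
    met, pollen, truth = generate_study(config)
    return config, met, pollen, truth
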