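import datetime as dt

import pytest

from patchflux.simulate import CampaignDesignSpec, simulate_campaign
from patchflux.types import ChamberGeometry


@pytest.fixture(scope="session")
def geometry() -> ChamberGeometry:
    """Reference cylinder: 10 cm tall, 25 cm internal diameter."""
    return ChamberGeometry(height=0.10, internal_diameter=0.25)


def small_spec(seed: int, **overrides) -> CampaignDesignSpec:
    """A fast 2-site campaign with the full design structure."""
    defaults = dict(
        n_sites=2,
        n_replicates=2,
        sampling_days=(-1, 0, 1, 3, 7, 14, 21),
        urine_n_kg_ha=(464, 789),
        site_mean_temp_c=(22, 27),
        start_date=dt.date(2015, 11, 15),
    )
    defaults.update(overrides)
    return CampaignDesignSpec(seed=seed, **defaults)


@pytest.fixture(scope="session")
def small_campaign():
    """One small noisy campaign plus its ground truth (shared, read-only)."""
    return simulate_campaign(small_spec(seed=11))


@pytest.fixture(scope="session")
def noisefree_campaign():
    return simulate_campaign(small_spec(seed=12, chamber_noise_sd_ppb=0.0))
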