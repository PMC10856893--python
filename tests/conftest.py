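import numpy as np
import pytest

import lysitran as lt
from lysitran import datasets
from lysitran.synthetic import logistic_lai


def flowering_recovery_frame(seed: int, n_days: int = 150, noise_sd: float = 0.05):
    """Synthetic flowering-stage dataset generated from the published
    coefficients: microclimate at the 2022 flowering climatology, canopy
    spanning the branch's LAI domain [1, lai_max]."""
    params = datasets.stage_params(
        2022, "flowering_fruit_setting", seed=seed, n_days=n_days
    )
    climate = lt.generate_microclimate(params)
    laip = lt.LaiTrajectoryParams()
    crossing = laip.midpoint_day - np.log(laip.lai_max - 1.0) / laip.rate
    lai = logistic_lai(np.linspace(crossing, 80.0, n_days), laip)
    transp = lt.generate_transpiration(
        climate, lai, lt.PUBLISHED["flowering"], noise_sd=noise_sd, seed=seed + 100
    )
    frame = climate.copy()
    frame["lai"] = lai
    frame["tm"] = transp["tm"].to_numpy()
    return frame


@pytest.fixture
def flowering_frame():
    return flowering_recovery_frame(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
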