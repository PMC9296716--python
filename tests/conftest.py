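import numpy as np
import pandas as pd
import pytest

import parafat as pf


@pytest.fixture
def noiseless_phantom():
    """Phantom with exact region means: para-left 580, para-right 700."""
    params = pf.PhantomParams(
        noise_sd=0.0,
        fat_fraction_pm_left=0.05,
        fat_fraction_pm_right=0.05,
        fat_fraction_para_left=0.30,
        fat_fraction_para_right=0.50,
        seed=1,
    )
    image, masks, truth = pf.generate_phantom(params)
    return params, image, masks, truth


@pytest.fixture
def small_records():
    """Long-format measurement records: 3 subjects x 2 observers x 2 sessions."""
    rows = []
    values = {
        (1, 1, 1): (0.50, 1), (1, 2, 1): (0.55, 1),
        (1, 1, 2): (0.52, 1), (1, 2, 2): (0.54, 2),
        (2, 1, 1): (0.70, 0), (2, 2, 1): (0.72, 0),
        (2, 1, 2): (0.69, 0), (2, 2, 2): (0.71, 0),
        (3, 1, 1): (0.30, 3), (3, 2, 1): (0.35, 2),
        (3, 1, 2): (0.31, 3), (3, 2, 2): (0.33, 3),
    }
    for (pid, obs, ses), (mfi, gcs) in values.items():
        rows.append(
            {"patient_id": pid, "level": "L2L3", "side": "left",
             "observer": obs, "session": ses, "mfi": mfi, "gcs": gcs}
        )
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
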