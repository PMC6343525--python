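import numpy as np
import pandas as pd
import pytest

from heliastress.synth import PlantModelTruth, gen_ril_panel
from heliastress.water import PotCalibration


@pytest.fixture
def cal():
    """Standard 15-L pot calibration: 18 kg at capacity, 6 kg TTSW."""
    return PotCalibration(w_max=18.0, ttsw=6.0)


@pytest.fixture
def plant_truth():
    return PlantModelTruth(
        genotype_id="g1", a_tr=-9.66, a_le=-4.94,
        demand_scale=1.1, potential_le=0.0, noise_sd_weight=0.0,
    )


@pytest.fixture(scope="session")
def small_panel():
    """90-line backcross panel, 17 LGs x 15 markers, 10% planted duplicates."""
    return gen_ril_panel(
        n_lines=90, lg_count=17, markers_per_lg=15, dup_fraction=0.1, seed=3
    )


@pytest.fixture
def toy_plants():
    """Noise-free two-line TKW trial with known gamma, alpha, beta."""
    rows = []
    for line, g, a in (("L1", 2.0, 0.1), ("L2", -2.0, -0.1)):
        for trt, s in (("control", 0.0), ("stress", 20.0)):
            rows.append((line, trt, s, g + (-0.5 + a) * s))
    return pd.DataFrame(rows, columns=["line", "treatment", "sftsw", "tkw"])
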