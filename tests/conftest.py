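import numpy as np
import pandas as pd
import pytest

from evoqg import TRAIT_COLUMNS, ctmc, synthetic
from evoqg.pipeline import default_g0, default_gamma_true


@pytest.fixture(scope="session")
def q_example() -> ctmc.RateMatrix:
    """Heterogeneous rate matrix used across CTMC tests (rates per second)."""
    return ctmc.RateMatrix(np.array([2.0, 0.5, 0.5, 0.5, 0.5, 0.5]))


@pytest.fixture(scope="session")
def small_tracks(q_example) -> pd.DataFrame:
    """100 simulated tracks with frame drops (mixed observation lags)."""
    cfg = synthetic.TrackSimConfig(
        Q_true=q_example,
        n_tracks=100,
        mean_track_duration=30.0,
        burn_in_discard=0.0,
        gap_probability=0.2,
        seed=11,
    )
    return synthetic.simulate_tracks(cfg, n_plates=2)


@pytest.fixture(scope="session")
def g_true() -> np.ndarray:
    return default_g0()


@pytest.fixture(scope="session")
def gamma_true() -> np.ndarray:
    return default_gamma_true()


@pytest.fixture(scope="session")
def panel_table(g_true) -> pd.DataFrame:
    """Inbred-line panel: 150 lines x 3 blocks from the default planted G."""
    cfg = synthetic.PanelSimConfig(
        G_true=g_true, n_lines=150, blocks_per_line=3, seed=5
    )
    return synthetic.simulate_line_phenotypes(cfg)


@pytest.fixture(scope="session")
def centered_line_traits() -> pd.DataFrame:
    """250 synthetic line trait means, centered, for selection-surface tests."""
    rng = np.random.default_rng(17)
    z = rng.standard_normal((250, 6)) * 0.5
    z -= z.mean(axis=0)
    df = pd.DataFrame(z, columns=list(TRAIT_COLUMNS))
    df.insert(0, "line_id", [f"L{i:04d}" for i in range(250)])
    return df
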