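import numpy as np
import pandas as pd
import pytest

import metstab as ms


@pytest.fixture(scope="session")
def hand_matrix() -> ms.GEMatrix:
    """3x3 worked example used across the hand-oracle tests.

    Rows (10,20,30), (20,25,30), (30,30,30): env means (20,25,30),
    genotype means (20,25,30), grand mean 25.  The double-centered
    residual is rank-1 with singular value 10, giving ecovalence
    (50,0,50), Shukla (50,-25,50), joint-regression slopes (2,1,0),
    Lin & Binns Pi (500/6, 125/6, 0), Huehn S1 (2/3, 0, 2/3).
    """
    v = pd.DataFrame(
        [[10.0, 20.0, 30.0], [20.0, 25.0, 30.0], [30.0, 30.0, 30.0]],
        index=["G1", "G2", "G3"],
        columns=["E1", "E2", "E3"],
    )
    return ms.GEMatrix(v)


@pytest.fixture(scope="session")
def small_sim():
    """Fast 10x4x3 synthetic MET with moderate noise."""
    cfg = ms.SimConfig(g=10, e=4, r=3, gei_rank=2, gei_axis_weights=(0.8, 0.2), seed=7)
    return ms.simulate_met(cfg)


@pytest.fixture(scope="session")
def paper_scale_sim():
    """34x8x3 synthetic MET at the default variance partition."""
    return ms.simulate_met(ms.SimConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_sim():
    """Zero-noise, zero-block configuration: the pattern is exact."""
    cfg = ms.SimConfig(seed=3, noise_sd=0.0, block_sd=0.0)
    return ms.simulate_met(cfg)


def make_dataset(values: np.ndarray, r: int = 2, noise: float = 0.0, seed: int = 0):
    """Expand a g x e means matrix into a balanced plot table."""
    rng = np.random.default_rng(seed)
    g, e = values.shape
    rows = []
    for j in range(e):
        for i in range(g):
            for t in range(r):
                rows.append(
                    (f"E{j+1}", f"G{i+1}", f"R{t+1}",
                     values[i, j] + (noise and rng.normal(0, noise)))
                )
    return ms.METDataset(pd.DataFrame(rows, columns=["env", "gen", "rep", "yield"]))
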