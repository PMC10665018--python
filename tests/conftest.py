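import numpy as np
import pandas as pd
import pytest

import evometab as em


@pytest.fixture(scope="session")
def default_table():
    """One study-design-scale synthetic table with ground truth."""
    return em.simulate_peak_table(em.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_pipeline(default_table):
    """Full pipeline products on the default synthetic table."""
    pt, gt = default_table
    imputed, fct, calls = em.foldchanges_from_raw(pt, impute_seed=5)
    return pt, gt, imputed, fct, calls


def _toy_values(data, compounds, modes, samples):
    idx = pd.MultiIndex.from_tuples(
        list(zip(compounds, modes)), names=["compound", "ion_mode"]
    )
    return pd.DataFrame(np.asarray(data, dtype=float), index=idx, columns=samples)


@pytest.fixture
def toy_table():
    """2 features x 4 samples (two lines, both phases, 1 replicate)."""
    samples = ["R06_exp_r1", "R06_sta_r1", "A-1_exp_r1", "A-1_sta_r1"]
    meta = pd.DataFrame(
        {
            "line_id": ["R06", "R06", "A-1", "A-1"],
            "phase": ["exponential", "stationary"] * 2,
            "replicate": [1, 1, 1, 1],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    values = _toy_values(
        [[10.0, 12.0, 40.0, 6.0], [5.0, 6.0, 20.0, 3.0]],
        ["ala", "glu"],
        ["pos", "pos"],
        samples,
    )
    return em.PeakTable(values=values, samples=meta)


def make_noise_fct(seed, n_features=196, planted_frac=0.0, planted_sd=2.0, phase="exponential"):
    """Tidy fold-change table: i.i.d. line profiles, optionally with a block
    of features sharing a common (12-line) effect — the planted-parallelism
    alternative for correlation tests."""
    rng = np.random.default_rng(seed)
    lines = list(em.EVOLVED_LINES)
    vals = rng.normal(0.0, 1.0, (n_features, len(lines)))
    n_planted = int(planted_frac * n_features)
    if n_planted:
        vals[:n_planted] += rng.normal(0.0, planted_sd, (n_planted, 1))
    recs = []
    for j, li in enumerate(lines):
        for i in range(n_features):
            recs.append((f"c{i:03d}", "pos", li, phase, float(2.0 ** vals[i, j]), float(vals[i, j])))
    return pd.DataFrame(
        recs, columns=["compound", "ion_mode", "line_id", "phase", "fc", "log2fc"]
    )


@pytest.fixture
def noise_fct_factory():
    return make_noise_fct
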