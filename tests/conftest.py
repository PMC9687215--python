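import numpy as np
import pandas as pd
import pytest

from bloodpanel.expression import CONTROL, DISEASE, ExpressionDataset
from bloodpanel.forest import SessionConfig
from bloodpanel.simulate import SimulationParams, generate_dataset


def make_dataset(values, labels, probe_ids=None, sample_ids=None, **kwargs):
    """Build a small ExpressionDataset from a plain array and 0/1 labels."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    probe_ids = probe_ids or [f"P{i}" for i in range(1, n_probes + 1)]
    sample_ids = sample_ids or [f"S{i}" for i in range(1, n_samples + 1)]
    labels = pd.Series(
        [DISEASE if int(l) else CONTROL for l in labels], index=sample_ids
    )
    return ExpressionDataset(
        values=pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        labels=labels,
        **kwargs,
    )


@pytest.fixture(scope="session")
def tiny_config():
    """Very small session profile for fast structural tests."""
    return SessionConfig(
        n_trees_stage1=25,
        top_k_stage2=30,
        n_trees_stage3=50,
        top_k_final=10,
        n_sessions=2,
        base_seed=7,
    )


@pytest.fixture(scope="session")
def small_signal_data():
    """300-probe dataset with 8 strongly planted probes, split 2:1."""
    from bloodpanel.expression import stratified_split

    params = SimulationParams(
        n_control=60, n_disease=60, n_probes=300, n_informative=8,
        effect_size=2.5, seed=314,
    )
    dataset, truth = generate_dataset(params)
    train, test = stratified_split(dataset, 1 / 3, seed=9)
    return train, test, truth
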