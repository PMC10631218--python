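import numpy as np
import pytest

from convboost.containers import LabeledDataset, RawSeries, SplitSpec
from convboost.data_io import one_hot_encode, split_dataset
from convboost.synthetic_data import MotifGeneratorConfig, gen_motif_sequences


@pytest.fixture(scope="session")
def motif_dataset() -> LabeledDataset:
    """Small planted-motif dataset (random placement) shared across tests."""
    seqs, y = gen_motif_sequences(MotifGeneratorConfig(n=120, seed=11))
    return LabeledDataset(one_hot_encode(seqs), y, "sequence", ["background", "motif"])


@pytest.fixture(scope="session")
def motif_splits(motif_dataset):
    return split_dataset(motif_dataset, SplitSpec(seed=11))


@pytest.fixture()
def single_label_series() -> list[RawSeries]:
    """Three subjects, one activity each, constant-frequency channels."""
    rng = np.random.default_rng(3)
    out = []
    for s, lab in enumerate(["walk", "sit", "jog"]):
        T = 200 + 40 * s
        t = np.arange(T) * 0.05
        ch = rng.normal(size=(T, 4))
        out.append(RawSeries(f"s{s}", t, ch, np.array([lab] * T, dtype=object)))
    return out
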