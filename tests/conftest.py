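import numpy as np
import pytest

from dpalign.features import FeatureSet, MeasuredFeature
from dpalign.simulate import SimulationConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_feature(d, i, mz, rt, drift=None, intensity=100.0, charge=2,
                 sequence=None, score=None, fragments=()):
    coords = {"mz": mz, "rt": rt}
    if drift is not None:
        coords["drift"] = drift
    return MeasuredFeature(
        dataset_index=d,
        feature_index=i,
        coords=coords,
        intensity=intensity,
        charge=charge,
        sequence=sequence,
        id_score=score,
        fragments=list(fragments),
    )


@pytest.fixture
def small_datasets():
    """Three tiny replicate runs from the generator (identity-free warps)."""
    cfg = SimulationConfig(n_latent_peptides=40, seed=3)
    datasets, truth = generate(cfg)
    return datasets, truth


@pytest.fixture
def identified_replicates():
    """Two identical replicate datasets sharing 6 identified peptides."""
    seqs = [f"PEPTIDE{c}K" for c in "ABCDEF"]
    rng = np.random.default_rng(0)
    mz = 400 + 700 * rng.random(6)
    rt = 10 + 70 * rng.random(6)
    datasets = []
    for d in range(2):
        feats = [
            make_feature(d, i, float(mz[i]), float(rt[i]),
                         sequence=seqs[i], score=6.0 + i)
            for i in range(6)
        ]
        datasets.append(
            FeatureSet(dataset_label=f"rep{d}", features=feats,
                       dimension_names=("mz", "rt"))
        )
    return datasets
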