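import numpy as np
import pytest

import arraybench as ab
from arraybench.containers import ExpressionMatrix, SampleMeta


def make_matrix(values, gene_ids=None, labels=None, patients=None, flags=None):
    """Build an ExpressionMatrix from a plain array for unit tests."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    labels = labels if labels is not None else ["a"] * (n_samples // 2) + \
        ["b"] * (n_samples - n_samples // 2)
    patients = patients or [f"p{i}" for i in range(n_samples)]
    meta = [SampleMeta(f"s{i}", patients[i], labels[i]) for i in range(n_samples)]
    return ExpressionMatrix(values=values, gene_ids=list(gene_ids), meta=meta,
                            flags=flags)


@pytest.fixture(scope="session")
def clean_cfg():
    """Bias-free, background-free, flag-free generator settings with a
    strong planted signal."""
    return ab.SimConfig(n_genes=400, n_samples=24, n_patients=20, n_diff=30,
                        effect_size=3.0, noise_sd=1.0, dye_bias_amplitude=0.0,
                        n_printtips=4, background_level=0.0, flag_rate=0.0,
                        dup_rate=0.0, seed=7)


@pytest.fixture(scope="session")
def clean_dataset(clean_cfg):
    return ab.generate_dataset(clean_cfg, return_truth=True)


@pytest.fixture(scope="session")
def clean_matrix(clean_dataset):
    spots, meta, _ = clean_dataset
    return ab.preprocess(ab.normalize_dataset(spots, meta, 0))


@pytest.fixture(scope="session")
def separable_xy():
    """Linearly separable two-class sample matrix (samples x genes)."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(40, 10))
    y = np.array(["neg"] * 20 + ["pos"] * 20, dtype=object)
    X[20:, :4] += 4.0
    return X, y
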