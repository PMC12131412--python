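import numpy as np
import pytest

import stloc


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_dataset():
    """3 observations x 2 genes with coordinates, for container tests."""
    return stloc.SpatialDataset(
        expr=np.array([[1.0, 2.0], [0.0, 5.0], [3.0, 3.0]]),
        gene_ids=["gA", "gB"],
        obs_ids=["s1", "s2", "s3"],
        coords=np.array([[0.0, 0.0], [10.0, 5.0], [5.0, 20.0]]),
    )


@pytest.fixture(scope="session")
def tiny_reference():
    """A small synthetic tissue shared by training-dependent tests."""
    cfg = stloc.SynthConfig(n_spots=300, n_genes=50, n_svg=12, mean_depth=1200, seed=5)
    reference, truth = stloc.generate_reference(cfg)
    return cfg, reference, truth


@pytest.fixture(scope="session")
def tiny_trained(tiny_reference):
    """A quickly trained small model for prediction/SVG plumbing tests."""
    cfg, reference, truth = tiny_reference
    normalized = stloc.normalize_counts(reference)
    normalizer = stloc.fit_coord_normalizer(reference.coords)
    spec = stloc.ModelSpec(n_genes=50, hidden_widths=(32, 8), l1_lambda=1e-8)
    train_cfg = stloc.TrainConfig(batch_size=64, max_epochs=60, seed=2)
    model = stloc.train(stloc.build_model(spec, seed=2), normalized, normalizer, train_cfg)
    return normalized, normalizer, model, truth
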