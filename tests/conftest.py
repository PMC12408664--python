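import numpy as np
import pytest

from scdrp.datamodel import ExpressionMatrix, ResponseLabels
from scdrp.pipeline import SmallModelSpec, run_synthetic_pipeline
from scdrp.simulate import SimConfig


def tiny_spec() -> SmallModelSpec:
    """Deliberately small architecture for fast unit-level training runs."""
    return SmallModelSpec(
        bottleneck=16,
        encoder_dims=[32],
        n_tokens=4,
        n_heads=2,
        predictor_dims=[16],
        dae_epochs=40,
        dann_epochs=8,
        pretrain_epochs=60,
        batch_size=64,
    )


def tiny_sim(seed: int = 0, **overrides) -> SimConfig:
    defaults = dict(n_genes=60, n_bulk=120, n_cells=120, n_latent=5,
                    n_markers_per_class=5, seed=seed)
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_trained():
    """One small trained pipeline shared by tests that only need *a* model."""
    result, y_sc, truth = run_synthetic_pipeline(tiny_sim(seed=0), seed=0, spec=tiny_spec())
    return result, y_sc, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, domain="single_cell", layer="counts", prefix="c"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"g{j}" for j in range(values.shape[1])],
        domain=domain,
        layer=layer,
    )


def make_labels(labels, prefix="c", **kw):
    labels = np.asarray(labels)
    return ResponseLabels([f"{prefix}{i}" for i in range(len(labels))], labels, **kw)
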