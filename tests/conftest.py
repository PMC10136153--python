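import numpy as np
import pytest

from scpatch.io import ExpressionMatrix, LabelMap, log_normalize
from scpatch.model import ModelConfig, build_model
from scpatch.simulate import SyntheticSpec, generate


@pytest.fixture
def tiny_counts() -> ExpressionMatrix:
    """2 cells x 3 genes of raw counts."""
    return ExpressionMatrix(
        values=np.array([[1.0, 0.0, 2.0], [0.0, 0.0, 5.0]]),
        gene_ids=["gA", "gB", "gC"],
        cell_ids=["c1", "c2"],
    )


@pytest.fixture(scope="session")
def micro_dataset() -> ExpressionMatrix:
    """Small separable dataset for fast training tests: 120 cells, 256 genes."""
    spec = SyntheticSpec(n_cells=120, n_genes=256, n_types=3,
                         markers_per_type=40, marker_fold=10.0, base_mean=0.3,
                         dispersion=2.0, dropout_rate=0.3, seed=11)
    return log_normalize(generate(spec))


@pytest.fixture
def micro_model_cfg() -> ModelConfig:
    return ModelConfig.desk_preset(n_classes=3, embed_dim=16, depth=1,
                                   n_heads=2, classifier_hidden=(16, 8))


@pytest.fixture
def small_state():
    """Seeded model over 100 genes, 2 classes, for forward-pass tests."""
    lm = LabelMap(["alpha", "beta"])
    cfg = ModelConfig.desk_preset(n_classes=2, patch_size=4, embed_dim=16,
                                  depth=2, n_heads=2)
    return build_model(n_genes=100, label_map=lm, config=cfg, seed=42)
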