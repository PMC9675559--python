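import numpy as np
import pytest

from metimm.io import ExpressionMatrix


@pytest.fixture
def toy_expression() -> ExpressionMatrix:
    """8 genes x 3 samples with distinct values, deterministic."""
    rng = np.random.default_rng(42)
    genes = [f"G{i}" for i in range(1, 9)]
    samples = ["S1", "S2", "S3"]
    return ExpressionMatrix(genes, samples, rng.normal(5, 2, size=(8, 3)))


@pytest.fixture
def planted_module_expression() -> tuple[ExpressionMatrix, list[str]]:
    """A 16-gene coherent module among 50 independent noise genes.

    Module genes share a strong per-sample latent; noise genes are iid.
    Returns (matrix, module gene names).
    """
    rng = np.random.default_rng(7)
    n_samples = 60
    latent = rng.normal(0, 3, n_samples)
    module_genes = [f"MOD{i:02d}" for i in range(16)]
    noise_genes = [f"NOISE{i:02d}" for i in range(50)]
    module = latent[None, :] + rng.normal(0, 0.5, (16, n_samples))
    noise = rng.normal(0, 1, (50, n_samples))
    expr = ExpressionMatrix(
        module_genes + noise_genes,
        [f"S{j}" for j in range(n_samples)],
        np.vstack([module, noise]),
    )
    return expr, module_genes
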