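import numpy as np
import pytest

import aiocnn as ac


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort: 60 samples x 256 genes in 16 blocks."""
    cfg = ac.SyntheticConfig(n_samples=60, n_genes=256, n_blocks=16, seed=7)
    return ac.simulate_cohort(cfg)


def prepare_aios(cohort, n_genes=None, height=None, width=None, channels=1):
    """Run the full preprocessing pipeline on a synthetic cohort."""
    n_genes = n_genes or cohort.expression.shape[1]
    if height is None:
        side = int(np.sqrt(n_genes // channels))
        height = width = side
    order = ac.shared_gene_order(
        cohort.annotation, [cohort.expression.gene_ids], n_genes
    )
    scaled, scaler = ac.rescale_per_gene(
        ac.log2_transform(cohort.expression), order
    )
    pmap = ac.make_pixel_map(order, ac.AIOConfig(height, width, channels))
    return ac.build_aios(scaled, pmap), order, scaler, pmap


@pytest.fixture(scope="session")
def small_aios(small_cohort):
    aios, order, scaler, pmap = prepare_aios(small_cohort)  # 16x16x1
    return aios


@pytest.fixture
def tiny_spec_2d():
    """An 8x8 single-channel spec small enough for sub-second training."""
    return ac.ModelSpec(
        input_shape=(1, 8, 8),
        n_classes=2,
        conv_filters=(2, 2, 3, 3, 4, 4),
        conv1x1_filters=4,
        dense_widths=(8, 6, 4),
        embedding_dim=3,
        global_pool=False,
        batch_norm=False,
        dropout=0.0,
    )
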