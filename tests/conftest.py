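import numpy as np
import pandas as pd
import pytest

from hmivae.io_ingest import ChannelMap, PixelStack, SegmentationMask
from hmivae.synthetic import SyntheticSpec, generate
from hmivae.views import extract_views


def make_channel_map(n_proteins=3, n_background=1):
    rows = [(i, f"protein_{i}", False, False) for i in range(n_proteins)]
    rows.append((n_proteins, "DNA1", True, False))
    rows.append((n_proteins + 1, "DNA2", True, False))
    for j in range(n_background):
        rows.append((n_proteins + 2 + j, f"BG{j}", False, True))
    return ChannelMap(
        pd.DataFrame(
            rows,
            columns=["channel_index", "protein_name", "is_dna_intercalator", "is_background"],
        )
    )


def make_random_sample(seed=0, shape=(20, 20), n_cells=5, n_proteins=3, sample_id="s0"):
    """Small random stack/mask pair with blocky cells for oracle tests."""
    rng = np.random.default_rng(seed)
    h, w = shape
    mask = np.zeros(shape, dtype=np.int64)
    # non-overlapping 3x3 blocks on a coarse grid
    spots = [(y, x) for y in range(1, h - 3, 4) for x in range(1, w - 3, 4)]
    chosen = rng.choice(len(spots), size=n_cells, replace=False)
    for cid, si in enumerate(chosen, start=1):
        y, x = spots[si]
        mask[y : y + 3, x : x + 3] = cid
    n_channels = n_proteins + 3  # + 2 DNA + 1 background
    pixels = rng.gamma(2.0, 2.0, size=(h, w, n_channels))
    stack = PixelStack(pixels, sample_id=sample_id)
    return stack, SegmentationMask(mask, sample_id=sample_id), make_channel_map(n_proteins)


@pytest.fixture(scope="session")
def small_dataset():
    spec = SyntheticSpec(
        n_samples=2, cells_per_sample=40, shape=(64, 64), n_proteins=6, seed=1
    )
    return generate(spec)


@pytest.fixture(scope="session")
def small_views(small_dataset):
    return extract_views(small_dataset.samples, k=5)


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic spec: 4 phenotypes, 3 samples, ~600 cells, seed 0."""
    return generate(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def default_views(default_dataset):
    return extract_views(default_dataset.samples, k=10)


@pytest.fixture(scope="session")
def trained_small(small_views):
    from hmivae.model import ModelConfig, train

    cfg = ModelConfig(
        hidden_size=16, latent_dim=4, batch_size=32, seed=0, max_epochs=30, patience=30
    )
    model, log = train(small_views, cfg)
    return model, log, cfg
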