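import numpy as np
import pandas as pd
import pytest

from hybcal.datamodel_io import ExpressionSet


def make_obs(n_slides: int, protocol: str = "51C") -> pd.DataFrame:
    """Balanced dye-swap design: first half Cy3->sample0, second half swapped."""
    rows = []
    for i in range(n_slides):
        swap = i >= n_slides // 2
        rows.append({"slide": f"s{i + 1}", "dye": "Cy3", "sample": int(swap), "protocol": protocol})
        rows.append({"slide": f"s{i + 1}", "dye": "Cy5", "sample": int(not swap), "protocol": protocol})
    return pd.DataFrame(rows)


def make_es(values, n_slides=None, protocol="51C", gene_ids=None, transform="log2"):
    values = np.asarray(values, dtype=float)
    if n_slides is None:
        n_slides = values.shape[1] // 2
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    return ExpressionSet(
        gene_ids=gene_ids,
        values=values,
        obs=make_obs(n_slides, protocol),
        transform=transform,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_es():
    """2 slides / 4 observations, 4 genes: the smallest valid design."""
    vals = np.arange(16, dtype=float).reshape(4, 4)
    return make_es(vals, n_slides=2)


def planted_two_group_es(
    rng, n_genes=60, n_slides=6, effect=1.0, noise_sd=0.3, informative_fraction=0.5
):
    """Dye-swap set where a fraction of genes separates the two samples."""
    obs = make_obs(n_slides)
    y = obs["sample"].to_numpy()
    base = rng.normal(8.0, 1.0, size=n_genes)
    eff = np.where(np.arange(n_genes) < int(informative_fraction * n_genes), effect, 0.0)
    values = base[:, None] + eff[:, None] * (y[None, :] == 1)
    values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return ExpressionSet(
        gene_ids=[f"g{i}" for i in range(n_genes)], values=values, obs=obs
    )
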