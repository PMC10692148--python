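import numpy as np
import pandas as pd
import pytest

from ribotome.counts import CountMatrix
from ribotome.simulate import DEFAULT_CELL_TYPES, SimConfig

CONDITIONS = ["naive", "dpi2", "dpi10", "dpi42"]


def make_count_matrix(counts: np.ndarray, conditions=None,
                      n_pairs: int | None = None) -> CountMatrix:
    """Wrap a genes x samples array in the standard paired layout.

    Columns are ordered (condition, pair, fraction) with fraction cycling
    fastest; the sample count must be 2 * n_pairs * len(conditions).
    """
    conditions = conditions or CONDITIONS
    n = counts.shape[1]
    if n_pairs is None:
        n_pairs = n // (2 * len(conditions))
    assert n == 2 * n_pairs * len(conditions)
    rows = []
    for c in conditions:
        for k in range(1, n_pairs + 1):
            for fraction in ("total", "OL"):
                rows.append({"sample_id": f"{c}_p{k}_{fraction}",
                             "fraction": fraction, "condition": c,
                             "pair_id": f"{c}_p{k}"})
    samples = pd.DataFrame(rows)
    genes = [f"g{i:05d}" for i in range(1, counts.shape[0] + 1)]
    df = pd.DataFrame(counts.astype(np.int64), index=pd.Index(genes, name="gene_id"),
                      columns=samples["sample_id"].tolist())
    return CountMatrix(df, samples, list(conditions))


def small_sim_config(seed: int = 3, **overrides) -> SimConfig:
    """A fast, fully featured simulation for unit tests."""
    defaults = dict(
        n_genes=1500,
        marker_set_sizes={t: 80 for t in DEFAULT_CELL_TYPES},
        n_regulated_ol=60, n_regulated_shared=30, n_inflammatory=40,
        operon_sizes=(120, 80, 60), lib_size_mean=5e5, seed=seed)
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_experiment():
    from ribotome.simulate import generate_experiment

    config = small_sim_config()
    cm, truth = generate_experiment(config)
    return config, cm, truth
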