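from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from thermode.io_formats import CountMatrix, LibraryDescriptor

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_matrix(
    data: dict[str, list[int]],
    genes: list[str],
    species: str = "TSD",
    stage: int = 22,
    temps: list[str] | None = None,
    n_pooled: int = 10,
) -> CountMatrix:
    """Small deterministic CountMatrix; temperatures default low, high, ..."""
    lib_ids = list(data)
    temps = temps or (["low", "high"] * len(lib_ids))[: len(lib_ids)]
    libraries = [
        LibraryDescriptor(
            library_id=lid,
            species=species,
            stage=stage,
            temperature=temp,
            tissue="gonad",
            n_pooled=n_pooled,
        )
        for lid, temp in zip(lib_ids, temps)
    ]
    frame = pd.DataFrame(
        {lid: np.asarray(vals, dtype=np.int64) for lid, vals in data.items()},
        index=genes,
    )
    frame.index.name = "gene_id"
    return CountMatrix(counts=frame, libraries=libraries)


@pytest.fixture
def two_library_matrix() -> CountMatrix:
    return make_matrix(
        {"L26": [100, 400, 10, 20, 30, 40], "L31": [200, 800, 20, 40, 60, 80]},
        genes=["Tfr", "Hprt1", "g1", "g2", "g3", "g4"],
    )


def skewed_composition_matrix(
    n_genes: int = 2000, seed: int = 11, skew_fold: float = 4.0,
    skew_fraction: float = 0.3,
) -> tuple[CountMatrix, set[str]]:
    """Two libraries with constant housekeeping genes and a high-abundance
    block upregulated in the high-temperature library — the scenario where
    the upper quartile misestimates the scale but housekeeping anchoring
    does not.  Returns the matrix and the truly shifted gene set.
    """
    rng = np.random.default_rng(seed)
    genes = ["Tfr", "Hprt1"] + [f"g{i:04d}" for i in range(1, n_genes - 1)]
    base = rng.lognormal(mean=5.0, sigma=0.6, size=n_genes)
    base[:2] = 800.0
    order = np.argsort(base)[::-1]
    n_skew = int(skew_fraction * n_genes)
    skew_idx = np.array([i for i in order if i >= 2][:n_skew])
    mult = np.ones(n_genes)
    mult[skew_idx] = skew_fold
    low = rng.poisson(base)
    high = rng.poisson(base * mult)
    # keep the anchors exactly constant across libraries
    low[:2] = high[:2] = 800
    matrix = make_matrix(
        {"L26": low.tolist(), "L31": high.tolist()}, genes=genes
    )
    return matrix, {genes[i] for i in skew_idx}
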