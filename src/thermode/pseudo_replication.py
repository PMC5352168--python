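"""Library subsampling as pseudo-replication for consensus DE calling.

Each pooled library is randomly split into k equal-probability subsamples
(k in {2, 3}).  At count level, random assignment of reads to subsamples
is exactly a multinomial split of each gene's count with probabilities
1/k, so the subsamples are technical replicates whose only noise is
multinomial.  Matched subsample pairs across the two temperatures are
then compared gene-by-gene with an exact conditional binomial test —
given the pair's totals N1 and N2, a gene with x1 + x2 counts has
x1 ~ Binomial(x1 + x2, N1/(N1 + N2)) under the null of equal relative
expression — BH-adjusted at a 1% FDR.  The consensus call set keeps the
genes significant with a consistent direction in *all* pairs, an
intersection rule that can only lower the realized false-discovery rate
relative to any single pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .fisher_de import bh_adjust
from .io_formats import CountMatrix, LibraryDescriptor

__all__ = [
    "SubsamplePartition",
    "partition_counts",
    "conditional_binomial_test",
    "consensus_calls",
]

_MASS_GUARD = 1.0 + 1e-7


@dataclass
class SubsamplePartition:
    """k multinomial subsamples of one library, counts conserved exactly."""

    source_library_id: str
    k: int
    seed: int
    matrices: list[CountMatrix]

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if len(self.matrices) != self.k:
            raise ValueError("need exactly k subsample matrices")

    @property
    def subsample_ids(self) -> list[str]:
        return [m.library_ids[0] for m in self.matrices]

    def counts_frame(self) -> pd.DataFrame:
        return pd.concat([m.counts for m in self.matrices], axis=1)

    def manifest_row(self) -> dict:
        totals = [int(m.counts.iloc[:, 0].sum()) for m in self.matrices]
        return {
            "library_id": self.source_library_id,
            "k": self.k,
            "seed": self.seed,
            "subsample_totals": ",".join(str(t) for t in totals),
        }


def partition_counts(
    matrix: CountMatrix, library_id: str, k: int, seed: int
) -> SubsamplePartition:
    """Split one library's counts into k multinomial subsamples.

    Each gene's count n is distributed over the k subsamples with equal
    probabilities 1/k — the count-level equivalent of randomly assigning
    reads.  Deterministic given seed; per-gene sums are conserved exactly.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = matrix.counts[library_id].to_numpy(dtype=np.int64)
    rng = np.random.default_rng(seed)
    split = rng.multinomial(counts, np.full(k, 1.0 / k))  # (n_genes, k)
    source = matrix.descriptor(library_id)
    matrices = []
    for j in range(k):
        sub_id = f"{library_id}.s{j + 1}"
        desc = LibraryDescriptor(
            library_id=sub_id,
            species=source.species,
            stage=source.stage,
            temperature=source.temperature,
            tissue=source.tissue,
            n_pooled=source.n_pooled,
        )
        frame = pd.DataFrame({sub_id: split[:, j]}, index=matrix.counts.index)
        frame.index.name = "gene_id"
        matrices.append(
            CountMatrix(
                counts=frame,
                libraries=[desc],
                provenance=[f"subsample {j + 1}/{k} of {library_id} (seed {seed})"],
            )
        )
    return SubsamplePartition(
        source_library_id=library_id, k=k, seed=seed, matrices=matrices
    )


def conditional_binomial_test(x1: int, x2: int, N1: int, N2: int) -> float:
    """Exact two-sided conditional test of equal relative expression.

    Under the null, x1 ~ Binomial(x1 + x2, N1/(N1 + N2)); the two-sided
    p-value follows the probability-mass convention (sum of outcome
    probabilities not exceeding the observed one, with a 1 + 1e-7 relative
    guard).
    """
    if N1 <= 0 or N2 <= 0:
        raise ValueError("subsample totals must be positive")
    if x1 < 0 or x2 < 0:
        raise ValueError("counts must be non-negative")
    n = x1 + x2
    if n < 1:
        raise ValueError("x1 + x2 must be >= 1")
    pr = N1 / (N1 + N2)
    support = np.arange(n + 1)
    logpmf = binom.logpmf(support, n, pr)
    pmf = np.exp(logpmf - logpmf.max())
    observed = pmf[x1]
    p = pmf[pmf <= observed * _MASS_GUARD].sum() / pmf.sum()
    return float(np.clip(p, np.finfo(float).tiny, 1.0))


def _binomial_p_vec(x1: np.ndarray, n: np.ndarray, pr: float) -> np.ndarray:
    out = np.ones(len(n), dtype=float)
    for i in range(len(n)):
        ni = int(n[i])
        if ni < 1:
            continue
        support = np.arange(ni + 1)
        logpmf = binom.logpmf(support, ni, pr)
        pmf = np.exp(logpmf - logpmf.max())
        observed = pmf[int(x1[i])]
        p = pmf[pmf <= observed * _MASS_GUARD].sum() / pmf.sum()
        out[i] = float(np.clip(p, np.finfo(float).tiny, 1.0))
    return out


def consensus_calls(
    partition_low: SubsamplePartition,
    partition_high: SubsamplePartition,
    alpha: float = 0.01,
) -> dict:
    """Consensus DE genes across matched subsample pairs at FDR ``alpha``.

    Pair i matches the i-th subsample of the low-temperature library with
    the i-th subsample of the high-temperature library.  Per pair, every
    gene with at least one count is tested with the conditional binomial
    test and BH-adjusted; the consensus set holds the genes significant in
    *all* pairs with the same direction in every pair.

    Returns a dict with ``per_pair`` (list of per-pair DataFrames),
    ``pair_sets`` (list of significant gene sets), ``pair_directions``
    and ``consensus`` (the consensus gene set) plus ``consensus_direction``.
    """
    if partition_low.k != partition_high.k:
        raise ValueError(
            f"mismatched k: {partition_low.k} vs {partition_high.k}"
        )
    k = partition_low.k
    genes = partition_low.matrices[0].counts.index
    per_pair: list[pd.DataFrame] = []
    pair_sets: list[set[str]] = []
    pair_directions: list[dict[str, str]] = []
    for i in range(k):
        low = partition_low.matrices[i].counts.iloc[:, 0].to_numpy(np.int64)
        high = partition_high.matrices[i].counts.reindex(genes).iloc[:, 0]
        high = high.fillna(0).to_numpy(np.int64)
        N1, N2 = int(low.sum()), int(high.sum())
        if N1 <= 0 or N2 <= 0:
            raise ValueError("empty subsample total")
        n = low + high
        testable = n >= 1
        p = np.ones(len(genes), dtype=float)
        p[testable] = _binomial_p_vec(low[testable], n[testable], N1 / (N1 + N2))
        q = np.ones(len(genes), dtype=float)
        if testable.any():
            q[testable] = bh_adjust(p[testable])
        # direction: compare within-pair shares low/N1 vs high/N2 exactly
        left = low.astype(np.int64) * N2
        right = high.astype(np.int64) * N1
        direction = np.where(left > right, "low",
                             np.where(right > left, "high", "none"))
        frame = pd.DataFrame(
            {
                "gene_id": genes,
                "pair": i + 1,
                "x_low": low,
                "x_high": high,
                "p": p,
                "q": q,
                "direction": direction,
            }
        )
        per_pair.append(frame)
        sig = (q <= alpha) & testable & (direction != "none")
        pair_sets.append(set(np.asarray(genes)[sig]))
        pair_directions.append(
            dict(zip(np.asarray(genes)[sig], direction[sig]))
        )
    consensus: set[str] = set.intersection(*pair_sets) if pair_sets else set()
    consensus_direction: dict[str, str] = {}
    for g in sorted(consensus):
        dirs = {pair_directions[i][g] for i in range(k)}
        if len(dirs) == 1:
            consensus_direction[g] = dirs.pop()
    consensus = set(consensus_direction)
    return {
        "per_pair": per_pair,
        "pair_sets": pair_sets,
        "pair_directions": pair_directions,
        "consensus": consensus,
        "consensus_direction": consensus_direction,
        "alpha": alpha,
        "k": k,
    }
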