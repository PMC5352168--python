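"""Per-gene Fisher exact tests on the focal-gene vs remaining-genes table.

The unit of observation in this design is one pooled-embryo library per
(species, stage, temperature) cell, so there are no biological replicates
and conventional count-model tests do not apply.  Instead, for each gene
at one stage the two temperature libraries are laid out as a 2x2
contingency table::

                     26°C (low)        31°C (high)
    focal gene X     n11               n12
    remaining genes  n21               n22

and the exact conditional test evaluates the null hypothesis that the
odds ratio theta = pi11*pi22 / (pi12*pi21) equals 1 — i.e. that the focal
gene takes the same share of the library at both temperatures.  Under the
null, n11 given the margins is hypergeometric; the two-sided p-value sums
the probabilities of all tables with the same margins whose probability
does not exceed the observed table's (the probability-mass convention,
with a 1 + 1e-7 relative guard against floating-point strictness).

P-values within one species x stage family are Benjamini-Hochberg
adjusted, and calls are tiered: *stringent* at an FDR-adjusted cutoff of
1e-10 (the unreplicated design makes the exact test anti-conservative
against biological variability, so only extreme signals are trusted) and
*suggestive* at the standard 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix
from .normalization import NormalizedMatrix

__all__ = [
    "ContingencyTable2x2",
    "DEConfig",
    "build_contingency",
    "fisher_two_sided_p",
    "fisher_two_sided_p_vec",
    "bh_adjust",
    "classify_direction",
    "call_de",
]

#: Relative guard when comparing table probabilities to the observed one.
_MASS_GUARD = 1.0 + 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Focal-gene vs remaining-genes counts at the two temperatures."""

    n11: int  # focal gene, low temperature (26°C)
    n12: int  # focal gene, high temperature (31°C)
    n21: int  # remaining genes, low temperature
    n22: int  # remaining genes, high temperature

    def __post_init__(self) -> None:
        for name in ("n11", "n12", "n21", "n22"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def row_focal(self) -> int:
        return self.n11 + self.n12

    @property
    def row_rest(self) -> int:
        return self.n21 + self.n22

    @property
    def col_low(self) -> int:
        return self.n11 + self.n21

    @property
    def col_high(self) -> int:
        return self.n12 + self.n22

    @property
    def total(self) -> int:
        return self.row_focal + self.row_rest

    def sample_odds_ratio(self) -> float:
        """n11*n22 / (n12*n21); inf/nan at zero cells."""
        denom = self.n12 * self.n21
        if denom == 0:
            return float("inf") if self.n11 * self.n22 > 0 else float("nan")
        return (self.n11 * self.n22) / denom


@dataclass(frozen=True)
class DEConfig:
    """Thresholds and input policy for the per-stage exact tests."""

    stringent_alpha: float = 1e-10
    suggestive_alpha: float = 0.05
    input_values: str = "normalized-rounded"  # or "raw"

    def __post_init__(self) -> None:
        if not 0 < self.stringent_alpha <= self.suggestive_alpha <= 1:
            raise ValueError(
                "need 0 < stringent_alpha <= suggestive_alpha <= 1"
            )
        if self.input_values not in ("normalized-rounded", "raw"):
            raise ValueError("input_values must be 'normalized-rounded' or 'raw'")


def _log_factorials(n: int) -> np.ndarray:
    # gammaln(k+1) = log k!; one vectorized call covers the whole range
    return gammaln(np.arange(n + 1, dtype=np.float64) + 1.0)


def _two_sided_from_support(
    logpmf: np.ndarray, observed_index: np.ndarray | int
) -> np.ndarray | float:
    """Probability-mass two-sided p from the full support pmf.

    ``logpmf`` covers every achievable n11 given the margins; the p-value
    for an observed index sums pmf over support points whose probability is
    <= observed * (1 + 1e-7).
    """
    pmf = np.exp(logpmf - logpmf.max())
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    csum = np.cumsum(sorted_pmf)
    total = csum[-1]
    thresholds = pmf[observed_index] * _MASS_GUARD
    pos = np.searchsorted(sorted_pmf, thresholds, side="right")
    p = np.where(pos > 0, csum[np.maximum(pos, 1) - 1], 0.0) / total
    # p >= P(observed table) > 0 mathematically; guard against underflow of
    # the rescaled pmf for extremely significant tables
    return np.clip(p, np.finfo(float).tiny, 1.0)


def fisher_two_sided_p(table: ContingencyTable2x2) -> float:
    """Exact two-sided p for one table (probability-mass convention).

    A table whose focal-gene margin is 0 admits a single configuration and
    returns p = 1.0 (the untestable case).
    """
    r1, c1, N = table.row_focal, table.col_low, table.total
    if N == 0 or r1 == 0 or table.row_rest == 0 or c1 == 0 or table.col_high == 0:
        return 1.0
    lf = _log_factorials(N)
    return float(_fisher_p_with_lf(table.n11, r1, c1, N, lf))


def _fisher_p_with_lf(n11: int, r1: int, c1: int, N: int, lf: np.ndarray) -> float:
    r2 = N - r1
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    k = np.arange(lo, hi + 1)
    logpmf = (
        -lf[k] - lf[r1 - k] - lf[c1 - k] - lf[r2 - c1 + k]
    )  # constant margin terms cancel in the ratio to the max
    return float(_two_sided_from_support(logpmf, int(n11 - lo)))


def fisher_two_sided_p_family(
    row_focal: int, row_rest: int, col_low: int, _lf: np.ndarray | None = None
) -> tuple[int, np.ndarray]:
    """Two-sided p for *every* table sharing the given margins.

    Returns ``(lo, p)`` where ``p[i]`` is the p-value of the table with
    n11 = lo + i; the support runs over all achievable n11.  Useful for
    exhaustive sweeps and for testing many genes that share margins.
    """
    if row_focal < 0 or row_rest < 0 or col_low < 0:
        raise ValueError("margins must be non-negative")
    N = row_focal + row_rest
    if col_low > N:
        raise ValueError("column margin exceeds grand total")
    lo = max(0, col_low - row_rest)
    hi = min(row_focal, col_low)
    if N == 0 or row_focal == 0 or row_rest == 0 or col_low in (0, N):
        return lo, np.ones(hi - lo + 1, dtype=float)
    lf = _lf if _lf is not None else _log_factorials(N)
    k = np.arange(lo, hi + 1)
    logpmf = -lf[k] - lf[row_focal - k] - lf[col_low - k] - lf[row_rest - col_low + k]
    p = _two_sided_from_support(logpmf, np.arange(len(k)))
    return lo, np.asarray(p, dtype=float)


def fisher_two_sided_p_vec(
    n11: np.ndarray, n12: np.ndarray, n21: np.ndarray, n22: np.ndarray
) -> np.ndarray:
    """Vectorized exact two-sided p over many tables.

    One shared log-factorial table serves all tables; each table's
    hypergeometric support is enumerated exactly, so cost is proportional
    to the summed focal-gene margins rather than the grand totals.
    """
    n11 = np.asarray(n11, dtype=np.int64)
    n12 = np.asarray(n12, dtype=np.int64)
    n21 = np.asarray(n21, dtype=np.int64)
    n22 = np.asarray(n22, dtype=np.int64)
    if np.any(n11 < 0) or np.any(n12 < 0) or np.any(n21 < 0) or np.any(n22 < 0):
        raise ValueError("all cells must be non-negative")
    N = n11 + n12 + n21 + n22
    out = np.ones(n11.shape, dtype=float)
    if N.size == 0:
        return out
    lf = _log_factorials(int(N.max()))
    r1 = n11 + n12
    c1 = n11 + n21
    testable = (r1 > 0) & (n21 + n22 > 0) & (c1 > 0) & (n12 + n22 > 0)
    for i in np.nonzero(testable)[0]:
        out[i] = _fisher_p_with_lf(
            int(n11[i]), int(r1[i]), int(c1[i]), int(N[i]), lf
        )
    return out


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_direction(table: ContingencyTable2x2) -> str:
    """Which temperature carries the larger focal-gene share.

    Compares n11/(n11+n21) against n12/(n12+n22) by exact cross
    multiplication; returns "low" (26°C-biased), "high" (31°C-biased) or
    "none" on an exact tie (including untestable zero columns).
    """
    left = table.n11 * (table.n12 + table.n22)
    right = table.n12 * (table.n11 + table.n21)
    if left > right:
        return "low"
    if right > left:
        return "high"
    return "none"


def build_contingency(
    data: NormalizedMatrix | CountMatrix,
    gene: str,
    lib_low: str,
    lib_high: str,
) -> ContingencyTable2x2:
    """Build the focal-gene table for one gene at one stage's contrast.

    Normalized input is rounded half-up to integers first.  Column totals
    cover the *eligible* universe only (genes trimmed by a *99 scheme are
    outside the tested universe and asking for one raises).
    """
    values, trimmed = _integer_values(data)
    if gene in trimmed:
        raise KeyError(f"gene {gene!r} not in tested universe (trimmed by scheme)")
    if gene not in values.index:
        raise KeyError(f"gene {gene!r} absent from matrix")
    eligible = values.loc[[g for g in values.index if g not in trimmed]]
    n11 = int(eligible.at[gene, lib_low])
    n12 = int(eligible.at[gene, lib_high])
    n21 = int(eligible[lib_low].sum()) - n11
    n22 = int(eligible[lib_high].sum()) - n12
    return ContingencyTable2x2(n11=n11, n12=n12, n21=n21, n22=n22)


def _integer_values(
    data: NormalizedMatrix | CountMatrix,
) -> tuple[pd.DataFrame, frozenset[str]]:
    if isinstance(data, NormalizedMatrix):
        return data.rounded(), data.trimmed_genes
    return data.counts, frozenset()


_TIER_ORDER = {"stringent": 0, "suggestive": 1, "ns": 2}


def call_de(
    data: NormalizedMatrix | CountMatrix,
    config: DEConfig | None = None,
    species: Sequence[str] | None = None,
    stages: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Run the per-gene exact tests for every species x stage contrast.

    For each (species, stage) with exactly one library per temperature,
    every eligible gene is laid out against the remaining genes, tested,
    and BH-adjusted within that family.  Genes with zero (rounded) counts
    at both temperatures are untestable: they are reported with p = q = 1,
    tier ``ns``, direction ``none`` and excluded from the BH family so they
    do not dilute the correction.

    Returns a tidy frame with columns gene_id, species, stage, mean_low,
    mean_high, log2fc, p, q, tier, direction.
    """
    config = config or DEConfig()
    values, trimmed = _integer_values(data)
    if isinstance(data, NormalizedMatrix):
        real_values = data.values
        source = data.source
        if config.input_values == "raw":
            values, real_values = source.counts, source.counts.astype(float)
    else:
        real_values = data.counts.astype(float)
        source = data
    eligible_genes = [g for g in values.index if g not in trimmed]
    frame = values.loc[eligible_genes]
    species_list = list(species) if species is not None else source.species
    records: list[pd.DataFrame] = []
    for sp in species_list:
        stage_list = list(stages) if stages is not None else source.stages(sp)
        for stage in stage_list:
            try:
                lib_low = source.find_library(sp, stage, "low").library_id
                lib_high = source.find_library(sp, stage, "high").library_id
            except KeyError as err:
                raise ValueError(
                    f"design cell missing or ambiguous: species={sp}, "
                    f"stage={stage}: {err}"
                ) from None
            records.append(
                _test_family(
                    frame, real_values, eligible_genes, sp, stage,
                    lib_low, lib_high, config,
                )
            )
    if not records:
        raise ValueError("no species/stage contrasts to test")
    result = pd.concat(records, ignore_index=True)
    return result


def _test_family(
    frame: pd.DataFrame,
    real_values: pd.DataFrame,
    genes: list[str],
    sp: str,
    stage: int,
    lib_low: str,
    lib_high: str,
    config: DEConfig,
) -> pd.DataFrame:
    x_low = frame[lib_low].to_numpy(dtype=np.int64)
    x_high = frame[lib_high].to_numpy(dtype=np.int64)
    t_low = int(x_low.sum())
    t_high = int(x_high.sum())
    n21 = t_low - x_low
    n22 = t_high - x_high
    testable = (x_low + x_high) > 0
    p = np.ones(len(genes), dtype=float)
    p[testable] = fisher_two_sided_p_vec(
        x_low[testable], x_high[testable], n21[testable], n22[testable]
    )
    q = np.ones(len(genes), dtype=float)
    if testable.any():
        q[testable] = bh_adjust(p[testable])
    tier = np.where(
        ~testable, "ns",
        np.where(q <= config.stringent_alpha, "stringent",
                 np.where(q <= config.suggestive_alpha, "suggestive", "ns")),
    )
    # direction by exact cross multiplication of the two column shares
    left = x_low.astype(object) * (x_high + n22).astype(object)
    right = x_high.astype(object) * (x_low + n21).astype(object)
    direction = np.where(
        ~testable, "none", np.where(left > right, "low",
                                    np.where(right > left, "high", "none"))
    )
    mean_low = real_values.loc[genes, lib_low].to_numpy(dtype=float)
    mean_high = real_values.loc[genes, lib_high].to_numpy(dtype=float)
    log2fc = np.log2((mean_high + 0.5) / (mean_low + 0.5))
    return pd.DataFrame(
        {
            "gene_id": genes,
            "species": sp,
            "stage": stage,
            "mean_low": mean_low,
            "mean_high": mean_high,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "tier": tier,
            "direction": direction,
        }
    )
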