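"""The four count-normalization schemes compared by the pipeline.

Each scheme produces one positive scale factor per library; normalized
expression is the raw count divided by that factor.  Factors are always
re-centered so their geometric mean across libraries is 1, which keeps
normalized magnitudes near the raw count scale (important because the
downstream exact tests round normalized values back to integers).

* ``UQ100`` — upper-quartile only: each library is scaled by the 75th
  percentile of its nonzero counts.
* ``UQ99`` — upper-quartile after removing the top 1 percentile of genes
  by mean expression from both factor estimation and downstream testing.
* ``UQHK100`` — the mixed upper-quartile + housekeeping scheme: the
  upper-quartile step is computed first and the housekeeping anchoring is
  applied last, so constitutively expressed reference genes (by default
  Tfr and Hprt1) end up exactly equalized across libraries.
* ``UQHK99`` — the mixed scheme with the top-1% trim.

A note on composition: because the upper-quartile factor is exactly
scale-equivariant, a chain of multiplicative factor steps telescopes to
whichever step is applied last.  The combined schemes therefore anchor on
the housekeeping genes (the final step), and the upper-quartile component
is retained in the factor table as a diagnostic — the ratio of the two
components measures how far library composition skews the quantile away
from the housekeeping anchor.  Both step orders can be computed; the
canonical order is the anchoring one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import CountMatrix

__all__ = [
    "NormalizationScheme",
    "NormalizationFactors",
    "NormalizedMatrix",
    "SCHEMES",
    "DEFAULT_HOUSEKEEPING",
    "get_scheme",
    "trim_top_percentile",
    "upper_quartile_factor",
    "housekeeping_factor",
    "apply_scheme",
    "compare_schemes",
]

#: The study's reference genes: Transferrin receptor and hypoxanthine
#: phosphoribosyl transferase 1, constitutively expressed across stages.
DEFAULT_HOUSEKEEPING: frozenset[str] = frozenset({"Tfr", "Hprt1"})


@dataclass(frozen=True)
class NormalizationScheme:
    name: str
    use_housekeeping: bool
    trim_top_fraction: float
    housekeeping_genes: frozenset[str] = DEFAULT_HOUSEKEEPING

    def __post_init__(self) -> None:
        if not 0.0 <= self.trim_top_fraction < 1.0:
            raise ValueError("trim_top_fraction must be in [0, 1)")
        if self.use_housekeeping and not self.housekeeping_genes:
            raise ValueError("housekeeping scheme requires a non-empty gene set")


def _builtin(name: str, hk: bool, trim: float) -> NormalizationScheme:
    return NormalizationScheme(name=name, use_housekeeping=hk, trim_top_fraction=trim)


SCHEMES: dict[str, NormalizationScheme] = {
    "UQ100": _builtin("UQ100", False, 0.0),
    "UQ99": _builtin("UQ99", False, 0.01),
    "UQHK100": _builtin("UQHK100", True, 0.0),
    "UQHK99": _builtin("UQHK99", True, 0.01),
}


def get_scheme(
    name: str, housekeeping_genes: Iterable[str] | None = None
) -> NormalizationScheme:
    """Look up a built-in scheme, optionally overriding the reference genes."""
    try:
        scheme = SCHEMES[name]
    except KeyError:
        raise ValueError(
            f"unknown scheme {name!r}; expected one of {sorted(SCHEMES)}"
        ) from None
    if housekeeping_genes is not None:
        scheme = NormalizationScheme(
            name=scheme.name,
            use_housekeeping=scheme.use_housekeeping,
            trim_top_fraction=scheme.trim_top_fraction,
            housekeeping_genes=frozenset(housekeeping_genes),
        )
    return scheme


@dataclass
class NormalizationFactors:
    """Per-library scale factors and the genes excluded from estimation."""

    hk_factor: pd.Series
    uq_factor: pd.Series
    combined_factor: pd.Series
    trimmed_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name, f in (
            ("hk", self.hk_factor),
            ("uq", self.uq_factor),
            ("combined", self.combined_factor),
        ):
            values = f.to_numpy(dtype=float)
            if not np.all(np.isfinite(values)) or np.any(values <= 0):
                raise ValueError(f"{name}_factor must be strictly positive and finite")

    def as_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "library_id": self.combined_factor.index,
                "hk_factor": self.hk_factor.to_numpy(dtype=float),
                "uq_factor": self.uq_factor.to_numpy(dtype=float),
                "combined_factor": self.combined_factor.to_numpy(dtype=float),
            }
        )


@dataclass
class NormalizedMatrix:
    """Normalized expression with the scheme and factors that produced it."""

    values: pd.DataFrame
    scheme: NormalizationScheme
    factors: NormalizationFactors
    source: CountMatrix

    @property
    def libraries(self):
        return self.source.libraries

    @property
    def trimmed_genes(self) -> frozenset[str]:
        return self.factors.trimmed_genes

    def rounded(self) -> pd.DataFrame:
        """Normalized values rounded half-up to integers (exact-test input)."""
        return pd.DataFrame(
            np.floor(self.values.to_numpy(dtype=float) + 0.5).astype(np.int64),
            index=self.values.index,
            columns=self.values.columns,
        )


def _center_geometric(factors: np.ndarray) -> np.ndarray:
    return factors / np.exp(np.mean(np.log(factors)))


def trim_top_percentile(matrix: CountMatrix, fraction: float) -> frozenset[str]:
    """The ceil(fraction * n_genes) genes with largest mean raw count.

    Boundary ties are broken by lexicographic gene_id so the trimmed set is
    deterministic.  fraction 0 returns the empty set.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0.0:
        return frozenset()
    n_remove = int(np.ceil(fraction * len(matrix.counts.index)))
    means = matrix.counts.mean(axis=1)
    order = sorted(means.index, key=lambda g: (-means[g], g))
    return frozenset(order[:n_remove])


def upper_quartile_factor(
    matrix: CountMatrix | pd.DataFrame, exclude: Iterable[str] = ()
) -> pd.Series:
    """Per-library 75th percentile of nonzero counts, centered to gmean 1.

    The quantile is taken over each library's *nonzero* counts among
    non-excluded genes, with linear interpolation between order statistics.
    """
    frame = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    excluded = set(exclude)
    eligible = frame.loc[[g for g in frame.index if g not in excluded]]
    raw = np.empty(len(frame.columns), dtype=float)
    for j, lib in enumerate(frame.columns):
        col = eligible[lib].to_numpy(dtype=float)
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise ValueError(f"library {lib!r} has no nonzero eligible counts")
        raw[j] = np.quantile(nonzero, 0.75, method="linear")
    return pd.Series(_center_geometric(raw), index=frame.columns, name="uq_factor")


def housekeeping_factor(
    matrix: CountMatrix | pd.DataFrame, hk: Iterable[str]
) -> pd.Series:
    """Housekeeping anchoring factors, centered to geometric mean 1.

    Per library, the factor is the geometric mean over reference genes of
    (value in library / cross-library geometric mean of that gene) — robust
    to a single outlying reference gene and symmetric in the libraries.
    Every reference gene must be present with a nonzero value everywhere.
    """
    frame = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    hk = sorted(set(hk))
    if not hk:
        raise ValueError("housekeeping gene set is empty")
    missing = [g for g in hk if g not in frame.index]
    if missing:
        raise ValueError(f"housekeeping genes absent from matrix: {missing}")
    block = frame.loc[hk].to_numpy(dtype=float)
    zero_mask = block <= 0
    if zero_mask.any():
        offenders = [
            f"{hk[i]}@{frame.columns[j]}" for i, j in zip(*np.nonzero(zero_mask))
        ]
        raise ValueError(f"housekeeping genes with zero counts: {offenders}")
    log_block = np.log(block)
    per_gene_ratio = log_block - log_block.mean(axis=1, keepdims=True)
    factors = np.exp(per_gene_ratio.mean(axis=0))
    return pd.Series(
        _center_geometric(factors), index=frame.columns, name="hk_factor"
    )


def apply_scheme(
    matrix: CountMatrix,
    scheme: NormalizationScheme,
    order: str = "uq_then_hk",
) -> NormalizedMatrix:
    """Normalize a count matrix under one scheme.

    The top-percentile trim (for *99 schemes) is computed first and removes
    those genes from factor estimation; the trimmed genes still receive
    normalized values but are flagged for exclusion from downstream testing.
    For combined schemes the canonical order computes the upper-quartile
    factor on raw counts and then the residual housekeeping factor on
    quartile-adjusted values, so the housekeeping genes are exactly
    anchored.  ``order="hk_then_uq"`` computes the alternative composition
    (which, by scale equivariance of the quantile, ends up equalizing the
    upper quartile instead of the reference genes).
    """
    if order not in ("uq_then_hk", "hk_then_uq"):
        raise ValueError("order must be 'uq_then_hk' or 'hk_then_uq'")
    trimmed = trim_top_percentile(matrix, scheme.trim_top_fraction)
    frame = matrix.counts.astype(float)
    exclude = set(trimmed)
    if not scheme.use_housekeeping:
        uq = upper_quartile_factor(matrix, exclude=exclude)
        hk = pd.Series(1.0, index=frame.columns, name="hk_factor")
        combined = uq.copy()
    elif order == "uq_then_hk":
        uq = upper_quartile_factor(matrix, exclude=exclude)
        adjusted = frame.div(uq, axis=1)
        hk = housekeeping_factor(adjusted, scheme.housekeeping_genes)
        combined = pd.Series(
            _center_geometric((uq * hk).to_numpy(dtype=float)), index=frame.columns
        )
    else:
        hk = housekeeping_factor(matrix, scheme.housekeeping_genes)
        adjusted = frame.div(hk, axis=1)
        uq = upper_quartile_factor(adjusted, exclude=exclude)
        combined = pd.Series(
            _center_geometric((uq * hk).to_numpy(dtype=float)), index=frame.columns
        )
    combined.name = "combined_factor"
    factors = NormalizationFactors(
        hk_factor=hk, uq_factor=uq, combined_factor=combined, trimmed_genes=trimmed
    )
    values = frame.div(combined, axis=1)
    return NormalizedMatrix(values=values, scheme=scheme, factors=factors, source=matrix)


def compare_schemes(
    matrix: CountMatrix,
    schemes: Sequence[NormalizationScheme | str],
    de_config=None,
    species: str | None = None,
    stage: int | None = None,
) -> dict:
    """Run the exact-test pipeline under each scheme on one stage's contrast.

    Returns a report with per-scheme DE gene counts at both significance
    tiers, the stringent-tier DE sets, and pairwise overlap statistics —
    the scheme-comparison analysis behind choosing the housekeeping-anchored
    approach.
    """
    from .comparative_analysis import overlap_sets
    from .fisher_de import DEConfig, call_de

    if len(schemes) < 2:
        raise ValueError("compare_schemes needs at least two schemes")
    config = de_config or DEConfig()
    resolved = [s if isinstance(s, NormalizationScheme) else get_scheme(s)
                for s in schemes]
    if species is None:
        species = matrix.species[0]
    if stage is None:
        stage = matrix.stages(species)[-1]
    rows = []
    stringent_sets: dict[str, set[str]] = {}
    labels: list[str] = []
    for scheme in resolved:
        label = scheme.name
        while label in labels:
            label += "'"
        labels.append(label)
    for label, scheme in zip(labels, resolved):
        normalized = apply_scheme(matrix, scheme)
        results = call_de(
            normalized, config=config, species=[species], stages=[stage]
        )
        stringent = set(results.loc[results["tier"] == "stringent", "gene_id"])
        suggestive = set(
            results.loc[results["tier"].isin(["stringent", "suggestive"]), "gene_id"]
        )
        stringent_sets[label] = stringent
        rows.append(
            {
                "scheme": label,
                "species": species,
                "stage": stage,
                "n_de_stringent": len(stringent),
                "n_de_suggestive": len(suggestive),
            }
        )
    report = {
        "table": pd.DataFrame(rows),
        "stringent_sets": stringent_sets,
        "overlap": overlap_sets(stringent_sets) if len(stringent_sets) <= 4 else None,
    }
    return report
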