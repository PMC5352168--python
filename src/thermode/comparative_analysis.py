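"""Set-level analyses downstream of the per-stage DE calls.

Covers overlap of DE gene sets across normalization schemes, stages and
species (Venn decompositions with Jaccard indices), per-gene direction
profiles across development, a reproducible surrogate for the qualitative
comparison of expression profiles against external qPCR data (the
comparable-stage direction-match fraction), gene-category tagging against
a gene-set catalog, and cross-species concordance over a caller-supplied
shared gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneSetCatalog

__all__ = [
    "OverlapReport",
    "DirectionProfile",
    "overlap_sets",
    "direction_profile",
    "direction_concordance",
    "tag_gene_sets",
    "cross_species_concordance",
]


@dataclass
class OverlapReport:
    """Exact Venn decomposition of 2-4 labeled gene sets."""

    labels: list[str]
    sizes: dict[str, int]
    regions: dict[frozenset[str], int]  # exclusive Venn regions, by member labels
    jaccard: dict[tuple[str, str], float]

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())

    def as_table(self) -> pd.DataFrame:
        rows = [
            {
                "region": "&".join(sorted(members)),
                "size": size,
            }
            for members, size in sorted(
                self.regions.items(), key=lambda kv: ("&".join(sorted(kv[0])))
            )
        ]
        return pd.DataFrame(rows, columns=["region", "size"])


def overlap_sets(sets: Mapping[str, set[str]]) -> OverlapReport:
    """Exact Venn-region counts and pairwise Jaccard indices for 2-4 sets."""
    labels = list(sets)
    if not 2 <= len(labels) <= 4:
        raise ValueError("overlap_sets handles 2-4 sets; use pairwise mode beyond")
    universe = set().union(*sets.values())
    regions: dict[frozenset[str], int] = {}
    for element in universe:
        members = frozenset(l for l in labels if element in sets[l])
        regions[members] = regions.get(members, 0) + 1
    jaccard: dict[tuple[str, str], float] = {}
    for a, b in combinations(labels, 2):
        union = len(sets[a] | sets[b])
        jaccard[(a, b)] = (len(sets[a] & sets[b]) / union) if union else float("nan")
    return OverlapReport(
        labels=labels,
        sizes={l: len(sets[l]) for l in labels},
        regions=regions,
        jaccard=jaccard,
    )


@dataclass
class DirectionProfile:
    """Per-stage temperature-bias calls for one gene in one species.

    Entries are "low" (26°C-biased), "high" (31°C-biased) or "ns", ordered
    to match ``stages``.
    """

    gene_id: str
    species: str
    stages: tuple[int, ...]
    entries: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.entries) != len(self.stages):
            raise ValueError("profile length must equal number of stages")
        bad = set(self.entries) - {"low", "high", "ns"}
        if bad:
            raise ValueError(f"invalid profile entries: {bad}")


def direction_profile(
    results: pd.DataFrame,
    gene: str,
    species: str,
    stages: Sequence[int],
) -> DirectionProfile:
    """Extract one gene's direction-across-development profile.

    Direction is reported only where the call reaches at least the
    suggestive tier; untested or non-significant stages are ``ns``.
    """
    sub = results[(results["gene_id"] == gene) & (results["species"] == species)]
    if sub.empty:
        raise KeyError(f"no results for gene {gene!r} in species {species!r}")
    by_stage = {int(r.stage): r for r in sub.itertuples()}
    entries = []
    for stage in stages:
        row = by_stage.get(int(stage))
        if row is None or row.tier == "ns" or row.direction == "none":
            entries.append("ns")
        else:
            entries.append(row.direction)
    return DirectionProfile(
        gene_id=gene,
        species=species,
        stages=tuple(int(s) for s in stages),
        entries=tuple(entries),
    )


def direction_concordance(
    profile: DirectionProfile,
    reference: DirectionProfile,
    include_ns_agreement: bool = False,
) -> dict:
    """Direction-match fraction over the stages where both profiles call.

    Stages where either side is ``ns`` are excluded from the denominator
    (agreement on "no signal" is not evidence of concordant direction)
    unless ``include_ns_agreement`` is set.  Returns a record with the
    per-stage outcomes, the comparable-stage count and the concordance
    fraction (NaN when no stage is comparable).
    """
    if profile.stages != reference.stages:
        raise ValueError(
            f"mismatched stage sets: {profile.stages} vs {reference.stages}"
        )
    per_stage = []
    n_match = 0
    n_comparable = 0
    for stage, a, b in zip(profile.stages, profile.entries, reference.entries):
        if a == "ns" and b == "ns":
            outcome = "both_ns"
            if include_ns_agreement:
                n_comparable += 1
                n_match += 1
        elif a == "ns" or b == "ns":
            outcome = "one_ns"
            if include_ns_agreement:
                n_comparable += 1
        else:
            n_comparable += 1
            if a == b:
                n_match += 1
                outcome = "match"
            else:
                outcome = "mismatch"
        per_stage.append({"stage": stage, "observed": a, "reference": b,
                          "outcome": outcome})
    concordance = (n_match / n_comparable) if n_comparable else float("nan")
    return {
        "gene_id": profile.gene_id,
        "per_stage": per_stage,
        "n_comparable": n_comparable,
        "n_match": n_match,
        "concordance": concordance,
    }


def tag_gene_sets(results: pd.DataFrame, catalog: GeneSetCatalog) -> pd.DataFrame:
    """Count DE genes per category x species x stage x tier x direction.

    A gene belonging to several categories is counted in each (declared
    multi-membership policy); genes in no category are tallied under
    ``uncategorized``.  Only stringent/suggestive-tier calls are counted.
    """
    if not catalog.sets:
        raise ValueError("empty gene-set catalog")
    de = results[results["tier"].isin(["stringent", "suggestive"])]
    rows: list[dict] = []
    names = list(catalog.sets) + ["uncategorized"]
    # iterate every species x stage present in the results so families with
    # zero DE genes still appear with zero counts
    for (sp, stage), family in results.groupby(["species", "stage"], sort=True):
        group = family[family["tier"].isin(["stringent", "suggestive"])]
        tallies = {
            name: {("stringent", "low"): 0, ("stringent", "high"): 0,
                   ("suggestive", "low"): 0, ("suggestive", "high"): 0}
            for name in names
        }
        for r in group.itertuples():
            cats = catalog.categories_of(r.gene_id) or ["uncategorized"]
            for cat in cats:
                key = (r.tier, r.direction)
                if key in tallies[cat]:
                    tallies[cat][key] += 1
        for name in names:
            t = tallies[name]
            rows.append(
                {
                    "category": name,
                    "species": sp,
                    "stage": int(stage),
                    "stringent_low": t[("stringent", "low")],
                    "stringent_high": t[("stringent", "high")],
                    "suggestive_low": t[("suggestive", "low")],
                    "suggestive_high": t[("suggestive", "high")],
                    "total_de": sum(t.values()),
                }
            )
    return pd.DataFrame(rows)


def cross_species_concordance(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    shared_genes: Sequence[str] | Mapping[str, str],
) -> dict:
    """Direction agreement for shared genes across two species.

    ``shared_genes`` is either a sequence of gene_ids present in both
    result tables or a mapping from species-A ids to species-B ids
    (orthology is an input, never inferred).  A gene is *comparable* at a
    stage when both species call a direction at the suggestive tier or
    better; a gene is concordant when it has at least one comparable stage
    and all comparable stages agree.

    Returns per-gene records plus summary counts.
    """
    if isinstance(shared_genes, Mapping):
        mapping = dict(shared_genes)
    else:
        mapping = {g: g for g in shared_genes}
    if not mapping:
        raise ValueError("empty shared gene set")
    stages = sorted(
        set(results_a["stage"].astype(int)) & set(results_b["stage"].astype(int))
    )
    species_a = results_a["species"].iloc[0]
    species_b = results_b["species"].iloc[0]
    per_gene = []
    n_concordant = n_discordant = n_not_comparable = 0
    for gene_a, gene_b in mapping.items():
        prof_a = direction_profile(results_a, gene_a, species_a, stages)
        prof_b = direction_profile(results_b, gene_b, species_b, stages)
        record = direction_concordance(
            prof_a,
            DirectionProfile(gene_a, species_a, prof_b.stages, prof_b.entries),
        )
        comparable = record["n_comparable"]
        if comparable == 0:
            status = "not_comparable"
            n_not_comparable += 1
        elif record["n_match"] == comparable:
            status = "concordant"
            n_concordant += 1
        else:
            status = "discordant"
            n_discordant += 1
        per_gene.append(
            {
                "gene_a": gene_a,
                "gene_b": gene_b,
                "n_comparable_stages": comparable,
                "n_matching_stages": record["n_match"],
                "status": status,
            }
        )
    return {
        "table": pd.DataFrame(per_gene),
        "n_concordant": n_concordant,
        "n_discordant": n_discordant,
        "n_not_comparable": n_not_comparable,
        "stages": stages,
    }
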