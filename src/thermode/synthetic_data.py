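"""Synthetic pooled-embryo RNA-seq libraries with known ground truth.

The generator emulates the study design end-to-end: two species — a
TSD-like species whose sex determination responds to incubation
temperature (pools of 10 embryos per library) and a GSD-like negative
control (pools of 5) — each sampled at five embryonic stages and two
incubation temperatures, one library per design cell.

The noise hierarchy is declared, not fitted: each embryo's expression of
gene g is a gamma draw around the gene's (temperature-adjusted) base mean
with a negative-binomial-style dispersion (variance = mu^2 * dispersion
among embryos); the pooled library sums the embryo contributions; and
sequencing is a single multinomial draw of the configured depth over the
pooled proportions, so column totals equal the depth exactly.  With
dispersion 0 the two temperature libraries of a null stage are
exchangeable multinomials — the regime in which the exact conditional
test is calibrated.

Temperature effects are stage-specific log2 fold-changes applied to a
configurable fraction of "thermosensitive" genes (split symmetrically:
low temperature gets 2^(-lfc/2), high gets 2^(+lfc/2)), with a coherent
per-gene sign shared across species so cross-species concordance is
meaningful.  Housekeeping genes are constitutive (zero fold-change, low
dispersion) and a configurable fraction of genes is "ncRNA-like"
(low-abundance).  The ground truth (per gene x species x stage fold-change
and category) is returned alongside the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, LibraryDescriptor, merge_counts

__all__ = [
    "SpeciesSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_experiment",
    "draw_pooled_library",
    "evaluate_calls",
]

DEFAULT_STAGES = (9, 12, 15, 19, 22)

#: Default stage-specific effects: the thermosensitive period spans the
#: onset (stage 15) through late development (stages 19, 22).
DEFAULT_TSD_PROFILE: Mapping[int, float] = {15: 2.0, 19: 2.0, 22: 2.0}


@dataclass(frozen=True)
class SpeciesSpec:
    """One species' pooling and temperature-response configuration."""

    name: str
    n_pooled: int
    de_fraction: float = 0.0
    stage_lfc: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_pooled < 1:
            raise ValueError("n_pooled must be >= 1")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")


def default_species() -> tuple[SpeciesSpec, SpeciesSpec]:
    return (
        SpeciesSpec(
            name="TSD", n_pooled=10, de_fraction=0.05, stage_lfc=dict(DEFAULT_TSD_PROFILE)
        ),
        SpeciesSpec(name="GSD", n_pooled=5, de_fraction=0.0, stage_lfc={}),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Design and noise parameters of the synthetic study.

    ``depth`` defaults to 2e6 reads per library — a desk-scale stand-in
    for the deep sequencing of the emulated design; ``dispersion`` is the
    among-embryo squared coefficient of variation (NB-style), 0 for pure
    technical noise.
    """

    n_genes: int = 20000
    stages: tuple[int, ...] = DEFAULT_STAGES
    species: tuple[SpeciesSpec, ...] = field(default_factory=default_species)
    depth: int = 2_000_000
    n_housekeeping: int = 20
    ncrna_fraction: float = 0.05
    dispersion: float = 0.05
    hk_dispersion: float = 0.0
    base_mean_sigma: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion < 0 or self.hk_dispersion < 0:
            raise ValueError("dispersions must be >= 0")
        if not 0.0 <= self.ncrna_fraction <= 1.0:
            raise ValueError("ncrna_fraction must be in [0, 1]")
        if self.n_housekeeping < 2:
            raise ValueError("need at least the two named housekeeping genes")
        if len({sp.name for sp in self.species}) != len(self.species):
            raise ValueError("duplicate species names")
        for sp in self.species:
            unknown = set(sp.stage_lfc) - set(self.stages)
            if unknown:
                raise ValueError(
                    f"stage_lfc stages {sorted(unknown)} outside {self.stages}"
                )


@dataclass
class SyntheticTruth:
    """Ground-truth fold-changes and categories behind a simulated matrix.

    ``lfc[species]`` is a genes x stages frame of true log2 fold-changes
    (high vs low temperature); a gene is truly DE wherever its entry is
    nonzero.  ``category`` tags each gene as housekeeping, thermosensitive,
    ncRNA-like or background.
    """

    lfc: dict[str, pd.DataFrame]
    category: pd.Series
    config: SimulationConfig
    expected_null_count: pd.Series | None = None  # depth * base_mean share

    def de_genes(self, species: str, stage: int) -> set[str]:
        col = self.lfc[species][stage]
        return set(col.index[col != 0.0])

    def as_table(self) -> pd.DataFrame:
        rows = []
        for sp, frame in self.lfc.items():
            for stage in frame.columns:
                col = frame[stage]
                for gene in frame.index:
                    rows.append(
                        {
                            "gene_id": gene,
                            "species": sp,
                            "stage": int(stage),
                            "true_log2fc": float(col[gene]),
                            "is_de": bool(col[gene] != 0.0),
                            "category": self.category[gene],
                        }
                    )
        return pd.DataFrame(rows)


def draw_pooled_library(
    base_means: np.ndarray,
    effects: np.ndarray,
    n_pooled: int,
    dispersion: np.ndarray | float,
    depth: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw one library's gene counts from the pooled-embryo hierarchy.

    ``effects`` multiplies the base means (temperature adjustment); each
    embryo contributes an independent gamma draw with the given NB-style
    dispersion (0 means the embryo contributes the mean exactly); the
    pooled expression vector is renormalized and sequenced as one
    multinomial of size ``depth``, so the column total is exact.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    base_means = np.asarray(base_means, dtype=float)
    effects = np.asarray(effects, dtype=float)
    if base_means.shape != effects.shape:
        raise ValueError("base_means and effects must align")
    if np.any(base_means < 0) or np.any(~np.isfinite(base_means)):
        raise ValueError("base means must be finite and non-negative")
    if not np.any(base_means > 0):
        raise ValueError("all base means are zero")
    if n_pooled < 1:
        raise ValueError("n_pooled must be >= 1")
    if depth <= 0:
        raise ValueError("depth must be positive")
    mu = base_means * effects
    disp = np.broadcast_to(np.asarray(dispersion, dtype=float), mu.shape)
    if np.any(disp < 0):
        raise ValueError("dispersion must be >= 0")
    pooled = np.zeros_like(mu)
    noisy = (disp > 0) & (mu > 0)
    exact = ~noisy
    pooled[exact] = n_pooled * mu[exact]
    if noisy.any():
        shape = 1.0 / disp[noisy]
        scale = mu[noisy] * disp[noisy]
        # sum of n_pooled iid Gamma(shape, scale) = Gamma(n_pooled*shape, scale)
        pooled[noisy] = rng.gamma(shape * n_pooled, scale)
    total = pooled.sum()
    return rng.multinomial(int(depth), pooled / total)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Generate the full study design and its ground truth.

    Deterministic given ``config.seed``: identical configs produce
    bit-identical count matrices and truth tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    # --- gene universe and categories -------------------------------------
    n_hk = config.n_housekeeping
    hk_ids = ["Tfr", "Hprt1"] + [f"HK{i:03d}" for i in range(3, n_hk + 1)]
    n_rest = n - n_hk
    rest_ids = [f"g{i:05d}" for i in range(1, n_rest + 1)]
    gene_ids = hk_ids + rest_ids
    base_means = rng.lognormal(mean=0.0, sigma=config.base_mean_sigma, size=n)
    # housekeeping genes sit comfortably above the upper quartile
    base_means[:n_hk] = 3.0 * np.quantile(base_means, 0.75)
    # ncRNA-like genes: low-abundance tail drawn from the non-hk pool
    n_nc = int(round(config.ncrna_fraction * n))
    nc_idx = rng.choice(np.arange(n_hk, n), size=n_nc, replace=False)
    base_means[nc_idx] *= 0.05
    category = np.array(["background"] * n, dtype=object)
    category[:n_hk] = "housekeeping"
    category[nc_idx] = "ncRNA-like"
    # --- thermosensitive genes: shared candidate order, nested per species
    candidates = np.arange(n_hk, n)
    rng.shuffle(candidates)
    signs = rng.choice([-1.0, 1.0], size=n)
    species_de_idx: dict[str, np.ndarray] = {}
    for sp in config.species:
        n_de = int(np.ceil(sp.de_fraction * n)) if sp.de_fraction > 0 else 0
        species_de_idx[sp.name] = candidates[:n_de]
    thermo_union = sorted({i for idx in species_de_idx.values() for i in idx})
    category[thermo_union] = "thermosensitive"
    dispersion = np.full(n, config.dispersion)
    dispersion[:n_hk] = config.hk_dispersion
    # --- truth tables ------------------------------------------------------
    lfc_tables: dict[str, pd.DataFrame] = {}
    for sp in config.species:
        frame = pd.DataFrame(
            0.0, index=gene_ids, columns=list(config.stages)
        )
        de_idx = species_de_idx[sp.name]
        for stage, magnitude in sp.stage_lfc.items():
            frame.loc[np.asarray(gene_ids, dtype=object)[de_idx], stage] = (
                signs[de_idx] * magnitude
            )
        lfc_tables[sp.name] = frame
    truth = SyntheticTruth(
        lfc=lfc_tables,
        category=pd.Series(category, index=gene_ids, name="category"),
        config=config,
        expected_null_count=pd.Series(
            config.depth * base_means / base_means.sum(),
            index=gene_ids,
            name="expected_null_count",
        ),
    )
    # --- libraries ---------------------------------------------------------
    tables: list[CountMatrix] = []
    for sp in config.species:
        for stage in config.stages:
            lfc = lfc_tables[sp.name][stage].to_numpy(dtype=float)
            for temperature in ("low", "high"):
                half = -0.5 if temperature == "low" else 0.5
                effects = np.power(2.0, half * lfc)
                counts = draw_pooled_library(
                    base_means=base_means,
                    effects=effects,
                    n_pooled=sp.n_pooled,
                    dispersion=dispersion,
                    depth=config.depth,
                    seed=rng,
                )
                lib_id = f"{sp.name}_s{stage}_{'26C' if temperature == 'low' else '31C'}"
                tissue = {9: "trunk", 12: "AKG", 15: "AKG"}.get(stage, "gonad")
                desc = LibraryDescriptor(
                    library_id=lib_id,
                    species=sp.name,
                    stage=stage,
                    temperature=temperature,
                    tissue=tissue,
                    n_pooled=sp.n_pooled,
                )
                frame = pd.DataFrame({lib_id: counts}, index=gene_ids)
                frame.index.name = "gene_id"
                tables.append(
                    CountMatrix(
                        counts=frame,
                        libraries=[desc],
                        provenance=[f"simulated (seed {config.seed})"],
                    )
                )
    matrix = merge_counts(tables)
    return matrix, truth


def evaluate_calls(
    results: pd.DataFrame,
    truth: SyntheticTruth,
    tier: str = "stringent",
) -> pd.DataFrame:
    """Score DE calls against the ground truth, per species x stage.

    ``tier="stringent"`` scores only stringent calls; ``tier="suggestive"``
    scores stringent and suggestive together.  Realized FDR is NaN when
    nothing was called; power is NaN when no gene is truly DE in that
    family.
    """
    if tier not in ("stringent", "suggestive"):
        raise ValueError("tier must be 'stringent' or 'suggestive'")
    accepted = {"stringent"} if tier == "stringent" else {"stringent", "suggestive"}
    truth_genes = set(truth.category.index)
    result_genes = set(results["gene_id"])
    if not result_genes <= truth_genes:
        raise ValueError("results contain genes outside the truth universe")
    rows = []
    for (sp, stage), group in results.groupby(["species", "stage"], sort=True):
        if sp not in truth.lfc:
            raise ValueError(f"species {sp!r} absent from truth")
        called = set(group.loc[group["tier"].isin(accepted), "gene_id"])
        true_de = truth.de_genes(sp, int(stage))
        tp = len(called & true_de)
        fp = len(called - true_de)
        fn = len(true_de - called)
        rows.append(
            {
                "species": sp,
                "stage": int(stage),
                "tier": tier,
                "n_called": len(called),
                "n_true_de": len(true_de),
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "fdr": (fp / len(called)) if called else float("nan"),
                "power": (tp / len(true_de)) if true_de else float("nan"),
            }
        )
    return pd.DataFrame(rows)
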