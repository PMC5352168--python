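"""End-to-end pipeline runner: normalize -> test -> FDR tiers ->
subsample cross-check -> overlap reports, with a machine-readable manifest.

A run is one directory: ``manifest.json`` records the configuration, its
hash, every seed, and the artifact list; subdirectories hold the factor
table, per-species DE tables, the subsample consensus tables, the scheme
comparison and cross-stage overlap reports, and the direction-profile
table.  Re-running an identical configuration reproduces byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .comparative_analysis import overlap_sets
from .fisher_de import DEConfig, call_de
from .io_formats import (
    CountMatrix,
    merge_counts,
    read_htseq_counts,
    read_sample_sheet,
    write_results,
)
from .normalization import apply_scheme, compare_schemes, get_scheme
from .pseudo_replication import consensus_calls, partition_counts
from .synthetic_data import SimulationConfig, simulate_experiment

__all__ = ["PipelineConfig", "run_pipeline", "make_report"]

logger = logging.getLogger("thermode")

_REQUIRED_ARTIFACTS = (
    "factors.tsv",
    "de/de_results.tsv",
    "subsample/consensus.tsv",
    "reports/scheme_comparison.tsv",
    "manifest.json",
)


@dataclass
class PipelineConfig:
    """One run's full configuration (all randomness flows from the seeds)."""

    counts_dir: str | None = None
    sample_sheet: str | None = None
    gene_sets: str | None = None
    simulate: bool = True  # simulate when no counts_dir is given
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    scheme: str = "UQHK100"
    housekeeping_genes: tuple[str, ...] | None = None
    stringent_alpha: float = 1e-10
    suggestive_alpha: float = 0.05
    subsample_k: tuple[int, ...] = (2, 3)
    subsample_alpha: float = 0.01
    subsample_seed: int = 17
    compare_schemes_at: tuple[str, int] | None = None  # (species, stage)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["species"] = [
            asdict(sp) | {"stage_lfc": {str(k): v for k, v in sp.stage_lfc.items()}}
            for sp in self.sim.species
        ]
        # JSON round trip normalizes tuples to lists and keys to strings so
        # the dict is YAML-safe and the hash is representation-stable
        return json.loads(json.dumps(d))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode("utf-8")
        return hashlib.sha256(payload).hexdigest()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        config = cls(**raw)
        if sim_raw is not None:
            from .synthetic_data import SpeciesSpec

            species_raw = sim_raw.pop("species", None)
            if species_raw is not None:
                sim_raw["species"] = tuple(
                    SpeciesSpec(
                        name=sp["name"],
                        n_pooled=sp["n_pooled"],
                        de_fraction=sp.get("de_fraction", 0.0),
                        stage_lfc={int(k): float(v)
                                   for k, v in (sp.get("stage_lfc") or {}).items()},
                    )
                    for sp in species_raw
                )
            if "stages" in sim_raw:
                sim_raw["stages"] = tuple(int(s) for s in sim_raw["stages"])
            config.sim = SimulationConfig(**sim_raw)
        return config


def _load_counts(config: PipelineConfig) -> tuple[CountMatrix, object | None]:
    if config.counts_dir is not None:
        if config.sample_sheet is None:
            raise ValueError("counts_dir requires a sample_sheet")
        descriptors = read_sample_sheet(config.sample_sheet)
        tables = []
        for desc in descriptors:
            path = Path(config.counts_dir) / f"{desc.library_id}.tsv"
            if not path.exists():
                raise FileNotFoundError(f"missing count file {path}")
            tables.append(read_htseq_counts(path, desc))
        return merge_counts(tables), None
    if not config.simulate:
        raise ValueError("no counts_dir given and simulation disabled")
    sim = SimulationConfig(**{**asdict_shallow(config.sim), "seed": config.sim.seed
                              if config.sim.seed else config.seed})
    matrix, truth = simulate_experiment(sim)
    return matrix, truth


def asdict_shallow(sim: SimulationConfig) -> dict:
    return {
        "n_genes": sim.n_genes,
        "stages": sim.stages,
        "species": sim.species,
        "depth": sim.depth,
        "n_housekeeping": sim.n_housekeeping,
        "ncrna_fraction": sim.ncrna_fraction,
        "dispersion": sim.dispersion,
        "hk_dispersion": sim.hk_dispersion,
        "base_mean_sigma": sim.base_mean_sigma,
        "seed": sim.seed,
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full analysis; returns the run directory."""
    out = Path(out_dir)
    for sub in ("de", "subsample", "reports"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    logger.info("stage: load counts")
    matrix, truth = _load_counts(config)

    logger.info("stage: normalization (%s)", config.scheme)
    scheme = get_scheme(config.scheme, config.housekeeping_genes)
    normalized = apply_scheme(matrix, scheme)
    write_results(normalized.factors.as_table(), out / "factors.tsv")
    artifacts.append("factors.tsv")

    logger.info("stage: differential expression")
    de_config = DEConfig(
        stringent_alpha=config.stringent_alpha,
        suggestive_alpha=config.suggestive_alpha,
    )
    results = call_de(normalized, config=de_config)
    results = results.sort_values(["species", "stage", "gene_id"]).reset_index(
        drop=True
    )
    write_results(results, out / "de" / "de_results.tsv")
    artifacts.append("de/de_results.tsv")
    if truth is not None:
        truth_table = truth.as_table().sort_values(
            ["species", "stage", "gene_id"]
        ).reset_index(drop=True)
        write_results(truth_table, out / "de" / "truth.tsv")
        artifacts.append("de/truth.tsv")

    logger.info("stage: subsample consensus")
    consensus_rows = []
    manifest_rows = []
    for sp in matrix.species:
        for stage in matrix.stages(sp):
            lib_low = matrix.find_library(sp, stage, "low").library_id
            lib_high = matrix.find_library(sp, stage, "high").library_id
            for k in config.subsample_k:
                seed_low = _derive_seed(config.subsample_seed, sp, stage, "low", k)
                seed_high = _derive_seed(config.subsample_seed, sp, stage, "high", k)
                part_low = partition_counts(matrix, lib_low, k, seed_low)
                part_high = partition_counts(matrix, lib_high, k, seed_high)
                manifest_rows.append(part_low.manifest_row())
                manifest_rows.append(part_high.manifest_row())
                result = consensus_calls(part_low, part_high,
                                         alpha=config.subsample_alpha)
                for gene in sorted(result["consensus"]):
                    consensus_rows.append(
                        {
                            "species": sp,
                            "stage": stage,
                            "k": k,
                            "gene_id": gene,
                            "direction": result["consensus_direction"][gene],
                        }
                    )
    consensus_table = pd.DataFrame(
        consensus_rows, columns=["species", "stage", "k", "gene_id", "direction"]
    )
    write_results(consensus_table, out / "subsample" / "consensus.tsv")
    artifacts.append("subsample/consensus.tsv")
    write_results(
        pd.DataFrame(manifest_rows,
                     columns=["library_id", "k", "seed", "subsample_totals"]),
        out / "subsample" / "partitions.tsv",
    )
    artifacts.append("subsample/partitions.tsv")

    logger.info("stage: scheme comparison")
    if config.compare_schemes_at is not None:
        cmp_species, cmp_stage = config.compare_schemes_at
    else:
        cmp_species = matrix.species[0]
        cmp_stage = matrix.stages(cmp_species)[-1]
    scheme_report = compare_schemes(
        matrix,
        ["UQ100", "UQ99", "UQHK100", "UQHK99"],
        de_config=de_config,
        species=cmp_species,
        stage=cmp_stage,
    )
    write_results(scheme_report["table"], out / "reports" / "scheme_comparison.tsv")
    artifacts.append("reports/scheme_comparison.tsv")
    if scheme_report["overlap"] is not None:
        write_results(
            scheme_report["overlap"].as_table(),
            out / "reports" / "scheme_overlap_regions.tsv",
        )
        artifacts.append("reports/scheme_overlap_regions.tsv")

    logger.info("stage: cross-stage overlap")
    overlap_rows = []
    for sp in matrix.species:
        stage_sets = {
            f"stage{stage}": set(
                results[
                    (results["species"] == sp)
                    & (results["stage"] == stage)
                    & (results["tier"] == "stringent")
                ]["gene_id"]
            )
            for stage in matrix.stages(sp)
        }
        # Venn machinery handles up to 4 sets; report pairwise beyond that.
        labels = list(stage_sets)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                pair = overlap_sets({a: stage_sets[a], b: stage_sets[b]})
                overlap_rows.append(
                    {
                        "species": sp,
                        "set_a": a,
                        "set_b": b,
                        "size_a": pair.sizes[a],
                        "size_b": pair.sizes[b],
                        "intersection": pair.regions.get(frozenset({a, b}), 0),
                        "jaccard": pair.jaccard[(a, b)],
                    }
                )
    write_results(
        pd.DataFrame(
            overlap_rows,
            columns=["species", "set_a", "set_b", "size_a", "size_b",
                     "intersection", "jaccard"],
        ),
        out / "reports" / "cross_stage_overlap.tsv",
    )
    artifacts.append("reports/cross_stage_overlap.tsv")

    manifest = {
        "thermode_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seeds": {
            "global": config.seed,
            "simulation": config.sim.seed if config.counts_dir is None else None,
            "subsample": config.subsample_seed,
        },
        "artifacts": sorted(artifacts),
    }
    with open(out / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run complete: %s", out)
    return out


def _derive_seed(base: int, species: str, stage: int, temperature: str, k: int) -> int:
    payload = f"{base}:{species}:{stage}:{temperature}:{k}".encode("utf-8")
    return int.from_bytes(hashlib.sha256(payload).digest()[:4], "big") % (2**31)


def make_report(run_dir: str | Path) -> dict:
    """Summarize a completed run from its artifacts.

    Raises if required artifacts are missing; returns per-stage DE counts
    by tier and direction, the scheme comparison, subsample consensus
    counts, and the run's provenance (seeds and config hash) verbatim.
    """
    run = Path(run_dir)
    missing = [a for a in _REQUIRED_ARTIFACTS if not (run / a).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run {run}: missing {missing}")
    with open(run / "manifest.json", "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    results = pd.read_csv(run / "de" / "de_results.tsv", sep="\t")
    de_counts = (
        results.groupby(["species", "stage", "tier", "direction"])
        .size()
        .reset_index(name="n_genes")
    )
    consensus = pd.read_csv(run / "subsample" / "consensus.tsv", sep="\t")
    consensus_counts = (
        consensus.groupby(["species", "stage", "k"]).size().reset_index(name="n_genes")
        if not consensus.empty
        else pd.DataFrame(columns=["species", "stage", "k", "n_genes"])
    )
    scheme_table = pd.read_csv(run / "reports" / "scheme_comparison.tsv", sep="\t")
    report = {
        "config_hash": manifest["config_hash"],
        "seeds": manifest["seeds"],
        "de_counts": de_counts,
        "consensus_counts": consensus_counts,
        "scheme_comparison": scheme_table,
        "n_results": int(len(results)),
    }
    summary = {
        "config_hash": report["config_hash"],
        "seeds": report["seeds"],
        "n_results": report["n_results"],
        "de_counts": de_counts.to_dict(orient="records"),
        "consensus_counts": consensus_counts.to_dict(orient="records"),
        "scheme_comparison": scheme_table.to_dict(orient="records"),
    }
    with open(run / "reports" / "summary.json", "w", encoding="utf-8",
              newline="\n") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
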