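"""Readers and writers for the pipeline's external representations.

Count tables arrive in HTSeq-count output format (``gene_id<TAB>count``,
one line per gene, with ``__``-prefixed summary rows such as
``__no_feature`` at the end).  Library metadata comes from a delimited
sample sheet assigning each sequencing library to a species, an embryonic
stage, an incubation temperature and a pooled-embryo count.  Gene-set
catalogs (housekeeping, heat-shock, ncRNA-like, urogenital-network, ...)
use the standard GMT format.  Result tables are plain tab-separated text
that round-trips losslessly through :func:`read_results`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LibraryDescriptor",
    "CountMatrix",
    "GeneSetCatalog",
    "DesignWarning",
    "DEFAULT_STAGES",
    "DEFAULT_TEMPERATURE_MAP",
    "DEFAULT_TEMPERATURE_LABELS",
    "read_htseq_counts",
    "write_htseq_counts",
    "merge_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gene_sets",
    "write_results",
    "read_results",
]

#: Ordered embryonic stages of the study design.
DEFAULT_STAGES: tuple[int, ...] = (9, 12, 15, 19, 22)

#: Accepted spellings for the two incubation temperatures.  The low
#: temperature is male-producing (MPT, 26°C) and the high temperature is
#: female-producing (FPT, 31°C) in the TSD species; the GSD species uses
#: the same labels without the sex-ratio semantics.
DEFAULT_TEMPERATURE_MAP: Mapping[str, str] = {
    "low": "low",
    "high": "high",
    "26": "low",
    "31": "high",
    "26C": "low",
    "31C": "high",
    "26°C": "low",
    "31°C": "high",
    "MPT": "low",
    "FPT": "high",
}

#: Display labels used when writing result tables.
DEFAULT_TEMPERATURE_LABELS: Mapping[str, str] = {"low": "26C", "high": "31C"}


class DesignWarning(UserWarning):
    """A sample sheet violates the expected one-library-per-cell design."""


@dataclass(frozen=True)
class LibraryDescriptor:
    """One pooled-embryo sequencing library and its design coordinates."""

    library_id: str
    species: str
    stage: int
    temperature: str  # "low" or "high"
    tissue: str = ""
    n_pooled: int = 1

    def __post_init__(self) -> None:
        if self.temperature not in ("low", "high"):
            raise ValueError(
                f"temperature must be 'low' or 'high', got {self.temperature!r}"
            )
        if self.n_pooled < 1:
            raise ValueError("n_pooled must be a positive integer")

    @property
    def design_cell(self) -> tuple[str, int, str]:
        return (self.species, self.stage, self.temperature)


@dataclass
class CountMatrix:
    """Integer gene x library read counts plus library metadata.

    ``counts`` is a genes x libraries DataFrame with unique gene_ids as the
    index and library_ids as columns, in the order of ``libraries``.
    ``qc`` holds the HTSeq ``__``-prefixed summary rows per library; they
    are provenance only and never enter the gene universe.
    """

    counts: pd.DataFrame
    libraries: list[LibraryDescriptor]
    qc: dict[str, dict[str, int]] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [lib.library_id for lib in self.libraries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate library_id in CountMatrix")
        if list(self.counts.columns) != ids:
            raise ValueError("counts columns must match library descriptors")
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate gene_ids: {list(dupes)[:5]}")
        if any(str(g).startswith("__") for g in self.counts.index):
            raise ValueError("HTSeq summary rows must not enter the gene universe")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_ids(self) -> list[str]:
        return [lib.library_id for lib in self.libraries]

    def descriptor(self, library_id: str) -> LibraryDescriptor:
        for lib in self.libraries:
            if lib.library_id == library_id:
                return lib
        raise KeyError(library_id)

    def find_library(
        self, species: str, stage: int, temperature: str
    ) -> LibraryDescriptor:
        """The unique library at a design cell; KeyError if absent or ambiguous."""
        hits = [
            lib
            for lib in self.libraries
            if lib.design_cell == (species, stage, temperature)
        ]
        if len(hits) != 1:
            raise KeyError(
                f"expected exactly one library for (species={species}, "
                f"stage={stage}, temperature={temperature}); found {len(hits)}"
            )
        return hits[0]

    @property
    def species(self) -> list[str]:
        seen: list[str] = []
        for lib in self.libraries:
            if lib.species not in seen:
                seen.append(lib.species)
        return seen

    def stages(self, species: str) -> list[int]:
        return sorted({lib.stage for lib in self.libraries if lib.species == species})


@dataclass
class GeneSetCatalog:
    """Named gene sets (the categories-of-interest machinery)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.sets:
            if not name:
                raise ValueError("blank gene-set name")

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def categories_of(self, gene_id: str) -> list[str]:
        return [name for name, members in self.sets.items() if gene_id in members]


def read_htseq_counts(path: str | Path, library: LibraryDescriptor) -> CountMatrix:
    """Parse one HTSeq-count output file into a single-library CountMatrix.

    ``__``-prefixed summary rows (``__no_feature``, ``__ambiguous``, ...)
    are excluded from the gene universe but retained as QC metadata.
    """
    path = Path(path)
    genes: list[str] = []
    values: list[int] = []
    qc: dict[str, int] = {}
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            gene, count_str = parts
            try:
                count = int(count_str)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: count {count_str!r} is not an integer"
                ) from None
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative count {count}")
            if gene.startswith("__"):
                qc[gene.lstrip("_")] = count
                continue
            if gene in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene!r}")
            seen.add(gene)
            genes.append(gene)
            values.append(count)
    if not genes:
        raise ValueError(f"{path}: no gene rows")
    counts = pd.DataFrame(
        {library.library_id: np.asarray(values, dtype=np.int64)}, index=genes
    )
    counts.index.name = "gene_id"
    return CountMatrix(
        counts=counts,
        libraries=[library],
        qc={library.library_id: qc},
        provenance=[str(path)],
    )


def write_htseq_counts(matrix: CountMatrix, library_id: str, path: str | Path) -> None:
    """Write one library's counts back out in HTSeq-count two-column format."""
    col = matrix.counts[library_id]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gene, count in col.items():
            fh.write(f"{gene}\t{int(count)}\n")
        for key, value in matrix.qc.get(library_id, {}).items():
            fh.write(f"__{key}\t{int(value)}\n")


def merge_counts(tables: Sequence[CountMatrix]) -> CountMatrix:
    """Merge single-library tables over the union gene universe.

    Genes absent from a library are zero-filled; per-library column totals
    are preserved exactly.
    """
    if len(tables) < 2:
        raise ValueError("merge_counts needs at least two tables")
    all_ids = [lid for t in tables for lid in t.library_ids]
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("duplicate library_id across merged tables")
    # Union universe, first-seen order then alphabetical for novel genes is
    # avoided: keep deterministic first-appearance order.
    universe: list[str] = []
    seen: set[str] = set()
    for t in tables:
        for g in t.gene_ids:
            if g not in seen:
                seen.add(g)
                universe.append(g)
    frames = [t.counts.reindex(universe, fill_value=0) for t in tables]
    counts = pd.concat(frames, axis=1).astype(np.int64)
    counts.index.name = "gene_id"
    qc: dict[str, dict[str, int]] = {}
    provenance: list[str] = []
    libraries: list[LibraryDescriptor] = []
    for t in tables:
        qc.update(t.qc)
        provenance.extend(t.provenance)
        libraries.extend(t.libraries)
    return CountMatrix(counts=counts, libraries=libraries, qc=qc, provenance=provenance)


_SHEET_COLUMNS = ("library_id", "species", "stage", "temperature", "tissue", "n_pooled")


def read_sample_sheet(
    path: str | Path,
    stages: Iterable[int] = DEFAULT_STAGES,
    temperature_map: Mapping[str, str] = DEFAULT_TEMPERATURE_MAP,
) -> list[LibraryDescriptor]:
    """Read a TSV/CSV sample sheet into library descriptors.

    Duplicate design cells (two libraries sharing species/stage/temperature)
    are retained but trigger a :class:`DesignWarning`; duplicate library ids
    and stages outside the declared set are errors.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    sheet = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in _SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"{path}: missing sample-sheet columns {missing}")
    stage_set = set(int(s) for s in stages)
    descriptors: list[LibraryDescriptor] = []
    seen_ids: set[str] = set()
    seen_cells: set[tuple[str, int, str]] = set()
    for _, row in sheet.iterrows():
        lid = str(row["library_id"])
        if lid in seen_ids:
            raise ValueError(f"{path}: duplicate library_id {lid!r}")
        seen_ids.add(lid)
        stage = int(row["stage"])
        if stage not in stage_set:
            raise ValueError(
                f"{path}: stage {stage} for {lid!r} outside declared set "
                f"{sorted(stage_set)}"
            )
        temp_label = str(row["temperature"])
        if temp_label not in temperature_map:
            raise ValueError(
                f"{path}: unknown temperature label {temp_label!r} for {lid!r}"
            )
        desc = LibraryDescriptor(
            library_id=lid,
            species=str(row["species"]),
            stage=stage,
            temperature=temperature_map[temp_label],
            tissue="" if pd.isna(row["tissue"]) else str(row["tissue"]),
            n_pooled=int(row["n_pooled"]),
        )
        if desc.design_cell in seen_cells:
            warnings.warn(
                f"{path}: more than one library at design cell {desc.design_cell}",
                DesignWarning,
                stacklevel=2,
            )
        seen_cells.add(desc.design_cell)
        descriptors.append(desc)
    return descriptors


def write_sample_sheet(
    descriptors: Sequence[LibraryDescriptor],
    path: str | Path,
    temperature_labels: Mapping[str, str] = DEFAULT_TEMPERATURE_LABELS,
) -> None:
    rows = [
        {
            "library_id": d.library_id,
            "species": d.species,
            "stage": d.stage,
            "temperature": temperature_labels[d.temperature],
            "tissue": d.tissue,
            "n_pooled": d.n_pooled,
        }
        for d in descriptors
    ]
    pd.DataFrame(rows, columns=list(_SHEET_COLUMNS)).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_gene_sets(path: str | Path) -> GeneSetCatalog:
    """Read a GMT gene-set file (name, description, members...)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            name = parts[0].strip()
            if not name:
                raise ValueError(f"{path}:{lineno}: blank gene-set name")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = frozenset(m for m in parts[2:] if m)
            if not members:
                warnings.warn(
                    f"{path}:{lineno}: gene set {name!r} is empty",
                    UserWarning,
                    stacklevel=2,
                )
            sets[name] = members
            descriptions[name] = parts[1] if len(parts) > 1 else ""
    return GeneSetCatalog(sets=sets, descriptions=descriptions)


def _format_value(value: object) -> str:
    """Render one cell: full-precision floats, scientific below 1e-4."""
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        v = float(value)
        if v != v:  # NaN
            return "NaN"
        if v != 0.0 and abs(v) < 1e-4:
            return f"{v:.17e}"
        return repr(v)
    return str(value)


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as tab-separated UTF-8 text with Unix newlines.

    Column order is preserved as given; floats are rendered at full
    precision (scientific notation below 1e-4) so the matching reader
    reproduces them bit-identically.
    """
    if table.columns.empty:
        raise ValueError("result table has no columns")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(str(c) for c in table.columns) + "\n")
        for row in table.itertuples(index=False):
            fh.write("\t".join(_format_value(v) for v in row) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_results` (types inferred)."""
    return pd.read_csv(path, sep="\t", dtype=None, keep_default_na=True,
                       na_values=["NaN"], float_precision="round_trip")
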