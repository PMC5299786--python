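"""Data model and text readers/writers for functional metagenomic tables.

The central currency of every pipeline stage is the sample x gene-family
abundance matrix (:class:`GeneProfile`), with KEGG-Orthology-style gene
identifiers treated as opaque strings.  Supporting tables are the many-to-many
gene-to-pathway association map (:class:`PathwayMap`), the genome x gene
copy-number matrix (:class:`GenomeContent`), a list of universal single-copy
marker families (:class:`MarkerSet`), and per-sample metadata
(:class:`SampleMetadata`).

All on-disk formats are plain delimited text.  Delimiters are auto-detected
from the file extension (``.csv`` -> comma, anything else -> tab) and can be
overridden.  Missing cells are hard errors, never silent zeros: the matrices
these tools consume are dense, and an empty cell almost always signals an
upstream problem.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("funcvar")

NORMALIZATION_STATES = ("raw", "relative", "copy_number")
MAPPING_SCHEMES = ("fractional", "complete", "empanada")
AGGREGATE_BASES = ("pathway", "cooccurrence")


class FuncvarError(ValueError):
    """Base class for input/contract violations raised by funcvar."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise FuncvarError(f"duplicate {what} IDs: {dups[:10]}")


def _check_matrix(values: np.ndarray, index: Sequence[str], columns: Sequence[str],
                  what: str) -> None:
    if not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))[0]
        raise FuncvarError(
            f"{what}: non-finite value at row {index[bad[0]]!r}, "
            f"column {columns[bad[1]]!r}")
    if (values < 0).any():
        bad = np.argwhere(values < 0)[0]
        raise FuncvarError(
            f"{what}: negative value at row {index[bad[0]]!r}, "
            f"column {columns[bad[1]]!r}")


@dataclass(frozen=True)
class GeneProfile:
    """Sample x gene-family abundance matrix.

    ``data`` rows are samples, columns are gene families.  ``normalization_state``
    tracks what the numbers mean: ``raw`` (arbitrary units / read counts),
    ``relative`` (per-sample fractions summing to 1), or ``copy_number``
    (average copies per genome after single-copy marker normalization).
    """

    data: pd.DataFrame
    normalization_state: str = "raw"

    def __post_init__(self) -> None:
        if self.normalization_state not in NORMALIZATION_STATES:
            raise FuncvarError(
                f"unknown normalization_state {self.normalization_state!r}")
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "gene")
        vals = self.data.to_numpy(dtype=float)
        _check_matrix(vals, list(self.data.index), list(self.data.columns),
                      "GeneProfile")
        if self.normalization_state == "relative" and vals.size:
            sums = vals.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.data.index[np.argmax(np.abs(sums - 1.0))]
                raise FuncvarError(
                    f"relative profile rows must sum to 1; sample {bad!r} "
                    f"sums to {sums[np.argmax(np.abs(sums - 1.0))]:.6g}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_genes(self) -> int:
        return self.data.shape[1]

    def with_values(self, values: np.ndarray, normalization_state: str | None = None) -> "GeneProfile":
        """New profile with the same axes but different values/state."""
        return GeneProfile(
            pd.DataFrame(values, index=self.data.index, columns=self.data.columns),
            normalization_state or self.normalization_state)

    def equals(self, other: "GeneProfile", rtol: float = 1e-12) -> bool:
        return (self.sample_ids == other.sample_ids
                and self.gene_ids == other.gene_ids
                and self.normalization_state == other.normalization_state
                and np.allclose(self.values, other.values, rtol=rtol, atol=0))


@dataclass(frozen=True)
class PathwayProfile:
    """Sample x pathway (or aggregate) abundance matrix."""

    data: pd.DataFrame
    mapping_scheme: str | None = None
    aggregate_basis: str = "pathway"

    def __post_init__(self) -> None:
        if self.mapping_scheme is not None and self.mapping_scheme not in MAPPING_SCHEMES:
            raise FuncvarError(f"unknown mapping_scheme {self.mapping_scheme!r}")
        if self.aggregate_basis not in AGGREGATE_BASES:
            raise FuncvarError(f"unknown aggregate_basis {self.aggregate_basis!r}")
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "pathway")
        _check_matrix(self.data.to_numpy(dtype=float),
                      list(self.data.index), list(self.data.columns),
                      "PathwayProfile")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


class PathwayMap:
    """Many-to-many gene-family -> pathway association.

    A gene is *shared* iff it maps to two or more pathways, *non-shared* iff it
    maps to exactly one.  Non-shared genes anchor the support values of the
    evidence-based mapping scheme.
    """

    def __init__(self, associations: Iterable[tuple[str, str]]):
        assoc = set()
        for pair in associations:
            gene, pathway = pair
            assoc.add((str(gene), str(pathway)))
        self.associations: frozenset[tuple[str, str]] = frozenset(assoc)
        by_gene: dict[str, set[str]] = {}
        by_pathway: dict[str, set[str]] = {}
        for g, p in self.associations:
            by_gene.setdefault(g, set()).add(p)
            by_pathway.setdefault(p, set()).add(g)
        self._by_gene = {g: frozenset(ps) for g, ps in by_gene.items()}
        self._by_pathway = {p: frozenset(gs) for p, gs in by_pathway.items()}

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self._by_gene)

    @property
    def pathways(self) -> frozenset[str]:
        return frozenset(self._by_pathway)

    def pathways_of(self, gene: str) -> frozenset[str]:
        return self._by_gene[gene]

    def genes_of(self, pathway: str) -> frozenset[str]:
        return self._by_pathway[pathway]

    def degree(self, gene: str) -> int:
        return len(self._by_gene[gene])

    @property
    def shared_genes(self) -> frozenset[str]:
        return frozenset(g for g, ps in self._by_gene.items() if len(ps) >= 2)

    @property
    def nonshared_genes(self) -> frozenset[str]:
        return frozenset(g for g, ps in self._by_gene.items() if len(ps) == 1)

    def __len__(self) -> int:
        return len(self.associations)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PathwayMap) and self.associations == other.associations

    def __hash__(self) -> int:
        return hash(self.associations)


@dataclass(frozen=True)
class GenomeContent:
    """Genome x gene-family copy-number matrix (non-negative integers)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "genome")
        _check_unique(self.data.columns, "gene")
        vals = self.data.to_numpy(dtype=float)
        _check_matrix(vals, list(self.data.index), list(self.data.columns),
                      "GenomeContent")
        if not np.array_equal(vals, np.round(vals)):
            bad = np.argwhere(vals != np.round(vals))[0]
            raise FuncvarError(
                f"GenomeContent: non-integer copy number at genome "
                f"{self.data.index[bad[0]]!r}, gene {self.data.columns[bad[1]]!r}")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def copies(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def genome_sizes(self) -> pd.Series:
        """Total gene copies per genome (the simplest genome-size proxy)."""
        return self.data.sum(axis=1)


@dataclass(frozen=True)
class MarkerSet:
    """Universal single-copy marker gene families used as a normalization yardstick."""

    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise FuncvarError("MarkerSet must be non-empty")

    @classmethod
    def from_ids(cls, ids: Iterable[str]) -> "MarkerSet":
        return cls(frozenset(str(i) for i in ids))

    def intersect_profile(self, profile: GeneProfile) -> tuple[list[str], list[str]]:
        """Split markers into (present, missing) against a profile's genes."""
        genes = set(profile.gene_ids)
        present = sorted(self.gene_ids & genes)
        missing = sorted(self.gene_ids - genes)
        return present, missing

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample labels: individual, visit number and optional case/control group."""

    data: pd.DataFrame  # index: sample_id; columns: individual_id, visit, group

    def __post_init__(self) -> None:
        required = {"individual_id", "visit"}
        missing = required - set(self.data.columns)
        if missing:
            raise FuncvarError(f"SampleMetadata missing columns: {sorted(missing)}")
        _check_unique(self.data.index, "sample")
        visits = self.data["visit"].to_numpy()
        if not np.issubdtype(np.asarray(visits).dtype, np.integer):
            raise FuncvarError("visit must be integer")
        if (visits < 1).any():
            raise FuncvarError("visit numbers must be >= 1")
        pairs = list(zip(self.data["individual_id"], self.data["visit"]))
        if len(pairs) != len(set(pairs)):
            raise FuncvarError("(individual_id, visit) pairs must be unique")
        if "group" in self.data.columns:
            groups = set(self.data["group"].dropna().unique())
            bad = groups - {"case", "control"}
            if bad:
                raise FuncvarError(f"group labels must be case/control, got {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def samples_of_visit(self, visit: int) -> pd.Series:
        """individual_id -> sample_id for the given visit."""
        sub = self.data[self.data["visit"] == visit]
        return pd.Series(sub.index.values, index=sub["individual_id"].values)

    def group_of(self) -> pd.Series:
        if "group" not in self.data.columns:
            raise FuncvarError("metadata has no group column")
        return self.data["group"]


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric non-negative distance matrix with zero diagonal."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.data.index) != list(self.data.columns):
            raise FuncvarError("DistanceMatrix index and columns must match")
        _check_unique(self.data.index, "distance-matrix")
        vals = self.data.to_numpy(dtype=float)
        if vals.size:
            if (np.abs(np.diag(vals)) > 0).any():
                raise FuncvarError("DistanceMatrix diagonal must be exactly 0")
            if not np.allclose(vals, vals.T, atol=1e-12, rtol=0):
                raise FuncvarError("DistanceMatrix must be symmetric to 1e-12")
            if (vals < 0).any():
                raise FuncvarError("DistanceMatrix must be non-negative")

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        n = len(self.ids)
        iu = np.triu_indices(n, k=1)
        return self.values[iu]

    @classmethod
    def from_square(cls, values: np.ndarray, ids: Sequence[str]) -> "DistanceMatrix":
        values = np.asarray(values, dtype=float)
        # Symmetrize away floating roundoff and force a clean diagonal.
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        return cls(pd.DataFrame(values, index=list(ids), columns=list(ids)))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def detect_delimiter(path: str | Path, delimiter: str | None = None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def _read_table_lines(path: str | Path, delimiter: str) -> list[list[str]]:
    rows: list[list[str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith("#"):  # provenance / comment header lines
                continue
            rows.append(line.split(delimiter))
    return rows


def _parse_matrix(path: str | Path, delimiter: str | None,
                  what: str) -> pd.DataFrame:
    """Parse a delimited matrix with a header row of column IDs and a leading
    column of row IDs.  Ragged rows, empty cells and non-numeric cells are
    hard errors naming the offending location."""
    delim = detect_delimiter(path, delimiter)
    rows = _read_table_lines(path, delim)
    if len(rows) < 2:
        raise FuncvarError(f"{what}: file {path} has no data rows")
    header = rows[0]
    ncol = len(header)
    col_ids = [c.strip() for c in header[1:]]
    if any(not c for c in col_ids):
        raise FuncvarError(f"{what}: empty column ID in header of {path}")
    row_ids: list[str] = []
    values = np.empty((len(rows) - 1, ncol - 1), dtype=float)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise FuncvarError(
                f"{what}: ragged row at line {i} of {path} "
                f"({len(row)} fields, expected {ncol})")
        rid = row[0].strip()
        if not rid:
            raise FuncvarError(f"{what}: empty row ID at line {i} of {path}")
        row_ids.append(rid)
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if not cell:
                raise FuncvarError(
                    f"{what}: empty cell at row {rid!r}, column {col_ids[j]!r} "
                    f"(line {i} of {path}); missing values are not allowed")
            try:
                values[i - 2, j] = float(cell)
            except ValueError as exc:
                raise FuncvarError(
                    f"{what}: non-numeric cell {cell!r} at row {rid!r}, "
                    f"column {col_ids[j]!r} of {path}") from exc
    return pd.DataFrame(values, index=row_ids, columns=col_ids)


def read_profile(path: str | Path, orientation: str = "genes_in_rows",
                 delimiter: str | None = None) -> GeneProfile:
    """Read a sample x gene abundance matrix from delimited text.

    The default on-disk layout has one row per gene family and one column per
    sample (``genes_in_rows``); pass ``orientation="genes_in_columns"`` for the
    transposed layout.  The returned profile always has samples as rows.
    """
    if orientation not in ("genes_in_rows", "genes_in_columns"):
        raise FuncvarError(f"unknown orientation {orientation!r}")
    frame = _parse_matrix(path, delimiter, "profile")
    if orientation == "genes_in_rows":
        frame = frame.T
    return GeneProfile(frame, normalization_state="raw")


def read_pathway_profile(path: str | Path, orientation: str = "genes_in_rows",
                         delimiter: str | None = None,
                         aggregate_basis: str = "pathway") -> PathwayProfile:
    """Read a sample x pathway abundance matrix (pathways in rows by default)."""
    frame = _parse_matrix(path, delimiter, "pathway profile")
    if orientation == "genes_in_rows":
        frame = frame.T
    return PathwayProfile(frame, mapping_scheme=None, aggregate_basis=aggregate_basis)


def read_genome_content(path: str | Path, orientation: str = "genes_in_columns",
                        delimiter: str | None = None) -> GenomeContent:
    """Read a genome x gene copy-number matrix (genomes in rows by default)."""
    frame = _parse_matrix(path, delimiter, "genome content")
    if orientation == "genes_in_rows":
        frame = frame.T
    return GenomeContent(frame)


def _write_matrix(frame: pd.DataFrame, path: str | Path, delimiter: str | None,
                  corner: str, provenance: Mapping[str, str] | None = None) -> None:
    delim = detect_delimiter(path, delimiter)
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            for key, val in provenance.items():
                fh.write(f"# {key}: {val}\n")
        fh.write(delim.join([corner] + [str(c) for c in frame.columns]) + "\n")
        for rid, row in zip(frame.index, frame.to_numpy()):
            fh.write(delim.join([str(rid)] + [repr(float(v)) for v in row]) + "\n")


def write_profile(profile: GeneProfile | PathwayProfile, path: str | Path,
                  orientation: str = "genes_in_rows", delimiter: str | None = None,
                  provenance: Mapping[str, str] | None = None) -> None:
    """Write a profile as delimited text (genes/pathways in rows by default).

    Values are written with full float precision so that a read/write round
    trip preserves them to better than 1e-12 relative.
    """
    if profile.data.shape[0] == 0 or profile.data.shape[1] == 0:
        raise FuncvarError("refusing to write a profile with an empty axis")
    frame = profile.data.T if orientation == "genes_in_rows" else profile.data
    corner = "gene_id" if isinstance(profile, GeneProfile) else "pathway_id"
    _write_matrix(frame, path, delimiter, corner, provenance)


def write_genome_content(content: GenomeContent, path: str | Path,
                         delimiter: str | None = None) -> None:
    _write_matrix(content.data, path, delimiter, "genome_id")


def read_pathway_map(path: str | Path, delimiter: str | None = None) -> PathwayMap:
    """Read a two-column (gene_id, pathway_id) association table.

    Duplicate identical pairs are deduplicated with a warning; lines that do
    not have exactly two fields are hard errors naming the line number.
    """
    delim = detect_delimiter(path, delimiter)
    pairs: list[tuple[str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(delim)
            if len(fields) != 2:
                raise FuncvarError(
                    f"pathway map: line {lineno} of {path} has "
                    f"{len(fields)} fields, expected 2")
            pairs.append((fields[0].strip(), fields[1].strip()))
    n_unique = len(set(pairs))
    if n_unique < len(pairs):
        warnings.warn(
            f"pathway map {path}: {len(pairs) - n_unique} duplicate "
            f"association(s) collapsed", stacklevel=2)
    return PathwayMap(pairs)


def write_pathway_map(pmap: PathwayMap, path: str | Path,
                      delimiter: str | None = None) -> None:
    delim = detect_delimiter(path, delimiter)
    with open(path, "w", encoding="utf-8") as fh:
        for gene, pathway in sorted(pmap.associations):
            fh.write(f"{gene}{delim}{pathway}\n")


def read_marker_set(path: str | Path) -> MarkerSet:
    """Read a one-ID-per-line marker gene list."""
    ids = []
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    if not ids:
        raise FuncvarError(f"marker list {path} is empty")
    return MarkerSet.from_ids(ids)


def write_marker_set(markers: MarkerSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gid in sorted(markers.gene_ids):
            fh.write(gid + "\n")


def read_metadata(path: str | Path, delimiter: str | None = None) -> SampleMetadata:
    """Read a sample metadata table: sample_id, individual_id, visit[, group]."""
    delim = detect_delimiter(path, delimiter)
    rows = _read_table_lines(path, delim)
    if not rows:
        raise FuncvarError(f"metadata file {path} is empty")
    header = [h.strip() for h in rows[0]]
    if header[0] != "sample_id":
        raise FuncvarError(
            f"metadata {path}: first column must be 'sample_id', got {header[0]!r}")
    records = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise FuncvarError(f"metadata {path}: ragged row at line {lineno}")
        records.append([c.strip() for c in row])
    frame = pd.DataFrame(records, columns=header).set_index("sample_id")
    frame["visit"] = frame["visit"].astype(int)
    if "group" in frame.columns:
        frame["group"] = frame["group"].replace({"": None})
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path: str | Path,
                   delimiter: str | None = None) -> None:
    delim = detect_delimiter(path, delimiter)
    cols = [c for c in ("individual_id", "visit", "group") if c in meta.data.columns]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delim.join(["sample_id"] + cols) + "\n")
        for sid, row in meta.data.iterrows():
            fields = [str(sid)] + ["" if pd.isna(row[c]) else str(row[c]) for c in cols]
            fh.write(delim.join(fields) + "\n")
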