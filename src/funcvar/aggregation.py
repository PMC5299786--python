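"""Genome co-occurrence-based aggregation of gene families.

Gene families that co-occur across bacterial genomes form cohesive genomic
functional units; grouping by co-occurrence rather than by curated pathway
annotation can expose variation that annotation-level pooling averages away.

The pipeline is: binarize the genome x gene copy-number matrix to
presence/absence, compute pairwise Jaccard distances between gene presence
patterns (1 - |intersection| / |union| of the genome sets), cluster with
complete linkage, and cut the dendrogram into a fixed number of aggregates
(by default matched to the number of distinct pathways in the annotation).
Profiles are then summed over any aggregate definition exactly as they are
over pathways.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist

from .profiles_io import (AGGREGATE_BASES, DistanceMatrix, FuncvarError,
                          GeneProfile, GenomeContent, PathwayMap,
                          PathwayProfile, detect_delimiter)

logger = logging.getLogger("funcvar")


@dataclass(frozen=True)
class AggregateDefinition:
    """aggregate_id -> member gene set, plus the basis the grouping came from.

    Co-occurrence aggregates partition the clustered gene set (disjoint and
    covering); pathway-based aggregates may overlap (a shared gene belongs to
    every pathway it is annotated with).
    """

    members: Mapping[str, frozenset[str]]
    basis: str = "cooccurrence"

    def __post_init__(self) -> None:
        if self.basis not in AGGREGATE_BASES:
            raise FuncvarError(f"unknown aggregate basis {self.basis!r}")
        for agg_id, genes in self.members.items():
            if not genes:
                raise FuncvarError(f"aggregate {agg_id!r} is empty")
        if self.basis == "cooccurrence":
            all_genes: list[str] = []
            for genes in self.members.values():
                all_genes.extend(genes)
            if len(all_genes) != len(set(all_genes)):
                raise FuncvarError(
                    "co-occurrence aggregates must be disjoint")

    @property
    def aggregate_ids(self) -> list[str]:
        return list(self.members)

    @property
    def covered_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.members.values():
            out |= genes
        return frozenset(out)

    @classmethod
    def from_pathway_map(cls, pmap: PathwayMap) -> "AggregateDefinition":
        return cls({p: pmap.genes_of(p) for p in sorted(pmap.pathways)},
                   basis="pathway")

    def write(self, path: str | Path, delimiter: str | None = None) -> None:
        delim = detect_delimiter(path, delimiter)
        with open(path, "w", encoding="utf-8") as fh:
            for agg_id in sorted(self.members):
                for gene in sorted(self.members[agg_id]):
                    fh.write(f"{agg_id}{delim}{gene}\n")

    @classmethod
    def read(cls, path: str | Path, basis: str = "cooccurrence",
             delimiter: str | None = None) -> "AggregateDefinition":
        delim = detect_delimiter(path, delimiter)
        members: dict[str, set[str]] = {}
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n").rstrip("\r")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split(delim)
                if len(fields) != 2:
                    raise FuncvarError(
                        f"aggregate file {path}: line {lineno} has "
                        f"{len(fields)} fields, expected 2")
                members.setdefault(fields[0].strip(), set()).add(fields[1].strip())
        return cls({k: frozenset(v) for k, v in members.items()}, basis=basis)


def jaccard_distance(content: GenomeContent) -> DistanceMatrix:
    """Pairwise Jaccard distance between gene presence/absence patterns.

    Presence is copy number > 0.  distance(a, b) = 1 - |G_a & G_b| / |G_a | G_b|
    where G_x is the set of genomes carrying x.  Genes present in no genome are
    excluded with a warning (their union with anything may be empty).  Gene IDs
    are sorted lexicographically in the output so that downstream clustering is
    deterministic regardless of input column order.
    """
    presence = content.copies > 0
    carried = presence.any(axis=0)
    if not carried.any():
        raise FuncvarError("no gene is present in any genome")
    if not carried.all():
        dropped = [g for g, c in zip(content.gene_ids, carried) if not c]
        warnings.warn(
            f"{len(dropped)} gene(s) present in no genome excluded from "
            "Jaccard distance", stacklevel=2)
    genes = sorted(g for g, c in zip(content.gene_ids, carried) if c)
    mat = content.data[genes].to_numpy() > 0
    condensed = pdist(mat.T, metric="jaccard")
    from scipy.spatial.distance import squareform
    return DistanceMatrix.from_square(squareform(condensed), genes)


def cooccurrence_aggregates(dist: DistanceMatrix,
                            n_aggregates: int) -> AggregateDefinition:
    """Cut a complete-linkage dendrogram of the gene distance matrix into
    exactly ``n_aggregates`` clusters.

    ``cut_tree`` is used for the cut, which returns exactly the requested
    number of clusters and is deterministic given the input ordering (the
    distance matrix from :func:`jaccard_distance` is lexicographically
    sorted for this reason).  Aggregates are labeled ``CA0001``... in order
    of their lexicographically smallest member.
    """
    genes = dist.ids
    if not 1 <= n_aggregates <= len(genes):
        raise FuncvarError(
            f"n_aggregates must be in [1, {len(genes)}], got {n_aggregates}")
    if len(genes) == 1:
        labels = np.zeros(1, dtype=int)
    else:
        Z = linkage(dist.condensed(), method="complete")
        labels = cut_tree(Z, n_clusters=n_aggregates).ravel()
    clusters: dict[int, list[str]] = {}
    for gene, lab in zip(genes, labels):
        clusters.setdefault(int(lab), []).append(gene)
    ordered = sorted(clusters.values(), key=lambda gs: min(gs))
    width = max(4, len(str(len(ordered))))
    members = {f"CA{i + 1:0{width}d}": frozenset(gs)
               for i, gs in enumerate(ordered)}
    return AggregateDefinition(members, basis="cooccurrence")


def default_n_aggregates(pmap: PathwayMap) -> int:
    """Match the aggregate count to the number of distinct pathways."""
    return len(pmap.pathways)


def aggregate_abundance(profile: GeneProfile,
                        agg: AggregateDefinition) -> PathwayProfile:
    """Sum gene abundances over each aggregate.

    A gene belonging to several (pathway-basis) aggregates is counted in full
    in each of them — the uniform *complete* convention.  Genes in no
    aggregate are ignored with a logged count.
    """
    profile_genes = set(profile.gene_ids)
    uncovered = profile_genes - agg.covered_genes
    if uncovered:
        logger.info("aggregate_abundance: %d profile gene(s) in no aggregate",
                    len(uncovered))
    agg_ids = sorted(agg.members)
    out = np.zeros((profile.n_samples, len(agg_ids)))
    for j, agg_id in enumerate(agg_ids):
        cols = [g for g in agg.members[agg_id] if g in profile_genes]
        if cols:
            out[:, j] = profile.data[cols].to_numpy(dtype=float).sum(axis=1)
    frame = pd.DataFrame(out, index=profile.sample_ids, columns=agg_ids)
    return PathwayProfile(frame, mapping_scheme="complete",
                          aggregate_basis=agg.basis)
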