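"""Identification and filtering of genome-prevalent gene families.

A gene family that occurs with near-constant copy number in essentially every
genome of a reference set (all sequenced bacteria, or a gut-dwelling subset)
carries little information about which community a sample harbors, yet its
abundance dominates pathway sums.  Such families are flagged by the
coefficient of variation (CoV = sd / mean) of their copy number across the
genome set: prevalent iff CoV < threshold (1.5 by default).

Zeros — genomes that lack the gene entirely — are included in the CoV, so a
low CoV implies the gene is both widespread and copy-number stable.  The
standard deviation uses the n-1 (sample) denominator by default; both choices
are exposed because neither is forced by the definition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles_io import FuncvarError, GeneProfile, GenomeContent

logger = logging.getLogger("funcvar")


@dataclass(frozen=True)
class PrevalentGeneReport:
    """Per-gene CoV and prevalence call over a genome set."""

    table: pd.DataFrame  # index: gene_id; columns: cov, prevalent
    threshold: float
    genome_set_label: str

    def __post_init__(self) -> None:
        expected = self.table["cov"].to_numpy() < self.threshold
        if not (self.table["prevalent"].to_numpy() == expected).all():
            raise FuncvarError("prevalent flags inconsistent with cov < threshold")

    @property
    def prevalent_genes(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["prevalent"]])

    def write(self, path, delimiter: str | None = None) -> None:
        from .profiles_io import detect_delimiter
        delim = detect_delimiter(path, delimiter)
        out = self.table.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(path, sep=delim, index=False)


def copy_number_cov(content: GenomeContent, gene_id: str, ddof: int = 1) -> float:
    """CoV of a gene's copy number across all genomes (zeros included).

    Returns +inf when the mean is zero (gene absent from every genome); the
    +inf sentinel guarantees such genes are never called prevalent.
    """
    if gene_id not in content.data.columns:
        raise FuncvarError(f"gene {gene_id!r} not in genome content matrix")
    col = content.data[gene_id].to_numpy(dtype=float)
    if len(col) < 2:
        raise FuncvarError("CoV requires at least 2 genomes")
    mean = col.mean()
    if mean == 0:
        return float("inf")
    return float(col.std(ddof=ddof) / mean)


def identify_prevalent(content: GenomeContent, threshold: float = 1.5,
                       ddof: int = 1,
                       genome_set_label: str = "all") -> PrevalentGeneReport:
    """Flag every gene in the content matrix with copy-number CoV < threshold.

    The same operation applied to a gut-genome subset of the matrix yields the
    gut-prevalent list; ``genome_set_label`` records which set was used.
    """
    if content.data.shape[0] < 2:
        raise FuncvarError("identify_prevalent requires >= 2 genomes")
    vals = content.copies
    means = vals.mean(axis=0)
    sds = vals.std(axis=0, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = np.where(means > 0, sds / means, np.inf)
    table = pd.DataFrame(
        {"cov": cov, "prevalent": cov < threshold}, index=content.gene_ids)
    return PrevalentGeneReport(table, float(threshold), genome_set_label)


def filter_genes(profile: GeneProfile, exclude: frozenset[str] | set[str]) -> GeneProfile:
    """Drop the given genes from a profile, preserving sample and gene order.

    Excluding genes that are not in the profile is a no-op with a warning.
    Returns a profile that may have zero genes; downstream operations are
    responsible for rejecting empty inputs.
    """
    exclude = set(exclude)
    present = [g for g in profile.gene_ids if g in exclude]
    absent = exclude - set(profile.gene_ids)
    if absent:
        warnings.warn(
            f"{len(absent)} excluded gene(s) not present in profile",
            stacklevel=2)
    keep = [g for g in profile.gene_ids if g not in exclude]
    logger.info("filter_genes: removed %d of %d genes", len(present),
                profile.n_genes)
    if not keep:
        warnings.warn("filter removed every gene from the profile", stacklevel=2)
    return GeneProfile(profile.data[keep], profile.normalization_state)
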