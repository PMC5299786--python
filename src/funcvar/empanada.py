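"""Mapping gene-family abundances to pathway abundances.

Three schemes are implemented for distributing the abundance of *shared* gene
families (families annotated to two or more pathways):

* ``fractional`` — split uniformly: each of a gene's pathways receives
  value / degree.
* ``complete`` — no split: each pathway receives the full value.
* ``empanada`` — evidence-based, sample-specific split.  The *support* of a
  pathway in a sample is the mean abundance of its non-shared gene families
  (families mapped only to that pathway, hence unambiguous evidence for its
  presence).  A shared gene's abundance is then partitioned among its pathways
  proportionally to their support in that sample.

Under every scheme a pathway additionally receives the entire abundance of
each of its non-shared genes.  The analysis is restricted to *eligible*
pathways: at least ``min_nonshared`` non-shared families in the annotation
(a database property, counted from the map, not the profile) and a mean
fractional-mapped relative abundance above ``min_mean_rel_abundance``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles_io import FuncvarError, GeneProfile, PathwayMap, PathwayProfile

logger = logging.getLogger("funcvar")


@dataclass(frozen=True)
class EligibilityFilter:
    """Thresholds restricting which pathways are scored.

    ``min_nonshared`` is a count of non-shared families in the annotation map;
    ``min_mean_rel_abundance`` is a fraction (0.0005 = 0.05%) of total sample
    abundance, averaged over samples under uniform fractional mapping.
    """

    min_nonshared: int = 10
    min_mean_rel_abundance: float = 0.0005

    def __post_init__(self) -> None:
        if self.min_nonshared < 0 or self.min_mean_rel_abundance < 0:
            raise FuncvarError("eligibility thresholds must be >= 0")


def classify_genes(pmap: PathwayMap) -> tuple[frozenset[str], frozenset[str]]:
    """Partition mapped genes into (shared, non-shared) by pathway degree."""
    if len(pmap) == 0:
        raise FuncvarError("empty pathway map")
    return pmap.shared_genes, pmap.nonshared_genes


def _fractional_pathway_values(profile: GeneProfile,
                               pmap: PathwayMap) -> pd.DataFrame:
    """Uniform fractional mapping over ALL pathways (used for eligibility)."""
    pathways = sorted(pmap.pathways)
    out = np.zeros((profile.n_samples, len(pathways)))
    genes = [g for g in profile.gene_ids if g in pmap.genes]
    pw_index = {p: j for j, p in enumerate(pathways)}
    vals = profile.data[genes].to_numpy(dtype=float)
    for i, g in enumerate(genes):
        ps = pmap.pathways_of(g)
        share = 1.0 / len(ps)
        for p in ps:
            out[:, pw_index[p]] += vals[:, i] * share
    return pd.DataFrame(out, index=profile.sample_ids, columns=pathways)


def eligible_pathways(profile: GeneProfile, pmap: PathwayMap,
                      filt: EligibilityFilter = EligibilityFilter()) -> frozenset[str]:
    """Pathways passing both the non-shared-count and abundance thresholds.

    The non-shared count is a property of the annotation map (genes need not
    be present in the profile); the abundance criterion is the mean over
    samples of the pathway's fractional-mapped share of total sample
    abundance.
    """
    totals = profile.values.sum(axis=1)
    if (totals <= 0).any():
        raise FuncvarError("profile has all-zero sample(s); cannot compute "
                           "relative abundance for eligibility")
    _, nonshared = classify_genes(pmap)
    frac = _fractional_pathway_values(profile, pmap)
    mean_rel = (frac.to_numpy() / totals[:, None]).mean(axis=0)
    eligible = set()
    for p, rel in zip(frac.columns, mean_rel):
        n_ns = len(pmap.genes_of(p) & nonshared)
        if n_ns >= filt.min_nonshared and rel > filt.min_mean_rel_abundance:
            eligible.add(p)
    return frozenset(eligible)


def pathway_support(profile: GeneProfile, pmap: PathwayMap,
                    pathways: frozenset[str] | None = None) -> pd.DataFrame:
    """Per-sample pathway support: mean abundance of non-shared genes.

    Only non-shared genes *present in the profile* enter the mean — absent
    genes are annotation gaps, not zeros.  Pathways with no non-shared gene in
    the profile are excluded with a warning.  Returns samples x pathways.
    """
    _, nonshared = classify_genes(pmap)
    if pathways is None:
        pathways = pmap.pathways
    profile_genes = set(profile.gene_ids)
    cols: dict[str, np.ndarray] = {}
    skipped = []
    for p in sorted(pathways):
        genes = sorted(pmap.genes_of(p) & nonshared & profile_genes)
        if not genes:
            skipped.append(p)
            continue
        cols[p] = profile.data[genes].to_numpy(dtype=float).mean(axis=1)
    if skipped:
        warnings.warn(
            f"{len(skipped)} pathway(s) have no non-shared gene in the "
            f"profile and get no support value: {skipped[:5]}", stacklevel=2)
    if not cols:
        raise FuncvarError("no pathway has a computable support value")
    return pd.DataFrame(cols, index=profile.sample_ids)


def map_to_pathways(profile: GeneProfile, pmap: PathwayMap, scheme: str,
                    filt: EligibilityFilter = EligibilityFilter(),
                    keep_ineligible_in_degree: bool = False) -> PathwayProfile:
    """Convert a gene profile into a pathway profile under a mapping scheme.

    Eligibility is applied before mapping.  By default a shared gene's degree
    (and, for the evidence-based scheme, its support denominator) counts only
    eligible pathways, so abundance mass is conserved over the eligible set;
    ``keep_ineligible_in_degree=True`` restores full-annotation degrees, in
    which case shares routed to ineligible pathways are dropped.

    For the evidence-based scheme, a shared gene whose eligible pathways all
    have zero support in some sample falls back to a uniform fractional split
    for that gene/sample (logged) — discarding its abundance would break mass
    conservation.
    """
    if scheme not in ("fractional", "complete", "empanada"):
        raise FuncvarError(f"unknown mapping scheme {scheme!r}")
    shared, nonshared = classify_genes(pmap)
    eligible = sorted(eligible_pathways(profile, pmap, filt))
    if not eligible:
        raise FuncvarError("no pathway passes the eligibility filter")
    eligible_set = frozenset(eligible)
    pw_index = {p: j for j, p in enumerate(eligible)}
    profile_genes = set(profile.gene_ids)
    n_s = profile.n_samples
    out = np.zeros((n_s, len(eligible)))

    # Non-shared genes contribute their full abundance to their one pathway
    # (if that pathway is eligible).
    for g in sorted(nonshared & profile_genes):
        (p,) = pmap.pathways_of(g)
        if p in pw_index:
            out[:, pw_index[p]] += profile.data[g].to_numpy(dtype=float)

    shared_present = sorted(shared & profile_genes)
    # Per shared gene: the eligible pathways it maps to, and its degree.
    gene_targets: list[list[int]] = []
    gene_degree: list[int] = []
    kept_genes: list[str] = []
    for g in shared_present:
        ps = pmap.pathways_of(g)
        targets = [pw_index[p] for p in sorted(ps & eligible_set)]
        if not targets:
            continue
        kept_genes.append(g)
        gene_targets.append(targets)
        gene_degree.append(len(ps) if keep_ineligible_in_degree else len(targets))

    if not kept_genes:
        frame = pd.DataFrame(out, index=profile.sample_ids, columns=eligible)
        return PathwayProfile(frame, mapping_scheme=scheme)

    X = profile.data[kept_genes].to_numpy(dtype=float)  # samples x shared genes

    if scheme == "complete":
        for i, targets in enumerate(gene_targets):
            for j in targets:
                out[:, j] += X[:, i]
    elif scheme == "fractional":
        for i, targets in enumerate(gene_targets):
            share = 1.0 / gene_degree[i]
            for j in targets:
                out[:, j] += X[:, i] * share
    else:  # empanada
        if not (nonshared & profile_genes):
            raise FuncvarError(
                "evidence-based mapping needs non-shared genes in the profile "
                "to compute support values")
        support = pathway_support(profile, pmap, pathways=eligible_set)
        S = np.zeros((n_s, len(eligible)))
        for p in support.columns:
            S[:, pw_index[p]] = support[p].to_numpy()
        n_fallback = 0
        for i, targets in enumerate(gene_targets):
            sup = S[:, targets]                      # samples x targets
            denom = sup.sum(axis=1)
            ok = denom > 0
            if ok.any():
                weights = np.zeros_like(sup)
                weights[ok] = sup[ok] / denom[ok, None]
                for t, j in enumerate(targets):
                    out[ok, j] += X[ok, i] * weights[ok, t]
            if (~ok).any():
                # zero support across every eligible pathway of this gene in
                # these samples: uniform fallback keeps mass conserved
                n_fallback += int((~ok).sum())
                share = 1.0 / gene_degree[i]
                for j in targets:
                    out[~ok, j] += X[~ok, i] * share
        if n_fallback:
            logger.info("map_to_pathways: uniform fallback used for %d "
                        "gene/sample pairs with zero support", n_fallback)

    frame = pd.DataFrame(out, index=profile.sample_ids, columns=eligible)
    return PathwayProfile(frame, mapping_scheme=scheme)
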