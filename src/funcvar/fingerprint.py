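"""Function-based metagenomic codes for re-identifying individuals.

An individual's *metagenomic code* is a small ordered set of gene families
(k = 20 by default) that are maximally specific to that individual at a
baseline visit: among the genes for which the individual holds the strict
community-wide maximum relative abundance, the k with the largest ratio to
the runner-up individual are selected.  Codes are pairwise disjoint by
construction (a gene has at most one strict argmax individual).

A later visit-2 sample is scored against the codes: for every code gene, the
visit-2 sample holding the strict maximum relative abundance earns one point
for the code's owner.  Each visit-2 sample is then assigned to the individual
with the highest agreement score (ties -> unassigned, counted incorrect).
Agreement scores are bounded by the code size k.

Ties are broken conservatively throughout: a tie for the maximum abundance
disqualifies the gene (construction) or skips the increment (scoring), and a
tied best agreement score leaves the sample unassigned.  Ratio ranking treats
a zero runner-up abundance as an infinite ratio, ranked above all finite
ratios (ordered among themselves by own abundance descending, then gene ID).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalization import relative_normalize, single_copy_normalize
from .profiles_io import FuncvarError, GeneProfile, MarkerSet, SampleMetadata


@dataclass(frozen=True)
class MetagenomicCode:
    individual_id: str
    marker_genes: tuple[str, ...]   # ordered, best-ratio first
    ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.marker_genes) != len(set(self.marker_genes)):
            raise FuncvarError("code markers must be unique")
        if len(self.marker_genes) != len(self.ratios):
            raise FuncvarError("markers and ratios length mismatch")

    def __len__(self) -> int:
        return len(self.marker_genes)


@dataclass(frozen=True)
class MetagenomicCodeSet:
    codes: dict[str, MetagenomicCode]   # individual_id -> code
    k: int

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for code in self.codes.values():
            overlap = seen & set(code.marker_genes)
            if overlap:
                raise FuncvarError(f"codes are not disjoint: {sorted(overlap)[:5]}")
            seen |= set(code.marker_genes)

    @property
    def union_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for code in self.codes.values():
            out |= set(code.marker_genes)
        return frozenset(out)

    def owner_of(self, gene: str) -> str:
        for ind, code in self.codes.items():
            if gene in code.marker_genes:
                return ind
        raise KeyError(gene)


@dataclass(frozen=True)
class IdentificationResult:
    """Per visit-2 sample: assigned individual, score, correctness."""

    table: pd.DataFrame  # index sample_id; assigned_individual, true_individual,
                         # agreement_score, correct
    k: int

    @property
    def accuracy(self) -> float:
        return float(self.table["correct"].mean())


def _normalized_values(profile: GeneProfile, mode: str,
                       markers: MarkerSet | None) -> GeneProfile:
    if mode == "relative":
        return relative_normalize(profile)
    if mode == "single_copy":
        if markers is None:
            raise FuncvarError("single_copy fingerprint mode requires markers")
        return single_copy_normalize(profile, markers)
    raise FuncvarError(f"unknown fingerprint normalization mode {mode!r}")


def _visit_samples(profile: GeneProfile, meta: SampleMetadata,
                   visit: int) -> pd.Series:
    mapping = meta.samples_of_visit(visit)
    mapping = mapping[mapping.isin(profile.sample_ids)]
    if mapping.empty:
        raise FuncvarError(f"no visit-{visit} samples found in profile")
    return mapping


def build_codes(visit1: GeneProfile, meta: SampleMetadata, k: int = 20,
                mode: str = "relative",
                markers: MarkerSet | None = None) -> MetagenomicCodeSet:
    """Construct per-individual codes from the visit-1 profile.

    For each gene the strict-maximum individual (if any) is a candidate owner,
    ranked by the ratio of their abundance to the runner-up's.  Individuals
    with fewer than k candidate genes get a shorter code with a warning.
    """
    if k < 1:
        raise FuncvarError("k must be >= 1")
    mapping = _visit_samples(visit1, meta, visit=1)
    if len(mapping) < 2:
        raise FuncvarError("need >= 2 individuals to build codes")
    individuals = list(mapping.index)
    sub = GeneProfile(visit1.data.loc[list(mapping.values)],
                      visit1.normalization_state)
    vals = _normalized_values(sub, mode, markers).values  # individuals x genes
    genes = sub.gene_ids
    order = np.argsort(-vals, axis=0)
    top_idx = order[0]
    top = vals[top_idx, np.arange(len(genes))]
    second = vals[order[1], np.arange(len(genes))]
    candidates: dict[str, list[tuple[str, float, float]]] = {i: [] for i in individuals}
    for j, gene in enumerate(genes):
        if top[j] <= second[j]:        # tie for the maximum: gene disqualified
            continue
        owner = individuals[top_idx[j]]
        ratio = float("inf") if second[j] == 0 else float(top[j] / second[j])
        candidates[owner].append((gene, ratio, float(top[j])))
    codes: dict[str, MetagenomicCode] = {}
    for ind in individuals:
        cand = candidates[ind]
        # infinite ratios first (own abundance desc, then gene ID); finite
        # ratios by ratio desc, then own abundance desc, then gene ID
        cand.sort(key=lambda c: (not np.isinf(c[1]), -c[1] if np.isfinite(c[1]) else 0.0,
                                 -c[2], c[0]))
        if len(cand) < k:
            warnings.warn(
                f"individual {ind!r} has only {len(cand)} candidate gene(s); "
                f"code truncated below k={k}", stacklevel=2)
        chosen = cand[:k]
        codes[ind] = MetagenomicCode(
            ind, tuple(c[0] for c in chosen), tuple(c[1] for c in chosen))
    return MetagenomicCodeSet(codes, k)


def agreement_scores(codeset: MetagenomicCodeSet, visit2: GeneProfile,
                     meta: SampleMetadata, mode: str = "relative",
                     markers: MarkerSet | None = None) -> pd.DataFrame:
    """Score visit-2 samples against the codes.

    Returns a (visit-2 sample x individual) integer matrix.  For each code
    gene present in the visit-2 profile, the sample holding the strict maximum
    abundance earns one point for the gene's code owner; ties earn nothing.
    """
    mapping = _visit_samples(visit2, meta, visit=2)
    sub = GeneProfile(visit2.data.loc[list(mapping.values)],
                      visit2.normalization_state)
    vals = _normalized_values(sub, mode, markers).values
    sample_ids = sub.sample_ids
    genes = sub.gene_ids
    gene_pos = {g: j for j, g in enumerate(genes)}
    individuals = list(codeset.codes)
    scores = pd.DataFrame(0, index=sample_ids, columns=individuals, dtype=int)
    missing = 0
    for ind, code in codeset.codes.items():
        for gene in code.marker_genes:
            j = gene_pos.get(gene)
            if j is None:
                missing += 1
                continue
            col = vals[:, j]
            best = col.max()
            holders = np.flatnonzero(col == best)
            if len(holders) != 1:
                continue
            scores.loc[sample_ids[holders[0]], ind] += 1
    if missing:
        warnings.warn(f"{missing} code gene(s) absent from visit-2 profile "
                      "skipped", stacklevel=2)
    return scores


def identify(codeset: MetagenomicCodeSet, visit2: GeneProfile,
             meta: SampleMetadata, mode: str = "relative",
             markers: MarkerSet | None = None) -> IdentificationResult:
    """Assign each visit-2 sample to the individual with the top agreement
    score (strict argmax; ties leave the sample unassigned and incorrect)."""
    scores = agreement_scores(codeset, visit2, meta, mode, markers)
    true_ind = meta.data.loc[scores.index, "individual_id"]
    rows = []
    for sid in scores.index:
        row = scores.loc[sid]
        best = row.max()
        holders = row.index[row == best]
        assigned = holders[0] if len(holders) == 1 else None
        correct = assigned is not None and assigned == true_ind[sid]
        rows.append((sid, assigned, true_ind[sid], int(best), bool(correct)))
    table = pd.DataFrame(
        rows, columns=["sample_id", "assigned_individual", "true_individual",
                       "agreement_score", "correct"]).set_index("sample_id")
    return IdentificationResult(table, codeset.k)


def accuracy_sweep(visit1: GeneProfile, visit2: GeneProfile,
                   meta: SampleMetadata, k_values=range(1, 21),
                   mode: str = "relative",
                   markers: MarkerSet | None = None) -> pd.DataFrame:
    """Identification accuracy for each code size k.

    Accuracy is not guaranteed to be monotone in k; the full table is
    reported.  Candidate ranking is k-independent, so codes for smaller k are
    prefixes of the k-max code.
    """
    k_values = list(k_values)
    if not k_values:
        raise FuncvarError("k_values must be non-empty")
    if any(k < 1 for k in k_values):
        raise FuncvarError("all k values must be >= 1")
    full = build_codes(visit1, meta, k=max(k_values), mode=mode, markers=markers)
    rows = []
    for k in k_values:
        codes = {ind: MetagenomicCode(ind, code.marker_genes[:k], code.ratios[:k])
                 for ind, code in full.codes.items()}
        res = identify(MetagenomicCodeSet(codes, k), visit2, meta, mode, markers)
        rows.append((k, res.accuracy))
    return pd.DataFrame(rows, columns=["k", "accuracy"]).set_index("k")
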