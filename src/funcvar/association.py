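"""Case/control association scoring of pathway profiles.

Each pathway is tested for a case-vs-control abundance shift with a two-sided
Wilcoxon rank-sum (Mann-Whitney) test.  The disease-association score is the
signed standardized rank-sum statistic z (tie-corrected; positive = enriched
in cases), with Benjamini-Hochberg FDR control across pathways.  Being
rank-based, the scores are invariant to any monotone per-pathway transform of
the abundances.

Comparing the association results of two processing pipelines (e.g. the
standard relative-normalized / unfiltered / uniform-mapped pipeline against
the revised marker-normalized / prevalence-filtered / evidence-mapped one)
reports both the overall agreement of the scores and the pathways that cross
the significance boundary in exactly one pipeline — the "hidden association"
pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .profiles_io import FuncvarError, PathwayProfile, SampleMetadata


@dataclass(frozen=True)
class AssociationResult:
    """Per-pathway association statistics.

    ``table`` columns: statistic (signed rank-sum z), p, q (BH-adjusted),
    direction (enriched_in_case / depleted_in_case / none).
    """

    table: pd.DataFrame

    def significant(self, alpha: float = 0.05) -> frozenset[str]:
        return frozenset(self.table.index[self.table["q"] < alpha])


def _signed_ranksum_z(case: np.ndarray, control: np.ndarray) -> float:
    """Tie-corrected standardized Mann-Whitney statistic; >0 means the case
    group tends to have larger values."""
    n1, n2 = len(case), len(control)
    pooled = np.concatenate([case, control])
    ranks = sps.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0
    return float((u1 - mu) / np.sqrt(var))


def pathway_association(profile: PathwayProfile,
                        meta: SampleMetadata) -> AssociationResult:
    """Two-sided rank-sum test of each pathway against case/control labels.

    The p-value comes from scipy's Mann-Whitney implementation (exact when
    sample sizes permit and there are no ties, normal approximation
    otherwise); the reported statistic is the signed standardized z.
    """
    groups = meta.group_of()
    samples = [s for s in profile.sample_ids if s in groups.index]
    labels = groups.loc[samples]
    case_ids = [s for s in samples if labels[s] == "case"]
    control_ids = [s for s in samples if labels[s] == "control"]
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise FuncvarError(
            f"need >= 2 samples per group, got {len(case_ids)} case / "
            f"{len(control_ids)} control")
    case = profile.data.loc[case_ids].to_numpy(dtype=float)
    control = profile.data.loc[control_ids].to_numpy(dtype=float)
    stats_, ps = [], []
    for j in range(profile.data.shape[1]):
        z = _signed_ranksum_z(case[:, j], control[:, j])
        if z == 0.0 and np.all(case[:, j] == case[0, j]) \
                and np.all(control[:, j] == case[0, j]):
            p = 1.0  # all values identical: no evidence either way
        else:
            pooled = np.concatenate([case[:, j], control[:, j]])
            no_ties = len(np.unique(pooled)) == len(pooled)
            method = ("exact" if no_ties and max(len(case), len(control)) <= 12
                      else "asymptotic")
            _, p = sps.mannwhitneyu(case[:, j], control[:, j],
                                    alternative="two-sided", method=method)
        stats_.append(z)
        ps.append(float(p))
    qs = multipletests(ps, method="fdr_bh")[1]
    direction = np.where(np.array(stats_) > 0, "enriched_in_case",
                         np.where(np.array(stats_) < 0, "depleted_in_case",
                                  "none"))
    table = pd.DataFrame(
        {"statistic": stats_, "p": ps, "q": qs, "direction": direction},
        index=profile.pathway_ids)
    return AssociationResult(table)


@dataclass(frozen=True)
class PipelineComparison:
    """Agreement between association results of two pipelines."""

    r: float
    table: pd.DataFrame          # shared pathways, statistics + q from both
    only_in_a: frozenset[str]    # significant (q < alpha) only in pipeline A
    only_in_b: frozenset[str]
    alpha: float


def compare_pipelines(res_a: AssociationResult, res_b: AssociationResult,
                      alpha: float = 0.05) -> PipelineComparison:
    """Pearson correlation of signed scores over shared pathways plus the
    lists of pathways significant in exactly one pipeline."""
    shared = [p for p in res_a.table.index if p in set(res_b.table.index)]
    if len(shared) < 3:
        raise FuncvarError("need >= 3 shared pathways to compare pipelines")
    za = res_a.table.loc[shared, "statistic"].to_numpy(dtype=float)
    zb = res_b.table.loc[shared, "statistic"].to_numpy(dtype=float)
    if za.std() == 0 or zb.std() == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(za, zb)[0, 1])
    sig_a = res_a.significant(alpha) & set(shared)
    sig_b = res_b.significant(alpha) & set(shared)
    table = pd.DataFrame({
        "statistic_a": za, "statistic_b": zb,
        "q_a": res_a.table.loc[shared, "q"].to_numpy(),
        "q_b": res_b.table.loc[shared, "q"].to_numpy()}, index=shared)
    return PipelineComparison(r, table, frozenset(sig_a - sig_b),
                              frozenset(sig_b - sig_a), alpha)
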