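"""Variation and comparison statistics for functional profiles.

The workhorse measure of between-sample functional variation is the
coefficient of variation (CoV = sd / mean, sample sd with n-1 denominator).
Between-sample distances use Bray-Curtis.  Agreement between two distance
matrices (e.g. visit-1 vs visit-2 inter-individual distances) is assessed
with a one-sided Mantel permutation test.  Pairs of same-pathway genes whose
abundances anti-correlate across samples — evidence of alternative functional
strategies hidden by pathway pooling — are counted by
:func:`negative_pair_fraction`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from .profiles_io import (DistanceMatrix, FuncvarError, GeneProfile,
                          PathwayProfile)


def coefficient_of_variation(values, ddof: int = 1) -> float:
    """sd / mean of a non-negative vector; NaN sentinel when the mean is 0."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise FuncvarError("CoV requires a 1-d vector of length >= 2")
    mean = x.mean()
    if mean == 0:
        return float("nan")
    return float(x.std(ddof=ddof) / mean)


def fold_change_from_mean(profile: PathwayProfile | GeneProfile,
                          feature: str, log2: bool = False) -> pd.Series:
    """Per-sample ratio of a feature's abundance to its across-sample mean."""
    if feature not in profile.data.columns:
        raise FuncvarError(f"feature {feature!r} not in profile")
    col = profile.data[feature].astype(float)
    mean = col.mean()
    if mean <= 0:
        raise FuncvarError(f"feature {feature!r} has zero mean abundance")
    fc = col / mean
    return np.log2(fc) if log2 else fc


def bray_curtis_matrix(profile: GeneProfile | PathwayProfile) -> DistanceMatrix:
    """All-pairs Bray-Curtis distances between samples:
    d(i,j) = 1 - 2*sum_f min(x_if, x_jf) / (sum_f x_if + sum_f x_jf)."""
    vals = profile.values
    if (vals.sum(axis=1) <= 0).any():
        bad = [s for s, t in zip(profile.sample_ids, vals.sum(axis=1)) if t <= 0]
        raise FuncvarError(f"all-zero sample(s) have undefined Bray-Curtis "
                           f"distance: {bad[:10]}")
    condensed = pdist(vals, metric="braycurtis")
    return DistanceMatrix.from_square(squareform(condensed), profile.sample_ids)


def negative_pair_fraction(profile: GeneProfile | PathwayProfile,
                           members: frozenset[str] | set[str] | None = None,
                           r_threshold: float = -0.3) -> float:
    """Fraction of member-gene pairs with Pearson r below ``r_threshold``.

    Genes with zero variance across samples cannot be correlated and are
    excluded (with a warning) rather than counted as r = 0.
    """
    if profile.data.shape[0] < 3:
        raise FuncvarError("need >= 3 samples to screen correlations")
    if members is None:
        cols = list(profile.data.columns)
    else:
        cols = [g for g in profile.data.columns if g in set(members)]
    sub = profile.data[cols].to_numpy(dtype=float)
    usable = sub.std(axis=0) > 0
    n_dropped = int((~usable).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} zero-variance gene(s) excluded from "
                      "correlation screen", stacklevel=2)
    sub = sub[:, usable]
    if sub.shape[1] < 2:
        raise FuncvarError("fewer than 2 usable genes for correlation screen")
    corr = np.corrcoef(sub.T)
    iu = np.triu_indices(sub.shape[1], k=1)
    pairs = corr[iu]
    return float((pairs < r_threshold).mean())


def mantel_test(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999,
                seed: int | np.random.Generator | None = None) -> tuple[float, float]:
    """One-sided Mantel test between two distance matrices over the same IDs.

    r is the Pearson correlation of the upper-triangle entries; the p-value is
    (1 + #{permutations with r* >= r}) / (1 + n_perm), permuting the rows and
    columns of ``d2`` jointly.  The +1 correction means p can never be 0.
    ``d2`` is reindexed to ``d1``'s ID order; a mismatched ID set is an error.
    """
    if n_perm < 99:
        raise FuncvarError("n_perm must be >= 99")
    if set(d1.ids) != set(d2.ids):
        raise FuncvarError("distance matrices have different ID sets")
    m2 = d2.data.loc[d1.ids, d1.ids].to_numpy(dtype=float)
    m1 = d1.values
    n = len(d1.ids)
    if n < 3:
        raise FuncvarError("Mantel test needs >= 3 objects")
    iu = np.triu_indices(n, k=1)
    x = m1[iu]
    if x.std() == 0:
        raise FuncvarError("first distance matrix is constant off-diagonal")
    y = m2[iu]
    if y.std() == 0:
        raise FuncvarError("second distance matrix is constant off-diagonal")
    xz = (x - x.mean()) / x.std()
    r_obs = float(np.dot(xz, (y - y.mean()) / y.std()) / len(x))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = m2[np.ix_(perm, perm)][iu]
        sd = yp.std()
        r_perm = float(np.dot(xz, (yp - yp.mean()) / sd) / len(x)) if sd > 0 else 0.0
        if r_perm >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return r_obs, p


@dataclass(frozen=True)
class VariationReport:
    """Per-feature CoV under two processing schemes plus a paired test.

    ``table`` columns: mean_a, mean_b, cov_a, cov_b, cov_ratio (= cov_b/cov_a).
    ``statistic``/``pvalue`` come from a paired t test (or a rank-sum test on
    the two CoV distributions with ``test="ranksum"``).
    """

    table: pd.DataFrame
    statistic: float
    pvalue: float
    test: str


def compare_scheme_variation(profile_a: PathwayProfile, profile_b: PathwayProfile,
                             test: str = "paired_t") -> VariationReport:
    """Compare per-feature CoV between two pathway profiles (schemes A and B)."""
    shared = [f for f in profile_a.data.columns if f in set(profile_b.data.columns)]
    if set(profile_a.data.columns) != set(profile_b.data.columns):
        warnings.warn(
            f"feature sets differ; using the {len(shared)}-feature "
            "intersection", stacklevel=2)
    if len(shared) < 3:
        raise FuncvarError("need >= 3 shared features to compare schemes")
    a = profile_a.data[shared].to_numpy(dtype=float)
    b = profile_b.data[shared].to_numpy(dtype=float)

    def _cov(mat: np.ndarray) -> np.ndarray:
        means = mat.mean(axis=0)
        sds = mat.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(means > 0, sds / means, np.nan)

    cov_a, cov_b = _cov(a), _cov(b)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = cov_b / cov_a
    table = pd.DataFrame({
        "mean_a": a.mean(axis=0), "mean_b": b.mean(axis=0),
        "cov_a": cov_a, "cov_b": cov_b, "cov_ratio": ratio}, index=shared)
    ok = np.isfinite(cov_a) & np.isfinite(cov_b)
    if ok.sum() < 3:
        raise FuncvarError("fewer than 3 features with defined CoV in both schemes")
    if test == "paired_t":
        diffs = cov_b[ok] - cov_a[ok]
        if np.allclose(diffs, 0.0):
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ttest_rel(cov_b[ok], cov_a[ok])
    elif test == "ranksum":
        stat, p = sps.ranksums(cov_b[ok], cov_a[ok])
    else:
        raise FuncvarError(f"unknown test {test!r}")
    return VariationReport(table, float(stat), float(p), test)
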