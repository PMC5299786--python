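"""Independent brute-force reference implementations used as test oracles.

Everything here is written directly from the definitions as naive loops,
deliberately sharing no code with the package's vectorized paths.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd


def naive_map_to_pathways(df: pd.DataFrame, pairs: list[tuple[str, str]],
                          scheme: str, min_nonshared: int = 10,
                          min_mean_rel_abundance: float = 0.0005) -> pd.DataFrame:
    """Per-gene triple-loop gene->pathway mapping (samples x eligible pathways)."""
    pathways_of: dict[str, set[str]] = defaultdict(set)
    genes_of: dict[str, set[str]] = defaultdict(set)
    for g, p in set(pairs):
        pathways_of[g].add(p)
        genes_of[p].add(g)
    nonshared = {g for g in pathways_of if len(pathways_of[g]) == 1}

    totals = df.sum(axis=1)
    eligible = []
    for p in sorted(genes_of):
        rels = []
        for s in df.index:
            tot = 0.0
            for g in genes_of[p]:
                if g in df.columns:
                    tot += df.loc[s, g] / len(pathways_of[g])
            rels.append(tot / totals[s])
        if (len(genes_of[p] & nonshared) >= min_nonshared
                and np.mean(rels) > min_mean_rel_abundance):
            eligible.append(p)

    support: dict[tuple[str, str], float] = {}
    for p in eligible:
        ns_present = [g for g in genes_of[p] & nonshared if g in df.columns]
        for s in df.index:
            support[(s, p)] = (float(np.mean([df.loc[s, g] for g in ns_present]))
                               if ns_present else 0.0)

    out = pd.DataFrame(0.0, index=df.index, columns=eligible)
    for s in df.index:
        for g in df.columns:
            if g not in pathways_of:
                continue
            elig_ps = sorted(pathways_of[g] & set(eligible))
            if not elig_ps:
                continue
            v = df.loc[s, g]
            if g in nonshared:
                out.loc[s, elig_ps[0]] += v
            elif scheme == "complete":
                for p in elig_ps:
                    out.loc[s, p] += v
            elif scheme == "fractional":
                for p in elig_ps:
                    out.loc[s, p] += v / len(elig_ps)
            else:  # evidence-based
                sups = [support[(s, p)] for p in elig_ps]
                tot = sum(sups)
                if tot > 0:
                    for p, sup in zip(elig_ps, sups):
                        out.loc[s, p] += v * sup / tot
                else:
                    for p in elig_ps:
                        out.loc[s, p] += v / len(elig_ps)
    return out


def naive_cov_report(copies: np.ndarray, threshold: float,
                     ddof: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Per-column CoV and prevalence flags via an explicit loop."""
    covs, flags = [], []
    for j in range(copies.shape[1]):
        col = copies[:, j].astype(float)
        mean = col.mean()
        if mean == 0:
            cov = np.inf
        else:
            cov = col.std(ddof=ddof) / mean
        covs.append(cov)
        flags.append(cov < threshold)
    return np.array(covs), np.array(flags)


def naive_bray_curtis(mat: np.ndarray) -> np.ndarray:
    """All-pairs Bray-Curtis from the 1 - 2*sum(min)/sum(total) formula."""
    n = mat.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = 2.0 * np.minimum(mat[i], mat[j]).sum()
            den = mat[i].sum() + mat[j].sum()
            out[i, j] = 1.0 - num / den
    return out


def naive_jaccard(presence: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard distance between columns of a boolean matrix."""
    n = presence.shape[1]
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            inter = (presence[:, a] & presence[:, b]).sum()
            union = (presence[:, a] | presence[:, b]).sum()
            out[a, b] = 0.0 if a == b else 1.0 - inter / union
    return out


def random_mapping_instance(rng: np.random.Generator,
                            max_samples: int = 20, max_genes: int = 50,
                            max_pathways: int = 8):
    """Random small profile + many-to-many map for mapping-oracle tests."""
    n_s = int(rng.integers(2, max_samples + 1))
    n_g = int(rng.integers(5, max_genes + 1))
    n_p = int(rng.integers(2, max_pathways + 1))
    genes = [f"g{i}" for i in range(n_g)]
    pathways = [f"p{i}" for i in range(n_p)]
    pairs = []
    for i, g in enumerate(genes):
        # keep at least two single-pathway genes so support is computable
        deg = 1 if i < 2 else int(rng.integers(1, min(3, n_p) + 1))
        for p in rng.choice(n_p, size=deg, replace=False):
            pairs.append((g, pathways[int(p)]))
    vals = rng.gamma(1.0, 10.0, size=(n_s, n_g))
    vals[rng.random(vals.shape) < 0.2] = 0.0
    vals[:, 0] += 1.0  # keep every sample total positive
    df = pd.DataFrame(vals, index=[f"s{i}" for i in range(n_s)], columns=genes)
    return df, pairs
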