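"""Alpha diversity, phylum ratios and PERMANOVA — the descriptive layer.

Diversity indices operate on raw integer counts (no rarefaction is implied;
an optional subsampling depth is exposed for users who want it). Shannon
defaults to natural log; Simpson is the Gini-Simpson form 1 - sum p_i^2;
Chao1 uses the bias-corrected (F2 + 1) denominator so doubleton-free samples
are defined.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from longicore.abundance_io import AbundanceTable, aggregate_rank


def _check_counts(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if (x < 0).any() or not np.all(np.isfinite(x)):
        raise ValueError("counts must be finite and non-negative")
    return x


def observed_species(counts) -> int:
    """Number of taxa with a positive count."""
    return int((_check_counts(counts) > 0).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    x = _check_counts(counts)
    if not (x > 0).any():
        raise ValueError("chao1 undefined for an all-zero sample")
    s_obs = (x > 0).sum()
    f1 = (x == 1).sum()
    f2 = (x == 2).sum()
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def shannon(counts, base: float = np.e) -> float:
    """Shannon entropy -sum p log_base p over taxa with positive counts."""
    x = _check_counts(counts)
    total = x.sum()
    if total <= 0:
        raise ValueError("shannon undefined for an all-zero sample")
    p = x[x > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def simpson(counts) -> float:
    """Gini-Simpson diversity 1 - sum p_i^2."""
    x = _check_counts(counts)
    total = x.sum()
    if total <= 0:
        raise ValueError("simpson undefined for an all-zero sample")
    p = x / total
    return float(1.0 - (p**2).sum())


def alpha_diversity(table: AbundanceTable, shannon_base: float = np.e,
                    subsample_depth: int | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Per-sample observed species, Chao1, Shannon and Simpson indices.

    ``subsample_depth`` optionally rarefies each sample (without replacement)
    before computing indices; samples below the depth are left as-is.
    """
    counts = table.counts.to_numpy()
    if subsample_depth is not None:
        rng = np.random.default_rng(seed)
        counts = np.vstack(
            [_subsample(row, subsample_depth, rng) for row in counts]
        )
    rows = []
    for sample, row in zip(table.sample_ids, counts):
        rows.append(
            {
                "sample_id": sample,
                "observed_species": observed_species(row),
                "chao1": chao1(row),
                "shannon": shannon(row, base=shannon_base),
                "simpson": simpson(row),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def _subsample(row: np.ndarray, depth: int, rng) -> np.ndarray:
    total = int(row.sum())
    if total <= depth:
        return row
    expanded = np.repeat(np.arange(len(row)), row.astype(int))
    picked = rng.choice(expanded, size=depth, replace=False)
    return np.bincount(picked, minlength=len(row)).astype(float)


def phylum_ratio(table: AbundanceTable, numerator: str,
                 denominator: str) -> pd.Series:
    """Per-sample ratio of two phylum totals (e.g. Firmicutes/Bacteroidetes).

    Samples whose denominator total is zero yield NaN (flagged missing, never
    infinite). A phylum absent from the taxonomy entirely is an error.
    """
    phy = aggregate_rank(table, "phylum")
    for name in (numerator, denominator):
        if name not in phy.counts.columns:
            raise ValueError(f"phylum {name!r} absent from taxonomy")
    num = phy.counts[numerator]
    den = phy.counts[denominator]
    ratio = num / den.where(den > 0)
    ratio.name = f"{numerator}/{denominator}"
    return ratio


def clr_transform(table: AbundanceTable, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centred log-ratio transform of counts (pseudocount for zeros).

    Each row is log(x + c) minus its mean, so rows sum to zero; an
    alternative geometry for ordination distances.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logged = np.log(table.counts + pseudocount)
    return logged.sub(logged.mean(axis=1), axis=0)


def euclidean_distance(profile: pd.DataFrame) -> pd.DataFrame:
    """Square Euclidean distance matrix between sample rows."""
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(profile.to_numpy(), metric="euclidean"))
    return pd.DataFrame(d, index=profile.index, columns=profile.index)


def permanova(dist, groups, n_perm: int = 999, seed: int = 0):
    """Permutational multivariate ANOVA on a distance matrix.

    The pseudo-F partitions the total sum of squared distances into between-
    and within-group components:

        SS_total = sum_{i<j} d_ij^2 / n
        SS_within = sum_g sum_{i<j in g} d_ij^2 / n_g
        F = (SS_between / (g - 1)) / (SS_within / (n - g))

    The p-value is (1 + #{F_perm >= F_obs}) / (1 + n_perm) under random
    relabelling of samples, deterministic under ``seed``.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    labels = np.asarray(groups)
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValueError("group labels must match distance matrix size")
    uniq, codes = np.unique(labels, return_inverse=True)
    g = len(uniq)
    if g < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValueError("every group needs at least two samples")

    d2 = d**2
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n

    def pseudo_f(code_vec: np.ndarray) -> float:
        ss_within = 0.0
        for k in range(g):
            idx = np.flatnonzero(code_vec == k)
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
        ss_between = ss_total - ss_within
        if ss_within == 0:        # perfectly separated clusters
            return np.inf
        return (ss_between / (g - 1)) / (ss_within / (n - g))

    f_obs = pseudo_f(codes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(codes)) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(f_obs), float(p)


def group_compare(values: pd.Series, groups: pd.Series,
                  test: str = "wilcoxon") -> pd.DataFrame:
    """Pairwise two-group comparisons via standard library tests.

    'wilcoxon' is the two-sample rank-sum test; 'ttest' is Welch's t.
    """
    out = []
    labels = sorted(groups.dropna().unique())
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            va = values[groups == a].dropna()
            vb = values[groups == b].dropna()
            if test == "wilcoxon":
                stat, p = stats.ranksums(va, vb)
            elif test == "ttest":
                stat, p = stats.ttest_ind(va, vb, equal_var=False)
            else:
                raise ValueError(f"unknown test {test!r}")
            out.append({"group_a": a, "group_b": b, "statistic": float(stat),
                        "p_value": float(p)})
    return pd.DataFrame(out)
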