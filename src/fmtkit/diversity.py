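"""Alpha and beta diversity.

Alpha diversity is the Shannon entropy H = -sum p_i ln p_i of a sample's
relative abundances (natural log by default, matching the convention of the
analysis platform this pipeline mirrors); group comparisons use the
Kruskal-Wallis rank test, with pairwise contrasts realized as two-group
Kruskal-Wallis. Beta diversity is Bray-Curtis dissimilarity with PERMANOVA
on the resulting distance matrix.

The PERMANOVA implementation permutes group labels with a caller-supplied
seed and reports p = (exceedances + 1) / (n_permutations + 1); when the
number of distinct labelings is small (<= 10,000) it switches to exhaustive
enumeration over the label multiset and the p-value is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform


class DiversityError(ValueError):
    pass


def shannon(proportions, base: float | None = None) -> float:
    """Shannon entropy of a proportion vector; zero entries contribute 0.

    `base=None` means natural log (nats).
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise DiversityError("proportions must be non-negative")
    total = p.sum()
    if total == 0:
        raise DiversityError("all-zero proportion vector")
    if abs(total - 1.0) > 1e-9:
        raise DiversityError(f"proportions sum to {total!r}, expected 1")
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def alpha_diversity(rel, base: float | None = None) -> pd.Series:
    """Per-sample Shannon index for a RelAbundTable."""
    return rel.proportions.apply(lambda row: shannon(row.to_numpy(), base=base), axis=1)


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Rank-based H with tie correction; chi-square p with (k-1) df.

    All-identical values across groups give (H=0, p=1) rather than NaN.
    """
    if len(groups) < 2:
        raise DiversityError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise DiversityError("every group must be nonempty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def pairwise_kruskal(values: pd.Series, labels: pd.Series, adjust: bool = False) -> pd.DataFrame:
    """Two-group Kruskal-Wallis for every pair of labels.

    Raw p-values by default; `adjust=True` adds Benjamini-Hochberg adjusted
    p-values as an extra column.
    """
    from statsmodels.stats.multitest import multipletests

    uniq = sorted(set(labels))
    rows = []
    for i, a in enumerate(uniq):
        for b in uniq[i + 1 :]:
            h, p = kruskal_wallis([values[labels == a], values[labels == b]])
            rows.append({"group_a": a, "group_b": b, "H": h, "p_value": p})
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "H", "p_value"])
    if adjust and len(out):
        out["adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def bray_curtis(x, y) -> float:
    """1 - 2*sum(min(x,y)) / (sum x + sum y); in [0, 1] for non-negative input.

    No normalization happens here: callers decide whether to pass counts or
    relative abundances (the pipeline passes relative abundances).
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise DiversityError("vectors must have equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise DiversityError("abundances must be non-negative")
    sa, sb = a.sum(), b.sum()
    if sa == 0 or sb == 0:
        raise DiversityError("zero-sum abundance vector")
    return float(1.0 - 2.0 * np.minimum(a, b).sum() / (sa + sb))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    sample_ids: list[str]
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise DiversityError("distance matrix shape does not match sample ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise DiversityError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise DiversityError("distance matrix diagonal must be zero")
        self.distances = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.distances, index=self.sample_ids, columns=self.sample_ids)


def bray_curtis_matrix(rel) -> DistanceMatrix:
    """All-pairs Bray-Curtis distances for a RelAbundTable."""
    condensed = pdist(rel.proportions.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(list(rel.sample_ids), squareform(condensed))


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    seed: int | None
    exhaustive: bool = False


def _multiset_permutations(items: list):
    """Yield distinct permutations of a multiset (lexicographic order)."""
    items = sorted(items)
    n = len(items)
    yield tuple(items)
    while True:
        # next_permutation
        i = n - 2
        while i >= 0 and items[i] >= items[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while items[j] <= items[i]:
            j -= 1
        items[i], items[j] = items[j], items[i]
        items[i + 1 :] = reversed(items[i + 1 :])
        yield tuple(items)


def _n_distinct_labelings(labels: np.ndarray) -> int:
    _, counts = np.unique(labels, return_counts=True)
    total = math.factorial(len(labels))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """PERMANOVA pseudo-F from the squared-distance partition.

    SS_total = sum_{i<j} d2_ij / n; SS_within = sum over groups of the
    within-group pair sums divided by group size; F = (SS_between/(a-1)) /
    (SS_within/(n-a)).
    """
    n = len(codes)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        members = codes == g
        n_g = int(members.sum())
        ss_within += d2[np.ix_(members, members)].sum() / (2.0 * n_g)
    ss_between = ss_total - ss_within
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    dist: DistanceMatrix,
    labels,
    n_permutations: int = 999,
    seed: int | None = None,
    exhaustive_limit: int = 10_000,
) -> PermanovaResult:
    """One-way PERMANOVA with seeded label permutation.

    Exhaustive enumeration of all distinct labelings replaces sampling when
    their number is at most `exhaustive_limit`; the p-value is then exact
    (fraction of labelings with F >= observed, which includes the identity).
    """
    labels = np.asarray(list(labels))
    if len(labels) != len(dist.sample_ids):
        raise DiversityError("labels must match the distance matrix samples")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise DiversityError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = uniq[np.argmin(counts)]
        raise DiversityError(f"group {small!r} has fewer than 2 samples")
    d2 = dist.distances.astype(float) ** 2
    f_obs = _pseudo_f(d2, codes, len(uniq))
    eps = 1e-12

    if _n_distinct_labelings(codes) <= exhaustive_limit:
        exceed = 0
        total = 0
        for perm in _multiset_permutations(list(codes)):
            total += 1
            if _pseudo_f(d2, np.asarray(perm), len(uniq)) >= f_obs - eps:
                exceed += 1
        return PermanovaResult(
            pseudo_F=f_obs,
            p_value=exceed / total,
            n_permutations=total - 1,
            seed=seed,
            exhaustive=True,
        )

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, len(uniq)) >= f_obs - eps:
            exceed += 1
    return PermanovaResult(
        pseudo_F=f_obs,
        p_value=(exceed + 1) / (n_permutations + 1),
        n_permutations=n_permutations,
        seed=seed,
        exhaustive=False,
    )


def pcoa_coordinates(dist: DistanceMatrix, n_axes: int = 2) -> pd.DataFrame:
    """Classical multidimensional scaling (PCoA) coordinates for export."""
    d2 = dist.distances.astype(float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    k = min(n_axes, int((vals > 1e-12).sum()))
    coords = vecs[:, :k] * np.sqrt(np.maximum(vals[:k], 0.0))
    return pd.DataFrame(
        coords, index=dist.sample_ids, columns=[f"PCo{i + 1}" for i in range(k)]
    )
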