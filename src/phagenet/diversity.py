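"""Alpha/beta diversity, ordination, PERMANOVA, group tests, coupling, clustering.

This module carries the community-level statistics: Shannon alpha diversity,
Bray–Curtis and Sørensen dissimilarities, non-metric multidimensional scaling
(NMDS), the PERMANOVA (Adonis) test of categorical factors on a distance
matrix, Mann–Whitney group comparisons, the bacteria–phage composition
coupling regression, and average-linkage (UPGMA) hierarchical clustering.

Conventions
-----------
* Shannon entropy uses the natural logarithm.
* PERMANOVA is single-factor ("marginal"): each factor is tested on its own,
  one row per factor, with R² = SS_between / SS_total from the standard
  distance-based partition and a permutation p-value
  ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)``.
* NMDS minimizes Kruskal stress-1 (non-metric SMACOF, best of ``n_restarts``
  seeded random starts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average as _upgma_linkage
from scipy.spatial.distance import pdist, squareform

from .tables import AbundanceTable, PresenceAbsenceTable

_BOUNDED_METRICS = {"bray-curtis", "sorensen"}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities with zero diagonal."""

    labels: list[str]
    data: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        D = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if D.shape != (n, n):
            raise ValueError(f"distance matrix shape {D.shape} != ({n}, {n})")
        if not np.allclose(D, D.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(D), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (D < -1e-12).any():
            raise ValueError("negative dissimilarity")
        if self.metric_name in _BOUNDED_METRICS and (D > 1 + 1e-9).any():
            raise ValueError(f"{self.metric_name} dissimilarities must be <= 1")
        self.data = 0.5 * (D + D.T)
        np.fill_diagonal(self.data, 0.0)

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)

    def to_skbio(self):
        import skbio

        return skbio.DistanceMatrix(self.data, ids=self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.labels, columns=self.labels)


@dataclass
class PermanovaResult:
    factor_name: str
    df: int
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.R2 <= 1.0:
            raise ValueError(f"R2 {self.R2} outside [0, 1]")
        if self.p_value < 1.0 / (self.n_permutations + 1) - 1e-12:
            raise ValueError("permutation p below its attainable minimum")


@dataclass
class NMDSResult:
    coordinates: pd.DataFrame  # samples × k
    stress: float
    n_restarts: int
    seed: int


@dataclass
class CouplingRegression:
    """OLS fit of phage pairwise dissimilarity on bacterial pairwise dissimilarity."""

    slope: float
    intercept: float
    p_value: float
    n_pairs: int
    r_squared: float
    mantel_r: float | None = None
    mantel_p: float | None = None


@dataclass
class Dendrogram:
    """UPGMA merge tree: a scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray
    labels: list[str]

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.labels)
        return str(tree).strip()


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------


def shannon(abundances) -> float:
    """Shannon index H = −Σ pᵢ ln pᵢ over the positive entries (natural log)."""
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def alpha_diversity(table: AbundanceTable) -> pd.Series:
    """Per-sample Shannon index."""
    return pd.Series(
        {s: shannon(table.values[s].to_numpy()) for s in table.sample_ids}, name="shannon"
    )


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity D[i,j] = Σ|xᵢ−xⱼ| / Σ(xᵢ+xⱼ) between samples."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = table.values.to_numpy(dtype=float).T  # samples × taxa
    zero = X.sum(axis=1) <= 0
    if zero.sum() >= 2:
        bad = [s for s, z in zip(table.sample_ids, zero) if z]
        raise ValueError(f"Bray–Curtis undefined between all-zero samples: {bad}")
    D = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, D, "bray-curtis")


def sorensen(pa: PresenceAbsenceTable) -> DistanceMatrix:
    """Sørensen dissimilarity 1 − 2a/(2a+b+c) on presence/absence profiles."""
    X = pa.values.to_numpy(dtype=bool).T
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    absent = ~X.any(axis=1)
    if absent.sum() >= 2:
        bad = [s for s, z in zip(pa.sample_ids, absent) if z]
        raise ValueError(f"Sørensen undefined between all-absent samples: {bad}")
    # scipy's 'dice' dissimilarity is exactly (b+c) / (2a+b+c)
    D = squareform(pdist(X, metric="dice"))
    return DistanceMatrix(pa.sample_ids, D, "sorensen")


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------


def nmds(
    D: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> NMDSResult:
    """Non-metric MDS minimizing Kruskal stress-1; best of seeded random restarts."""
    if k >= D.n_samples:
        raise ValueError("embedding dimension must be below the sample count")
    from sklearn.manifold import MDS

    model = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        n_init=n_restarts,
        max_iter=max_iter,
        eps=tol,
        init="random",
        random_state=seed,
        normalized_stress=True,
    )
    coords = model.fit_transform(D.data)
    frame = pd.DataFrame(
        coords, index=D.labels, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return NMDSResult(frame, float(model.stress_), n_restarts, seed)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _permanova_ss(d2: np.ndarray, onehot: np.ndarray, sizes: np.ndarray) -> float:
    """Within-group sum of squares Σ_g Σ_{i<j∈g} d²ᵢⱼ / n_g."""
    within = np.einsum("ig,ij,jg->g", onehot, d2, onehot) / 2.0
    return float((within / sizes).sum())


def permanova(
    D: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int = 0,
    factor_name: str = "factor",
) -> PermanovaResult:
    """One-factor PERMANOVA (Adonis) on a distance matrix.

    ``grouping`` maps sample id → level (mapping or pandas Series). The
    pseudo-F and R² come from the standard distance-based partition
    (equivalently, Gower-centered inner products); the p-value permutes the
    sample labels.
    """
    levels = pd.Series(grouping).loc[D.labels]
    codes, uniques = pd.factorize(levels)
    g = len(uniques)
    n = D.n_samples
    if g < 2:
        raise ValueError("PERMANOVA needs at least 2 factor levels")
    if g >= n:
        raise ValueError("more levels than samples leaves no residual df")
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")

    d2 = D.data**2
    sst = d2.sum() / (2.0 * n)

    def f_stat(c: np.ndarray) -> float:
        onehot = np.eye(g)[c]
        sizes = onehot.sum(axis=0)
        ssw = _permanova_ss(d2, onehot, sizes)
        ssb = sst - ssw
        with np.errstate(divide="ignore"):
            return (ssb / (g - 1)) / (ssw / (n - g))  # inf when groups separate perfectly

    F = f_stat(codes)
    onehot = np.eye(g)[codes]
    sizes = onehot.sum(axis=0)
    R2 = (sst - _permanova_ss(d2, onehot, sizes)) / sst

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        if f_stat(rng.permutation(codes)) >= F - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return PermanovaResult(factor_name, g - 1, float(F), float(np.clip(R2, 0, 1)), p,
                           n_permutations, seed)


def permanova_table(
    D: DistanceMatrix,
    metadata: pd.DataFrame,
    factors: list[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """One PERMANOVA row per factor (Df, F, R2, p), each tested on its own."""
    rows = []
    for factor in factors:
        res = permanova(D, metadata[factor], n_permutations, seed, factor_name=factor)
        rows.append(
            {"Type": factor, "Df": res.df, "F": res.pseudo_F, "R2": res.R2, "p": res.p_value}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Small samples (min(n, m) ≤ 8) use the exact distribution — via full
    enumeration of label assignments when ties are present — larger samples
    the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    small = min(x.size, y.size) <= 8
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if small and not has_ties:
        method = "exact"
    elif small:
        from math import comb

        n_distinct = comb(x.size + y.size, x.size)
        method = stats.PermutationMethod(n_resamples=max(n_distinct + 1, 10_000), rng=0)
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# composition coupling
# ---------------------------------------------------------------------------


def coupling_regression(
    D_bacteria: DistanceMatrix,
    D_phage: DistanceMatrix,
    mantel_permutations: int = 0,
    seed: int = 0,
) -> CouplingRegression:
    """OLS of phage pairwise dissimilarity on bacterial pairwise dissimilarity.

    All s(s−1)/2 unordered sample pairs enter the fit; the OLS slope p-value
    treats pairs as independent (they are not), so a Mantel permutation
    p-value — the statistically defensible alternative — is also computed
    when ``mantel_permutations`` > 0.
    """
    if D_bacteria.labels != D_phage.labels:
        raise ValueError("distance matrices must share the same samples in the same order")
    xb = D_bacteria.condensed()
    yp = D_phage.condensed()
    if np.allclose(xb, xb[0]):
        raise ValueError("bacterial dissimilarities are constant; slope undefined")
    if np.allclose(yp, yp[0]):
        fit = None
        slope, intercept, p, r2 = 0.0, float(yp[0]), 1.0, 0.0
    else:
        fit = stats.linregress(xb, yp)
        slope, intercept, p, r2 = fit.slope, fit.intercept, fit.pvalue, fit.rvalue**2
    mantel_r = mantel_p = None
    if mantel_permutations > 0:
        mantel_r, mantel_p = _mantel(D_bacteria.data, D_phage.data, mantel_permutations, seed)
    return CouplingRegression(
        float(slope), float(intercept), float(p), xb.size, float(r2), mantel_r, mantel_p
    )


def _mantel(A: np.ndarray, B: np.ndarray, n_permutations: int, seed: int) -> tuple[float, float]:
    """Pearson Mantel test permuting the rows/columns of the second matrix."""
    a = squareform(A, checks=False)
    b = squareform(B, checks=False)
    r_obs = np.corrcoef(a, b)[0, 1]
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        bp = squareform(B[np.ix_(perm, perm)], checks=False)
        if abs(np.corrcoef(a, bp)[0, 1]) >= abs(r_obs) - 1e-12:
            exceed += 1
    return float(r_obs), (1.0 + exceed) / (1.0 + n_permutations)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------


def hclust_average(D: DistanceMatrix) -> Dendrogram:
    """UPGMA (average linkage) dendrogram; merge heights are non-decreasing."""
    Z = _upgma_linkage(D.condensed())
    heights = Z[:, 2]
    if (np.diff(heights) < -1e-9).any():
        raise AssertionError("UPGMA merge heights must be non-decreasing")
    return Dendrogram(Z, list(D.labels))
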