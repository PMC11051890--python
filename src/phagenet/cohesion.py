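"""Cohesion: null-model-corrected connectedness and per-sample interaction strength.

Cohesion quantifies how strongly a community's members co-vary, separated
into cooperative (positive) and antagonistic (negative) parts. Following the
taxon-shuffle null-model approach:

1. On relative abundances, compute pairwise taxon correlations (Pearson by
   default, Spearman optionally).
2. For each pair, subtract the mean correlation obtained when the focal
   taxon's abundances are shuffled across samples and each sample is
   re-closed to its original total (``n_iter`` shuffles per taxon).
   Shuffling destroys true co-variation while preserving the focal taxon's
   abundance distribution; re-closing keeps the data compositional, so the
   null reproduces — and the subtraction removes — correlation that closure
   alone would generate (e.g. the mechanical anti-correlation of two
   dominant taxa). The two directions (shuffle taxon i vs. shuffle taxon j)
   are averaged so the corrected matrix stays symmetric.
3. A taxon's positive (negative) connectedness is the mean of its positive
   (negative) corrected correlations with all other taxa.
4. A sample's positive (negative) cohesion is Σ abundance × connectedness
   over taxa; total cohesion = positive + |negative| — an exact identity
   asserted in the result container.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AbundanceTable, relative_abundance
from .diversity import mann_whitney

logger = logging.getLogger(__name__)


@dataclass
class CorrectedCorrelations:
    """Symmetric null-corrected correlation matrix (diagonal fixed at 0)."""

    matrix: pd.DataFrame
    n_iterations: int
    correlation_kind: str
    seed: int


@dataclass
class ConnectednessTable:
    """Per-taxon mean positive (≥0) and mean negative (≤0) corrected correlation."""

    table: pd.DataFrame  # columns: pos_connectedness, neg_connectedness
    n_iterations: int
    correlation_kind: str
    seed: int

    def __post_init__(self) -> None:
        if (self.table["pos_connectedness"] < -1e-12).any():
            raise ValueError("positive connectedness must be >= 0")
        if (self.table["neg_connectedness"] > 1e-12).any():
            raise ValueError("negative connectedness must be <= 0")


@dataclass
class CohesionResult:
    """Per-sample positive, negative, and total cohesion."""

    table: pd.DataFrame  # columns: positive_cohesion, negative_cohesion, total_cohesion

    def __post_init__(self) -> None:
        t = self.table
        if (t["positive_cohesion"] < -1e-12).any():
            raise ValueError("positive cohesion must be >= 0")
        if (t["negative_cohesion"] > 1e-12).any():
            raise ValueError("negative cohesion must be <= 0")
        expect = t["positive_cohesion"] + t["negative_cohesion"].abs()
        if not np.allclose(t["total_cohesion"], expect, rtol=0, atol=1e-12):
            raise ValueError("total cohesion must equal positive + |negative| exactly")


def _check_relative(table: AbundanceTable) -> None:
    totals = table.values.sum(axis=0)
    if not np.allclose(totals, 1.0, atol=1e-6):
        raise ValueError(
            "cohesion requires relative abundances (columns summing to 1); "
            "apply tables.relative_abundance first"
        )


def null_corrected_correlations(
    table: AbundanceTable,
    n_iter: int = 200,
    seed: int = 0,
    kind: str = "pearson",
) -> CorrectedCorrelations:
    """Observed minus mean taxon-shuffle-null pairwise correlation.

    ``table`` must hold relative abundances with ≥ 5 samples. For each focal
    taxon the null shuffles its abundances across samples and re-closes every
    sample to its original total before recomputing the focal taxon's
    correlations with all partners. Constant taxa (no correlation defined)
    are excluded with a logged warning.
    """
    _check_relative(table)
    if table.n_samples < 5:
        raise ValueError("null-corrected correlations need at least 5 samples")
    if n_iter < 10:
        raise ValueError("n_iter must be at least 10")
    if kind not in ("pearson", "spearman"):
        raise ValueError("correlation kind must be 'pearson' or 'spearman'")

    X = table.values.to_numpy(dtype=float)
    keep = np.ptp(X, axis=1) > 0
    if (~keep).any():
        logger.warning("excluding %d constant taxa from cohesion", int((~keep).sum()))
    taxa = [t for t, k in zip(table.taxon_ids, keep) if k]
    X = X[keep]

    def _rows_corr(A: np.ndarray, axis: int = -1) -> np.ndarray:
        mean = A.mean(axis=axis, keepdims=True)
        sd = A.std(axis=axis, keepdims=True)
        sd[sd == 0] = 1.0
        return (A - mean) / sd

    rank = (lambda M: np.apply_along_axis(stats.rankdata, -1, M)) if kind == "spearman" \
        else (lambda M: M)

    n_taxa, n_samples = X.shape
    Z = _rows_corr(rank(X))
    obs = Z @ Z.T / n_samples

    rng = np.random.default_rng(seed)
    colsum = X.sum(axis=0)
    null_mean = np.zeros_like(obs)
    cols = np.tile(np.arange(n_samples), (n_iter, 1))
    for i in range(n_taxa):
        perm = rng.permuted(cols, axis=1)
        F = X[i][perm]  # (n_iter, n_samples) shuffled focal abundances
        denom = (colsum - X[i])[None, :] + F  # per-sample totals after the swap
        focal = _rows_corr(rank(F / denom))  # (n_iter, S)
        others = _rows_corr(rank(X[None, :, :] / denom[:, None, :]))  # (iter, T, S)
        null_mean[i] = np.einsum("ks,kjs->j", focal, others) / (n_iter * n_samples)
    corrected = obs - 0.5 * (null_mean + null_mean.T)
    np.fill_diagonal(corrected, 0.0)
    frame = pd.DataFrame(corrected, index=taxa, columns=taxa)
    return CorrectedCorrelations(frame, n_iter, kind, seed)


def connectedness(corrected: CorrectedCorrelations) -> ConnectednessTable:
    """Mean positive and mean negative corrected correlation per taxon."""
    M = corrected.matrix.to_numpy()
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("corrected correlation matrix must be symmetric")
    n = M.shape[0]
    off = ~np.eye(n, dtype=bool)
    pos_mask = (M > 0) & off
    neg_mask = (M < 0) & off
    # a zero sum over an empty mask gives the required 0 default
    pos_mean = np.where(pos_mask, M, 0).sum(1) / np.maximum(pos_mask.sum(1), 1)
    neg_mean = np.where(neg_mask, M, 0).sum(1) / np.maximum(neg_mask.sum(1), 1)
    frame = pd.DataFrame(
        {"pos_connectedness": pos_mean, "neg_connectedness": neg_mean},
        index=corrected.matrix.index,
    )
    return ConnectednessTable(
        frame, corrected.n_iterations, corrected.correlation_kind, corrected.seed
    )


def compute_cohesion(table: AbundanceTable, conn: ConnectednessTable) -> CohesionResult:
    """Per-sample cohesion: Σ_taxa relative abundance × connectedness."""
    _check_relative(table)
    missing = conn.table.index.difference(table.values.index)
    if len(missing):
        raise ValueError(f"taxa in connectedness but not in table: {missing.tolist()}")
    sub = table.values.loc[conn.table.index]
    pos = sub.mul(conn.table["pos_connectedness"], axis=0).sum(axis=0)
    neg = sub.mul(conn.table["neg_connectedness"], axis=0).sum(axis=0)
    frame = pd.DataFrame(
        {
            "positive_cohesion": pos,
            "negative_cohesion": neg,
            "total_cohesion": pos + neg.abs(),
        }
    )
    frame.index.name = "sample_id"
    return CohesionResult(frame)


def persistence_filter(table: AbundanceTable, min_prevalence: float = 0.1) -> AbundanceTable:
    """Keep taxa present (abundance > 0) in at least ``min_prevalence`` of samples."""
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValueError("min_prevalence must be in [0, 1]")
    prevalence = (table.values > 0).mean(axis=1)
    keep = table.values.index[prevalence >= min_prevalence]
    if not len(keep):
        raise ValueError("persistence filter removed every taxon")
    return table.subset_taxa(keep)


def cohesion_pipeline(
    table: AbundanceTable,
    n_iter: int = 200,
    seed: int = 0,
    kind: str = "pearson",
    min_prevalence: float = 0.1,
) -> tuple[ConnectednessTable, CohesionResult]:
    """persistence filter → relative abundance → null correction → cohesion."""
    rel = relative_abundance(persistence_filter(table, min_prevalence))
    corrected = null_corrected_correlations(rel, n_iter=n_iter, seed=seed, kind=kind)
    conn = connectedness(corrected)
    return conn, compute_cohesion(rel, conn)


def cohesion_by_group(
    tables: dict[str, AbundanceTable],
    n_iter: int = 200,
    seed: int = 0,
    kind: str = "pearson",
    min_prevalence: float = 0.1,
) -> tuple[dict[str, CohesionResult], pd.DataFrame, pd.DataFrame]:
    """Full cohesion pipeline per group plus pairwise Mann–Whitney comparisons.

    Returns the per-group results, a long table (group, sample, metric, value),
    and a pairwise comparison table of total cohesion between groups.
    """
    if not tables:
        raise ValueError("need at least one group")
    results: dict[str, CohesionResult] = {}
    long_rows = []
    for group, table in tables.items():
        _, coh = cohesion_pipeline(
            table, n_iter=n_iter, seed=seed, kind=kind, min_prevalence=min_prevalence
        )
        results[group] = coh
        for sample, row in coh.table.iterrows():
            for metric in ("positive_cohesion", "negative_cohesion", "total_cohesion"):
                long_rows.append(
                    {"group": group, "sample": sample, "metric": metric, "value": row[metric]}
                )
    long = pd.DataFrame(long_rows)
    comps = []
    names = list(results)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = results[names[i]].table["total_cohesion"].to_numpy()
            b = results[names[j]].table["total_cohesion"].to_numpy()
            U, p = mann_whitney(a, b)
            comps.append({"group_a": names[i], "group_b": names[j], "U": U, "p": p})
    return results, long, pd.DataFrame(comps)
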