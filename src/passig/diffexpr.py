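"""Negative-binomial Wald differential expression.

A self-contained NB-Wald stack: median-of-ratios size factors, method-of-
moments dispersion, per-group NB means with a delta-method standard error on
the log2 fold change, a two-sided Wald p-value, and Benjamini-Hochberg
adjustment. This keeps the NB-Wald inferential form while remaining
analytically transparent; it does not attempt empirical-Bayes dispersion
shrinkage or fold-change shrinkage.

Fold changes are oriented A-vs-B: positive log2FC means higher expression in
group A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ExpressionMatrix, PassigError

__all__ = ["DEResult", "RankedList", "size_factors", "estimate_dispersion",
           "nb_wald_test", "bh_adjust", "significant_up", "ranked_list"]

#: pseudo-mean added inside the log2 to avoid log of zero (normalized counts)
DEFAULT_PSEUDO_MEAN = 0.5
#: lower bound on the method-of-moments dispersion estimate
DEFAULT_DISPERSION_FLOOR = 1e-8


class NormalizationError(PassigError):
    """Median-of-ratios normalization is undefined for this matrix."""


@dataclass
class DEResult:
    """Per-gene differential expression summary (DESeq2-style columns)."""

    table: pd.DataFrame  # baseMean, log2FoldChange, lfcSE, stat, pvalue, padj

    def __post_init__(self) -> None:
        required = ["baseMean", "log2FoldChange", "lfcSE", "stat", "pvalue", "padj"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"DEResult missing columns: {missing}")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class RankedList:
    """Genes in strictly decreasing order of a ranking statistic."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must align")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")

    def __len__(self) -> int:
        return len(self.genes)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"gene_id": self.genes, "score": self.scores}).to_csv(
            path, sep="\t", index=False)


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean pseudo-sample.

    Only genes with a positive geometric mean (i.e. nonzero in every sample)
    contribute to the median.
    """
    arr = counts.values.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_arr = np.log(arr)
    log_geomean = log_arr.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise NormalizationError("no gene has nonzero counts in every sample")
    ratios = log_arr[usable] - log_geomean[usable, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.sample_ids, name="size_factor")


def estimate_dispersion(counts: ExpressionMatrix, sf: pd.Series,
                        floor: float = DEFAULT_DISPERSION_FLOOR) -> pd.Series:
    """Method-of-moments NB dispersion on normalized counts.

    ``phi_i = max(floor, (s2_i - mean_i) / mean_i^2)`` where the mean and
    variance are taken across all samples after dividing by size factors.
    Genes with zero mean or sub-Poisson variance get the floor.
    """
    arr = counts.values.to_numpy(dtype=float)
    q = arr / sf.reindex(counts.sample_ids).to_numpy()[None, :]
    mean = q.mean(axis=1)
    var = q.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (var - mean) / mean**2
    phi = np.where(np.isfinite(phi), phi, 0.0)
    phi = np.maximum(phi, floor)
    return pd.Series(phi, index=counts.gene_ids, name="dispersion")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_wald_test(counts: ExpressionMatrix, sf: pd.Series, dispersions: pd.Series,
                 group_a: list[str], group_b: list[str],
                 pseudo_mean: float = DEFAULT_PSEUDO_MEAN) -> DEResult:
    """Two-sided Wald test of NB group means (group A vs group B).

    The normalized-count group means estimate the NB means; the variance of
    each mean follows the NB law ``Var(c/s) = mu/s + phi*mu^2`` and propagates
    to the log2 fold change by the delta method.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    missing = (set(group_a) | set(group_b)) - set(counts.sample_ids)
    if missing:
        raise KeyError(f"samples not in matrix: {sorted(missing)[:5]}")

    sf_all = sf.reindex(counts.sample_ids)
    phi = dispersions.reindex(counts.gene_ids).to_numpy()

    def group_stats(samples: list[str]) -> tuple[np.ndarray, np.ndarray]:
        sub = counts.values[samples].to_numpy(dtype=float)
        s = sf_all.reindex(samples).to_numpy()
        q = sub / s[None, :]
        mu = q.mean(axis=1)
        # Var(mean) = (1/n^2) sum_j (mu/s_j + phi mu^2)
        n = len(samples)
        var = (mu[:, None] / s[None, :] + phi[:, None] * mu[:, None] ** 2).sum(axis=1) / n**2
        return mu, var

    mu_a, var_a = group_stats(group_a)
    mu_b, var_b = group_stats(group_b)

    eps = pseudo_mean
    lfc = np.log2(mu_a + eps) - np.log2(mu_b + eps)
    ln2sq = np.log(2.0) ** 2
    var_lfc = (var_a / (mu_a + eps) ** 2 + var_b / (mu_b + eps) ** 2) / ln2sq
    se = np.sqrt(var_lfc)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    padj = bh_adjust(p)
    base_mean = np.concatenate([mu_a[None], mu_b[None]]).mean(axis=0)
    table = pd.DataFrame({
        "baseMean": base_mean,
        "log2FoldChange": lfc,
        "lfcSE": se,
        "stat": z,
        "pvalue": p,
        "padj": padj,
    }, index=counts.gene_ids)
    return DEResult(table)


def significant_up(de: DEResult, lfc_min: float = 1.0,
                   p_max: float = 0.05) -> set[str]:
    """Genes with log2FC > lfc_min and raw Wald p < p_max (volcano rule).

    Uses the unadjusted p-value; the symmetric "down" set is obtained by
    applying this to the negated contrast.
    """
    if lfc_min <= 0 or p_max <= 0:
        raise ValueError("thresholds must be positive")
    t = de.table
    keep = (t["log2FoldChange"] > lfc_min) & (t["pvalue"] < p_max)
    return set(t.index[keep])


def ranked_list(de: DEResult, metric: str = "stat") -> RankedList:
    """Rank genes by a DE statistic, descending; ties break by gene id."""
    t = de.table
    if metric not in t.columns:
        raise KeyError(f"unknown ranking metric {metric!r}")
    scores = t[metric]
    bad = scores.index[~np.isfinite(scores)]
    if len(bad):
        raise ValueError(f"non-finite ranking statistic for genes: {list(bad[:5])}")
    order = sorted(t.index, key=lambda g: (-scores[g], g))
    return RankedList(list(order), scores.reindex(order).to_numpy(dtype=float))
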