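"""Preranked GSEA and single-sample GSEA, implemented from first principles.

The enrichment score is the classical weighted Kolmogorov-Smirnov-like
running-sum statistic: walking the ranked list, hits increment the sum by
``|r|^p / N_R`` (with ``N_R`` the sum of ``|r|^p`` over set members) and
misses decrement it by ``1/(N - N_H)``; ES is the maximal signed deviation.
Significance comes from a gene-label permutation null (size-matched random
sets from the ranked universe), NES divides ES by the mean magnitude of
same-sign permuted scores, and the multiple-testing filter uses BH over the
permutation p-values.

ssGSEA scores one sample at a time: genes are ranked by expression, and the
score is the integrated difference between the rank-weighted in-set ECDF
(weights ``rank^alpha``) and the uniform out-of-set ECDF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix, GeneSetCollection, PassigError
from .diffexpr import RankedList, bh_adjust

__all__ = ["GseaResult", "CandidateSet", "gsea_es", "gsea_permutation",
           "gsea_all", "select_candidates", "ssgsea_score", "welch_fdr",
           "EmptyCandidatesError"]

DEFAULT_GSEA_WEIGHT = 1.0
DEFAULT_SSGSEA_ALPHA = 0.25


class DegenerateSetError(PassigError):
    """Gene set does not intersect the ranked list, or covers all of it."""


class EmptyCandidatesError(PassigError):
    """No pathway survived the ES > 0 and FDR filter."""


@dataclass
class GseaResult:
    pathway: str
    size: int                  # genes of the set present in the ranked list
    es: float
    nes: float
    pvalue: float
    padj: float                # BH across all tested pathways
    leading_edge: list[str]
    peak_index: int            # 0-based position of the running-sum extremum
    nes_unstable: bool = False


@dataclass
class CandidateSet:
    """Top pathways (ES > 0, FDR-filtered, NES-ranked, truncated)."""

    pathways: list[str]
    nes: dict[str, float]
    leading_edges: dict[str, set[str]]

    def __post_init__(self) -> None:
        if list(self.pathways) != sorted(self.pathways,
                                         key=lambda p: -self.nes[p]):
            raise ValueError("candidate pathways must be NES-sorted")

    def as_collection(self) -> GeneSetCollection:
        return GeneSetCollection(
            {p: set(self.leading_edges[p]) for p in self.pathways},
            {p: f"leading edge (NES={self.nes[p]:.4f})" for p in self.pathways},
        )


def gsea_es(ranked: RankedList, geneset: set[str],
            weight: float = DEFAULT_GSEA_WEIGHT
            ) -> tuple[float, np.ndarray, list[str], int]:
    """Enrichment score, full running sum, leading edge and peak position.

    Returns ``(es, running_sum, leading_edge, peak_index)`` where
    ``running_sum[i]`` is the value after processing position ``i`` of the
    ranked list. For positive ES the leading edge holds the set members at or
    before the peak; for negative ES those strictly after it.
    """
    genes = ranked.genes
    n = len(genes)
    hit = np.fromiter((g in geneset for g in genes), dtype=bool, count=n)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise DegenerateSetError("gene set does not intersect the ranked list")
    if n_hit == n:
        raise DegenerateSetError("gene set covers the whole ranked list")
    w = np.abs(ranked.scores) ** weight
    n_r = w[hit].sum()
    if n_r == 0:
        # all set members have zero score: fall back to unweighted hits
        steps = np.where(hit, 1.0 / n_hit, -1.0 / (n - n_hit))
    else:
        steps = np.where(hit, w / n_r, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    es = running[i_max] if running[i_max] >= -running[i_min] else running[i_min]
    if es >= 0:
        peak = i_max
        le = [g for j, g in enumerate(genes[: peak + 1]) if hit[j]]
    else:
        peak = i_min
        le = [g for j, g in enumerate(genes) if j > peak and hit[j]]
    return float(es), running, le, peak


def _es_for_hit_positions(pos: np.ndarray, w_sorted: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for many size-matched hit-position vectors.

    ``pos`` is (n_perm, m) of sorted 0-based hit positions; ``w_sorted`` the
    matching ``|r|^p`` weights. The running sum is piecewise linear between
    hits, so its extrema occur just before or at hit positions (or at the
    ends); evaluating only those O(m) points per permutation suffices.
    """
    n_perm, m = pos.shape
    miss_denom = n - m
    cum_w = np.cumsum(w_sorted, axis=1)
    tot_w = cum_w[:, -1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        cum_hit = np.where(tot_w > 0, cum_w / tot_w, 0.0)
    if np.any(tot_w == 0):
        # degenerate all-zero weights: unweighted hit increments
        unw = (np.arange(1, m + 1, dtype=float) / m)[None, :]
        cum_hit = np.where(tot_w > 0, cum_hit, unw)
    k = np.arange(1, m + 1, dtype=float)[None, :]
    # value at hit k: cum_hit_k - (pos_k + 1 - k)/miss_denom
    at_hits = cum_hit - (pos + 1 - k) / miss_denom
    # value just before hit k: cum_hit_{k-1} - (pos_k - (k-1))/miss_denom
    prev_hit = np.concatenate([np.zeros((n_perm, 1)), cum_hit[:, :-1]], axis=1)
    before_hits = prev_hit - (pos - (k - 1)) / miss_denom
    maxima = np.maximum(at_hits.max(axis=1), 0.0)
    minima = np.minimum(before_hits.min(axis=1), 0.0)
    return np.where(maxima >= -minima, maxima, minima)


def gsea_permutation(ranked: RankedList, geneset: set[str],
                     n_perm: int = 10000, seed: int = 0,
                     weight: float = DEFAULT_GSEA_WEIGHT
                     ) -> tuple[float, float, float, bool]:
    """Permutation p and NES for one gene set.

    Draws ``n_perm`` random same-size gene sets from the ranked universe,
    computes their ES, and returns
    ``p = (1 + #{same-sign |ES_perm| >= |ES|}) / (1 + #same-sign)`` together
    with ``NES = ES / mean(|ES_perm| of the same sign)``.
    Returns ``(es, nes, p, nes_unstable)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    es, _, _, _ = gsea_es(ranked, geneset, weight=weight)
    n = len(ranked)
    m = len(set(ranked.genes) & geneset)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    w_all = np.abs(ranked.scores) ** weight
    # size-matched sets drawn in chunks: argpartition of uniform keys gives a
    # uniform m-subset per row without a Python-level loop
    chunks = []
    chunk_size = max(1, min(n_perm, int(4e6 // max(n, 1)) or 1))
    done = 0
    while done < n_perm:
        k = min(chunk_size, n_perm - done)
        u = rng.random((k, n))
        pos = np.argpartition(u, m - 1, axis=1)[:, :m] if m < n else \
            np.tile(np.arange(n), (k, 1))
        pos = np.sort(pos, axis=1)
        chunks.append(_es_for_hit_positions(pos, w_all[pos], n))
        done += k
    perm_es = np.concatenate(chunks)
    same_sign = perm_es > 0 if es >= 0 else perm_es < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        return es, float(np.sign(es)), 1.0 / (1.0 + n_perm), True
    mags = np.abs(perm_es[same_sign])
    p = (1.0 + float((mags >= abs(es)).sum())) / (1.0 + n_same)
    nes = es / float(mags.mean())
    return es, float(nes), float(p), False


def gsea_all(ranked: RankedList, collection: GeneSetCollection,
             n_perm: int = 10000, seed: int = 0,
             weight: float = DEFAULT_GSEA_WEIGHT,
             min_size: int = 1) -> list[GseaResult]:
    """Run preranked GSEA over a collection with BH adjustment across sets.

    Sets with no genes in the ranked list are skipped. The per-set
    permutation seed is derived deterministically from ``seed`` and the
    pathway's position in the collection.
    """
    universe = set(ranked.genes)
    rows = []
    for idx, (name, genes) in enumerate(collection.items()):
        present = genes & universe
        if len(present) < min_size or len(present) >= len(universe):
            continue
        es, _, le, peak = gsea_es(ranked, genes, weight=weight)
        _, nes, p, unstable = gsea_permutation(
            ranked, genes, n_perm=n_perm, seed=(seed * 100003 + idx) % (2**31),
            weight=weight)
        rows.append(GseaResult(pathway=name, size=len(present), es=es, nes=nes,
                               pvalue=p, padj=np.nan, leading_edge=le,
                               peak_index=peak, nes_unstable=unstable))
    if rows:
        padj = bh_adjust(np.array([r.pvalue for r in rows]))
        for r, q in zip(rows, padj):
            r.padj = float(q)
    return rows


def select_candidates(results: list[GseaResult], fdr_max: float = 0.05,
                      top_k: int = 15) -> CandidateSet:
    """Filter to ES > 0 and FDR < fdr_max, rank by NES, keep the top k."""
    passing = [r for r in results if r.es > 0 and r.padj < fdr_max]
    if not passing:
        raise EmptyCandidatesError(
            "no pathway passed ES > 0 and FDR < "
            f"{fdr_max}; cannot build a signature")
    passing.sort(key=lambda r: (-r.nes, r.pvalue, r.pathway))
    keep = passing[:top_k]
    return CandidateSet(
        pathways=[r.pathway for r in keep],
        nes={r.pathway: r.nes for r in keep},
        leading_edges={r.pathway: set(r.leading_edge) for r in keep},
    )


def results_to_frame(results: list[GseaResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pathway": r.pathway, "size": r.size, "ES": r.es, "NES": r.nes,
        "pval": r.pvalue, "padj": r.padj,
        "leadingEdge": ",".join(sorted(r.leading_edge)),
    } for r in results])


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def ssgsea_score(tpm: ExpressionMatrix, genesets: GeneSetCollection,
                 alpha: float = DEFAULT_SSGSEA_ALPHA,
                 normalize: bool = True,
                 min_present_fraction: float = 0.5) -> pd.DataFrame:
    """ssGSEA score of each gene set in each sample.

    Per sample, genes are ordered by decreasing expression rank and the score
    integrates the difference between the weighted in-set ECDF (weights
    ``rank^alpha``) and the uniform out-of-set ECDF. With ``normalize`` the
    whole matrix is divided by its (max - min); validation cohorts should be
    scored within their own matrix so this coupling never crosses cohorts.

    Gene-set members absent from the matrix are dropped; a set missing more
    than ``1 - min_present_fraction`` of its genes is an error.
    """
    gene_index = pd.Index(tpm.gene_ids)
    n = len(gene_index)
    memberships = {}
    for name, genes in genesets.items():
        present = [g for g in genes if g in gene_index]
        if not present:
            raise DegenerateSetError(f"gene set {name!r} has no genes in the matrix")
        if len(present) < min_present_fraction * len(genes):
            raise DegenerateSetError(
                f"gene set {name!r}: only {len(present)}/{len(genes)} genes present")
        if len(present) == n:
            raise DegenerateSetError(f"gene set {name!r} covers all genes")
        memberships[name] = gene_index.isin(present)

    arr = tpm.values.to_numpy(dtype=float)
    scores = np.zeros((len(memberships), tpm.shape[1]))
    names = list(memberships)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")
        order = np.lexsort((np.asarray(gene_index), -ranks))  # desc rank, id tiebreak
        r_sorted = ranks[order]
        w = np.abs(r_sorted) ** alpha
        for k, name in enumerate(names):
            inset = memberships[name][order]
            w_in = np.where(inset, w, 0.0)
            denom_in = w_in.sum()
            ecdf_in = np.cumsum(w_in) / denom_in
            n_out = n - inset.sum()
            ecdf_out = np.cumsum(~inset) / n_out
            scores[k, j] = float(np.sum(ecdf_in - ecdf_out))
    out = pd.DataFrame(scores, index=names, columns=tpm.sample_ids)
    if normalize:
        span = float(out.to_numpy().max() - out.to_numpy().min())
        if span > 0:
            out = out / span
    return out


def welch_fdr(scores: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-pathway two-sided Welch t-test of R vs NR, BH-corrected.

    ``labels`` maps sample id -> R/NR; samples with other labels are ignored.
    Zero-variance degenerate groups are handled: equal means give t=0, p=1;
    unequal means with zero pooled variance give p=0 (the limiting normal).
    """
    lab = labels.reindex(scores.columns)
    r_cols = lab.index[lab == "R"]
    nr_cols = lab.index[lab == "NR"]
    if len(r_cols) < 2 or len(nr_cols) < 2:
        raise ValueError("need at least 2 samples per class")
    a = scores[list(r_cols)].to_numpy(dtype=float)
    b = scores[list(nr_cols)].to_numpy(dtype=float)
    t_stat = np.zeros(len(scores))
    p_val = np.ones(len(scores))
    for i in range(len(scores)):
        va, vb = a[i].var(ddof=1), b[i].var(ddof=1)
        if va == 0 and vb == 0:
            diff = a[i].mean() - b[i].mean()
            t_stat[i], p_val[i] = (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
        else:
            res = stats.ttest_ind(a[i], b[i], equal_var=False)
            t_stat[i], p_val[i] = res.statistic, res.pvalue
    return pd.DataFrame({
        "t": t_stat, "pvalue": p_val, "fdr": bh_adjust(p_val),
    }, index=scores.index)
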