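"""ROC/AUC, confusion metrics, rank-sum tests, resampling signature
comparison, and scoring engines for published transcriptomic signatures.

AUC is the Mann-Whitney concordance probability (ties count half), which
equals the trapezoidal area under the empirical ROC curve. The signature
comparison repeats stratified 80% subsampling (without replacement, keeping
the R/NR proportion within each cohort) and compares the resulting AUC
distributions with a one-sided rank-sum test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm

from .datamodel import ExpressionMatrix, PassigError

__all__ = ["RocCurve", "ConfusionMetrics", "SignatureComparison", "roc_auc",
           "confusion_metrics", "rank_sum_test",
           "compare_signatures_resampling", "published_signature_scores"]


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    mcc: float


@dataclass
class SignatureComparison:
    """Resampled AUC vectors and pairwise one-sided rank-sum p-values."""

    auc_table: pd.DataFrame        # n_rep x signatures
    mean_auc: pd.Series
    sd_auc: pd.Series
    pvalues: pd.DataFrame          # p[target, other]: P(target AUCs > other's)


def _as_binary(labels) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.dtype.kind in "UO":
        return lab == "R"
    return lab.astype(bool)


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve with the Mann-Whitney concordance AUC.

    ``labels`` may be boolean or R/NR strings (R = positive).
    """
    s = np.asarray(scores, dtype=float)
    pos = _as_binary(labels)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for a ROC curve")
    ranks = stats.rankdata(s)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)
    fpr, tpr, thr = skm.roc_curve(pos.astype(int), s)
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(auc))


def confusion_metrics(pred, truth) -> ConfusionMetrics:
    """Accuracy and Matthews correlation of binary predictions.

    MCC is defined as 0 when any marginal of the confusion matrix is empty.
    """
    p = _as_binary(pred)
    t = _as_binary(truth)
    if len(p) != len(t):
        raise ValueError("prediction and truth lengths differ")
    tp = int((p & t).sum())
    tn = int((~p & ~t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    n = len(p)
    acc = (tp + tn) / n
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn,
                            accuracy=float(acc), mcc=float(mcc))


def rank_sum_test(x, y, alternative: str = "greater") -> tuple[float, float]:
    """Wilcoxon-Mann-Whitney U test of x vs y.

    Exact enumeration is used for small untied samples (min n <= 8); otherwise
    the normal approximation with tie correction. ``alternative`` follows
    scipy ('greater' tests whether x tends to exceed y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty input to rank_sum_test")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def compare_signatures_resampling(score_table: pd.DataFrame, labels: pd.Series,
                                  cohorts: pd.Series, target: str,
                                  n_rep: int = 1000, frac: float = 0.8,
                                  seed: int = 0) -> SignatureComparison:
    """Stratified-resampling AUC comparison of signatures.

    ``score_table`` is samples x signatures; ``labels`` (R/NR) and
    ``cohorts`` are indexed by sample id. Each repetition draws
    ``ceil(frac * n)`` samples per cohort-x-class stratum without
    replacement, computes every signature's AUC on the union, and the
    ``target`` signature's AUC vector is compared against each other
    signature with a one-sided rank-sum test (alternative: target greater).
    """
    if score_table.shape[1] < 2:
        raise ValueError("need at least two signatures to compare")
    if target not in score_table.columns:
        raise KeyError(f"unknown target signature {target!r}")
    lab = labels.reindex(score_table.index)
    coh = cohorts.reindex(score_table.index)
    strata: list[np.ndarray] = []
    for c in coh.unique():
        for y in ("R", "NR"):
            idx = np.flatnonzero((coh == c).to_numpy() & (lab == y).to_numpy())
            if len(idx) == 0:
                raise ValueError(f"stratum cohort={c} class={y} is empty")
            strata.append(idx)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    ybin = (lab == "R").to_numpy()
    arr = score_table.to_numpy(dtype=float)
    aucs = np.zeros((n_rep, score_table.shape[1]))
    for rep in range(n_rep):
        chosen = np.concatenate([
            rng.choice(idx, size=int(np.ceil(frac * len(idx))), replace=False)
            for idx in strata])
        yb = ybin[chosen]
        for j in range(arr.shape[1]):
            aucs[rep, j] = roc_auc(arr[chosen, j], yb).auc
    table = pd.DataFrame(aucs, columns=score_table.columns)
    pvals = {}
    for other in score_table.columns:
        if other == target:
            continue
        _, p = rank_sum_test(table[target], table[other], alternative="greater")
        pvals[other] = p
    pframe = pd.DataFrame({target: pvals}).T
    return SignatureComparison(auc_table=table, mean_auc=table.mean(),
                               sd_auc=table.std(ddof=1), pvalues=pframe)


# ---------------------------------------------------------------------------
# Published comparator signatures
# ---------------------------------------------------------------------------

def load_comparator_definitions() -> dict:
    """Bundled reconstructions of published comparator signatures.

    The gene lists are approximate literature reconstructions (the file says
    so); swap in exact lists for a serious benchmark.
    """
    import importlib.resources as res
    with res.files("passig").joinpath("data/comparator_signatures.json").open() as fh:
        obj = json.load(fh)
    obj.pop("_comment", None)
    return obj


def published_signature_scores(tpm: ExpressionMatrix,
                               definitions: dict) -> pd.DataFrame:
    """Score samples on externally defined signatures.

    ``definitions`` maps signature name to a dict with a ``type`` key:

    - ``mean``: mean of ``log2(TPM + 1)`` over ``genes``
    - ``geomean``: geometric mean of ``(TPM + 1)`` over ``genes``
    - ``ratio``: ``log2((TPM_a + 1) / (TPM_b + 1))`` for ``numerator`` /
      ``denominator`` genes
    - ``pairs``: count of gene pairs ``[a, b]`` with expression(a) <
      expression(b) (checkpoint-pair style)

    Genes absent from the matrix beyond ``missing_tolerance`` (default 0.5 of
    the list) raise an error naming them.
    """
    vals = tpm.values
    out = {}
    for name, defn in definitions.items():
        kind = defn["type"]
        tol = float(defn.get("missing_tolerance", 0.5))

        def present(genes: list[str]) -> list[str]:
            have = [g for g in genes if g in vals.index]
            if len(have) < (1 - tol) * len(genes) or not have:
                missing = sorted(set(genes) - set(have))
                raise PassigError(
                    f"signature {name!r}: too many genes missing: {missing[:10]}")
            return have

        if kind == "mean":
            genes = present(defn["genes"])
            out[name] = np.log2(vals.loc[genes] + 1.0).mean(axis=0)
        elif kind == "geomean":
            genes = present(defn["genes"])
            out[name] = np.exp(np.log(vals.loc[genes] + 1.0).mean(axis=0))
        elif kind == "ratio":
            a, b = defn["numerator"], defn["denominator"]
            if a not in vals.index or b not in vals.index:
                raise PassigError(f"signature {name!r}: ratio genes missing")
            out[name] = np.log2((vals.loc[a] + 1.0) / (vals.loc[b] + 1.0))
        elif kind == "pairs":
            pairs = [(a, b) for a, b in defn["pairs"]
                     if a in vals.index and b in vals.index]
            if len(pairs) < (1 - tol) * len(defn["pairs"]) or not pairs:
                raise PassigError(f"signature {name!r}: too many pairs missing")
            score = np.zeros(vals.shape[1])
            for a, b in pairs:
                score += (vals.loc[a].to_numpy() < vals.loc[b].to_numpy())
            out[name] = pd.Series(score, index=vals.columns)
        else:
            raise PassigError(f"signature {name!r}: unknown type {kind!r}")
    return pd.DataFrame(out)
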