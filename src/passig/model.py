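"""Cost-sensitive elastic-net logistic regression and PASS signature building.

The classifier minimizes the weighted penalized negative log-likelihood

    (1/n) sum_i w_i [log(1 + e^eta_i) - y_i eta_i]
        + lambda * (alpha ||beta||_1 + (1 - alpha)/2 ||beta||_2^2)

with observation weights w_i inversely proportional to class frequency
(normalized to mean 1), fitted by iteratively reweighted least squares with
cyclic coordinate descent along a 100-point log-spaced lambda path from the
KKT-derived lambda_max. The penalty is chosen by stratified 3-fold
cross-validation on weighted binomial deviance with the one-standard-error
rule: the largest lambda whose CV deviance is within one SE of the minimum.

The PASS score of a sample is the coefficient-weighted average of its
pathway ssGSEA values, ``sum_k beta_k x_k / sum_k |beta_k|``; the logistic
odds ``exp(beta0 + sum_k beta_k x_k)`` drive the survival stratification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .datamodel import (ExpressionMatrix, GeneLengthTable, GeneSetCollection,
                        SampleTable, PassigError, counts_to_tpm)
from . import diffexpr as de_mod
from . import enrichment as enr_mod

__all__ = ["EnlrModel", "PassSignature", "fit_enlr", "fit_enlr_fixed",
           "enlr_objective", "pass_score", "sample_odds", "youden_cutoff",
           "train_signature", "train_time_signatures", "TrainSettings",
           "DegenerateModelError"]

N_LAMBDA = 100
LAMBDA_MIN_RATIO = 1e-4
IRLS_WEIGHT_FLOOR = 1e-5


class DegenerateModelError(PassigError):
    """The fitted model carries no information (all coefficients zero)."""


# ---------------------------------------------------------------------------
# Elastic-net logistic regression (IRLS + coordinate descent)
# ---------------------------------------------------------------------------

def class_weights(y: np.ndarray) -> np.ndarray:
    """Inverse-class-frequency observation weights, normalized to mean 1."""
    y = np.asarray(y)
    n = len(y)
    n1 = int(y.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    w = np.where(y == 1, n / (2.0 * n1), n / (2.0 * n0))
    return w


def enlr_objective(beta0: float, beta: np.ndarray, X: np.ndarray,
                   y: np.ndarray, w: np.ndarray, alpha: float,
                   lam: float) -> float:
    """Penalized weighted logistic objective (features already standardized)."""
    eta = beta0 + X @ beta
    # log(1+e^eta) - y*eta, computed stably
    loss = np.logaddexp(0.0, eta) - y * eta
    penalty = lam * (alpha * np.abs(beta).sum() + 0.5 * (1 - alpha) * (beta ** 2).sum())
    return float(np.mean(w * loss) + penalty)


def _soft(x: float, t: float) -> float:
    return np.sign(x) * max(abs(x) - t, 0.0)


def _cd_wls(X: np.ndarray, z: np.ndarray, v: np.ndarray, beta0: float,
            beta: np.ndarray, alpha: float, lam: float, tol: float,
            max_iter: int = 1000) -> tuple[float, np.ndarray]:
    """Cyclic coordinate descent on the penalized weighted least squares."""
    n, k = X.shape
    vx2 = (v[:, None] * X ** 2).sum(axis=0) / n
    vsum = v.sum()
    r = z - beta0 - X @ beta  # residual
    for _ in range(max_iter):
        delta = 0.0
        # intercept (unpenalized)
        b0_new = beta0 + (v @ r) / vsum
        r -= b0_new - beta0
        delta = max(delta, abs(b0_new - beta0))
        beta0 = b0_new
        for j in range(k):
            bj = beta[j]
            rho = (v * X[:, j] @ r) / n + vx2[j] * bj
            bj_new = _soft(rho, lam * alpha) / (vx2[j] + lam * (1 - alpha))
            if bj_new != bj:
                r -= X[:, j] * (bj_new - bj)
                delta = max(delta, abs(bj_new - bj))
                beta[j] = bj_new
        if delta < tol:
            break
    return beta0, beta


def fit_enlr_fixed(X: np.ndarray, y: np.ndarray, w: np.ndarray, alpha: float,
                   lam: float, beta0: float = 0.0,
                   beta: np.ndarray | None = None, tol: float = 1e-9,
                   max_outer: int = 100) -> tuple[float, np.ndarray]:
    """Fit at a single lambda by IRLS with a coordinate-descent inner solve.

    ``X`` must be standardized; returns the solution on that scale.
    """
    n, k = X.shape
    if beta is None:
        beta = np.zeros(k)
    beta = beta.copy()
    for _ in range(max_outer):
        eta = beta0 + X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        v = np.clip(p * (1 - p), IRLS_WEIGHT_FLOOR, None) * w
        z = eta + (y - p) / np.clip(p * (1 - p), IRLS_WEIGHT_FLOOR, None)
        b0_old, b_old = beta0, beta.copy()
        beta0, beta = _cd_wls(X, z, v, beta0, beta, alpha, lam, tol=tol)
        if abs(beta0 - b0_old) < 1e-8 and np.max(np.abs(beta - b_old), initial=0.0) < 1e-8:
            break
    return beta0, beta


def lambda_max(X: np.ndarray, y: np.ndarray, w: np.ndarray,
               alpha: float) -> float:
    """Smallest lambda at which the all-zero coefficient vector is optimal.

    From KKT stationarity at the weighted-intercept-only model:
    ``lambda_max = max_k |(1/n) sum_i w_i x_ik (y_i - ybar_w)| / alpha``.
    """
    n = len(y)
    ybar = float((w * y).sum() / w.sum())
    grad = np.abs((w * (y - ybar)) @ X) / n
    if alpha <= 0:
        raise ValueError("alpha must be positive for a finite lambda_max")
    return float(grad.max() / alpha)


def _weighted_deviance(beta0: float, beta: np.ndarray, X: np.ndarray,
                       y: np.ndarray, w: np.ndarray) -> float:
    eta = beta0 + X @ beta
    loss = np.logaddexp(0.0, eta) - y * eta
    return float(2.0 * np.mean(w * loss))


@dataclass
class EnlrModel:
    """Fitted cost-sensitive elastic-net logistic model over pathway scores."""

    feature_names: list[str]
    intercept: float                      # original (unstandardized) scale
    coef: pd.Series                       # original scale, indexed by feature
    alpha_mix: float
    lambda_path: np.ndarray
    lambda_chosen: float
    lambda_index: int
    cv_mean: np.ndarray
    cv_se: np.ndarray
    class_weight_map: dict[str, float]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    fold_assignments: np.ndarray
    seed: int
    intercept_std: float = 0.0            # standardized-scale solution, for KKT
    coef_std: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def nonzero(self) -> pd.Series:
        return self.coef[self.coef != 0.0]

    def linear_predictor(self, X: pd.DataFrame) -> pd.Series:
        """eta per sample; X is features x samples."""
        Xm = X.reindex(self.feature_names).to_numpy(dtype=float).T
        return pd.Series(self.intercept + Xm @ self.coef.to_numpy(),
                         index=X.columns)


def fit_enlr(X: pd.DataFrame, y: pd.Series, alpha_mix: float = 0.5,
             n_folds: int = 3, seed: int = 0,
             n_lambda: int = N_LAMBDA,
             lambda_min_ratio: float = LAMBDA_MIN_RATIO) -> EnlrModel:
    """Fit the cost-sensitive elastic net over a pathway-score matrix.

    ``X`` is features (pathways) x samples; ``y`` maps sample id to R/NR.
    Lambda is selected by the one-standard-error rule on stratified
    ``n_folds``-fold CV of the weighted binomial deviance.
    """
    samples = list(X.columns)
    yv = y.reindex(samples)
    if yv.isna().any():
        raise ValueError("labels missing for some samples")
    yb = (yv == "R").to_numpy(dtype=float)
    if yb.sum() < n_folds or (1 - yb).sum() < n_folds:
        raise ValueError("need at least n_folds samples per class")
    feats = list(X.index)
    Xm = X.to_numpy(dtype=float).T  # samples x features
    mu = Xm.mean(axis=0)
    sd = Xm.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (Xm - mu) / sd
    w = class_weights(yb)

    lmax = lambda_max(Xs, yb, w, alpha_mix)
    path = lmax * np.logspace(0, np.log10(lambda_min_ratio), n_lambda)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.zeros(len(yb), dtype=int)
    dev = np.zeros((n_folds, n_lambda))
    for f, (tr, va) in enumerate(skf.split(Xs, yb)):
        folds[va] = f
        w_tr = class_weights(yb[tr])
        b0, b = 0.0, np.zeros(len(feats))
        for li, lam in enumerate(path):
            b0, b = fit_enlr_fixed(Xs[tr], yb[tr], w_tr, alpha_mix, lam,
                                   beta0=b0, beta=b)
            dev[f, li] = _weighted_deviance(b0, b, Xs[va], yb[va], w[va])
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(cv_mean))
    threshold = cv_mean[i_min] + cv_se[i_min]
    i_1se = int(np.argmax(cv_mean <= threshold))  # first (largest) qualifying lambda

    b0, b = 0.0, np.zeros(len(feats))
    for li in range(i_1se + 1):
        b0, b = fit_enlr_fixed(Xs, yb, w, alpha_mix, path[li], beta0=b0, beta=b)
    lam = float(path[i_1se])

    coef_orig = b / sd
    intercept_orig = b0 - float((b * mu / sd).sum())
    return EnlrModel(
        feature_names=feats,
        intercept=float(intercept_orig),
        coef=pd.Series(coef_orig, index=feats),
        alpha_mix=alpha_mix,
        lambda_path=path,
        lambda_chosen=lam,
        lambda_index=i_1se,
        cv_mean=cv_mean,
        cv_se=cv_se,
        class_weight_map={"R": float(w[yb == 1][0]) if (yb == 1).any() else 1.0,
                          "NR": float(w[yb == 0][0]) if (yb == 0).any() else 1.0},
        feature_means=mu,
        feature_sds=sd,
        fold_assignments=folds,
        seed=seed,
        intercept_std=float(b0),
        coef_std=b,
    )


# ---------------------------------------------------------------------------
# PASS score, odds, cutoff
# ---------------------------------------------------------------------------

@dataclass
class PassSignature:
    """A trained pathway super signature: pathways, weights, cutoff."""

    pathways: list[str]
    leading_edges: dict[str, set[str]]
    effect_sizes: dict[str, float]
    intercept: float
    cutoff: float
    timepoint: str
    alpha_mix: float
    lambda_chosen: float
    ssgsea_alpha: float
    ssgsea_normalize: bool
    seed: int
    name: str = "PASS"

    def __post_init__(self) -> None:
        if set(self.pathways) != set(self.effect_sizes):
            raise ValueError("pathways and effect sizes must align")
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")

    def genesets(self) -> GeneSetCollection:
        return GeneSetCollection(
            {p: set(self.leading_edges[p]) for p in self.pathways})

    def to_json(self, path) -> None:
        obj = {
            "name": self.name,
            "timepoint": self.timepoint,
            "pathways": self.pathways,
            "leading_edges": {p: sorted(self.leading_edges[p]) for p in self.pathways},
            "effect_sizes": self.effect_sizes,
            "intercept": self.intercept,
            "cutoff": self.cutoff,
            "alpha_mix": self.alpha_mix,
            "lambda": self.lambda_chosen,
            "ssgsea_alpha": self.ssgsea_alpha,
            "ssgsea_normalize": self.ssgsea_normalize,
            "seed": self.seed,
        }
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "PassSignature":
        with open(path, "rt", encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls(
            pathways=list(obj["pathways"]),
            leading_edges={p: set(v) for p, v in obj["leading_edges"].items()},
            effect_sizes={p: float(v) for p, v in obj["effect_sizes"].items()},
            intercept=float(obj["intercept"]),
            cutoff=float(obj["cutoff"]),
            timepoint=obj["timepoint"],
            alpha_mix=float(obj["alpha_mix"]),
            lambda_chosen=float(obj["lambda"]),
            ssgsea_alpha=float(obj["ssgsea_alpha"]),
            ssgsea_normalize=bool(obj["ssgsea_normalize"]),
            seed=int(obj["seed"]),
            name=obj.get("name", "PASS"),
        )


def pass_score(signature: PassSignature, X: pd.DataFrame) -> pd.Series:
    """Weighted average of pathway scores, weights = effect sizes.

    ``score_j = sum_k beta_k x_kj / sum_k |beta_k|`` — invariant to positive
    rescaling of the coefficient vector.
    """
    missing = [p for p in signature.pathways if p not in X.index]
    if missing:
        raise KeyError(f"pathway scores missing: {missing}")
    beta = np.array([signature.effect_sizes[p] for p in signature.pathways])
    denom = np.abs(beta).sum()
    if denom == 0:
        raise DegenerateModelError("all effect sizes are zero")
    vals = X.reindex(signature.pathways).to_numpy(dtype=float)
    return pd.Series((beta @ vals) / denom, index=X.columns, name="pass_score")


def sample_odds(model_or_sig, X: pd.DataFrame) -> pd.Series:
    """Per-sample logistic odds ``exp(beta0 + sum_k beta_k x_kj)``."""
    if isinstance(model_or_sig, EnlrModel):
        eta = model_or_sig.linear_predictor(X)
    else:
        sig: PassSignature = model_or_sig
        beta = np.array([sig.effect_sizes[p] for p in sig.pathways])
        vals = X.reindex(sig.pathways).to_numpy(dtype=float)
        eta = pd.Series(sig.intercept + beta @ vals, index=X.columns)
    return np.exp(eta).rename("odds")


def youden_cutoff(scores, labels) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are the midpoints of consecutive sorted unique
    scores, plus sentinels below and above all scores; classification is
    ``score > cutoff -> positive``. Ties resolve to the smallest threshold.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    pos = lab == "R" if lab.dtype.kind in "UO" else lab.astype(bool)
    if pos.all() or (~pos).all():
        raise ValueError("both classes required for a cutoff")
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.array([])
    span = max(uniq[-1] - uniq[0], 1.0)
    cands = np.concatenate([[uniq[0] - span], mids, [uniq[-1] + span]])
    n_pos, n_neg = pos.sum(), (~pos).sum()
    best_j, best_c = -np.inf, cands[0]
    for c in cands:
        pred = s > c
        sens = (pred & pos).sum() / n_pos
        spec = (~pred & ~pos).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return float(best_c)


# ---------------------------------------------------------------------------
# Training pipelines
# ---------------------------------------------------------------------------

@dataclass
class TrainSettings:
    """Knobs of the training pipeline (volcano, GSEA, ssGSEA, ENLR)."""

    lfc_min: float = 1.0
    p_max: float = 0.05
    rank_metric: str = "stat"
    n_perm: int = 10000
    gsea_weight: float = 1.0
    fdr_max: float = 0.05
    top_k: int = 15
    ssgsea_alpha: float = 0.25
    ssgsea_normalize: bool = True
    alpha_mix: float = 0.5
    n_folds: int = 3
    min_per_class: int = 5
    seed: int = 0


@dataclass
class TrainReport:
    """Stage-by-stage account of one training run."""

    n_samples: int
    n_r: int
    n_nr: int
    n_genes: int
    n_up: int
    n_gsea_survivors: int
    candidates: list[str]
    selected: list[str]
    training_auc: float
    cutoff: float


def _de_and_candidates(counts: ExpressionMatrix, group_a: list[str],
                       group_b: list[str], genesets: GeneSetCollection,
                       cfg: TrainSettings) -> tuple[enr_mod.CandidateSet, dict]:
    sf = de_mod.size_factors(counts)
    phi = de_mod.estimate_dispersion(counts, sf)
    de = de_mod.nb_wald_test(counts, sf, phi, group_a, group_b)
    up = de_mod.significant_up(de, cfg.lfc_min, cfg.p_max)
    ranked = de_mod.ranked_list(de, metric=cfg.rank_metric)
    results = enr_mod.gsea_all(ranked, genesets, n_perm=cfg.n_perm,
                               seed=cfg.seed, weight=cfg.gsea_weight)
    survivors = [r for r in results if r.es > 0 and r.padj < cfg.fdr_max]
    cand = enr_mod.select_candidates(results, fdr_max=cfg.fdr_max,
                                     top_k=cfg.top_k)
    info = {"n_up": len(up), "n_gsea_survivors": len(survivors), "de": de,
            "ranked": ranked, "gsea": results}
    return cand, info


def _fit_on_candidates(counts: ExpressionMatrix, samples: SampleTable,
                       lengths: GeneLengthTable, cand: enr_mod.CandidateSet,
                       cfg: TrainSettings, timepoint: str,
                       name: str) -> tuple[PassSignature, EnlrModel, pd.DataFrame]:
    tpm = counts_to_tpm(counts, lengths)
    scores = enr_mod.ssgsea_score(tpm, cand.as_collection(),
                                  alpha=cfg.ssgsea_alpha,
                                  normalize=cfg.ssgsea_normalize)
    y = samples.labels(list(scores.columns))
    model = fit_enlr(scores, y, alpha_mix=cfg.alpha_mix, n_folds=cfg.n_folds,
                     seed=cfg.seed)
    nz = model.nonzero()
    if nz.empty:
        raise DegenerateModelError(
            "elastic net selected no pathway (all coefficients zero)")
    sig = PassSignature(
        pathways=list(nz.index),
        leading_edges={p: cand.leading_edges[p] for p in nz.index},
        effect_sizes={p: float(v) for p, v in nz.items()},
        intercept=model.intercept,
        cutoff=0.0,  # provisional; replaced by the Youden cutoff below
        timepoint=timepoint,
        alpha_mix=cfg.alpha_mix,
        lambda_chosen=model.lambda_chosen,
        ssgsea_alpha=cfg.ssgsea_alpha,
        ssgsea_normalize=cfg.ssgsea_normalize,
        seed=cfg.seed,
        name=name,
    )
    train_scores = pass_score(sig, scores)
    sig.cutoff = youden_cutoff(train_scores.to_numpy(), y.to_numpy())
    return sig, model, scores


def train_signature(counts: ExpressionMatrix, samples: SampleTable,
                    genesets: GeneSetCollection, lengths: GeneLengthTable,
                    timepoint: str, cfg: TrainSettings | None = None
                    ) -> tuple[PassSignature, EnlrModel, TrainReport]:
    """Full PASS training on one timepoint: DE -> GSEA -> ssGSEA -> ENLR.

    Differential expression contrasts responders (A) against nonresponders
    (B) among samples of ``timepoint``; candidate pathways are the top-NES
    GSEA survivors; the elastic net is fitted on their leading-edge ssGSEA
    scores and the Youden cutoff is taken from the training PASS scores.
    """
    cfg = cfg or TrainSettings()
    sub = samples.at_timepoint(timepoint)
    sub = sub.subset((sub.table["response"].isin(["R", "NR"])).to_numpy())
    r_ids = list(sub.table.loc[sub.table["response"] == "R", "sample_id"])
    nr_ids = list(sub.table.loc[sub.table["response"] == "NR", "sample_id"])
    if len(r_ids) < cfg.min_per_class or len(nr_ids) < cfg.min_per_class:
        raise ValueError(
            f"need >= {cfg.min_per_class} samples per class at {timepoint}; "
            f"got {len(r_ids)} R / {len(nr_ids)} NR")
    counts_tp = counts.subset_samples(r_ids + nr_ids)
    cand, info = _de_and_candidates(counts_tp, r_ids, nr_ids, genesets, cfg)
    sig, model, scores = _fit_on_candidates(
        counts_tp, sub, lengths, cand, cfg, timepoint, name=f"PASS-{timepoint}")
    from .metrics import roc_auc  # deferred: metrics imports nothing from here
    y = sub.labels(list(scores.columns))
    auc = roc_auc(pass_score(sig, scores).to_numpy(), (y == "R").to_numpy()).auc
    report = TrainReport(
        n_samples=len(r_ids) + len(nr_ids), n_r=len(r_ids), n_nr=len(nr_ids),
        n_genes=counts.shape[0], n_up=info["n_up"],
        n_gsea_survivors=info["n_gsea_survivors"],
        candidates=list(cand.pathways), selected=list(sig.pathways),
        training_auc=float(auc), cutoff=sig.cutoff)
    return sig, model, report


def train_time_signatures(counts: ExpressionMatrix, samples: SampleTable,
                          genesets: GeneSetCollection,
                          lengths: GeneLengthTable,
                          cfg: TrainSettings | None = None
                          ) -> tuple[PassSignature, PassSignature]:
    """Time-response variant: shared candidates, two independent models.

    Candidate pathways come from the unpaired DE contrast of responders'
    on-treatment vs pre-treatment samples; then one elastic net is fitted on
    PRE samples (R vs NR) and an independent one on ON samples, both using
    ssGSEA features of the same candidate leading edges.
    """
    cfg = cfg or TrainSettings()
    resp = samples.subset((samples.table["response"] == "R").to_numpy())
    on_ids = list(resp.table.loc[resp.table["timepoint"] == "ON", "sample_id"])
    pre_ids = list(resp.table.loc[resp.table["timepoint"] == "PRE", "sample_id"])
    if len(on_ids) < cfg.min_per_class or len(pre_ids) < cfg.min_per_class:
        raise ValueError("responders required at both timepoints")
    counts_r = counts.subset_samples(on_ids + pre_ids)
    cand, _ = _de_and_candidates(counts_r, on_ids, pre_ids, genesets, cfg)

    sigs = []
    for tp in ("PRE", "ON"):
        sub = samples.at_timepoint(tp)
        sub = sub.subset((sub.table["response"].isin(["R", "NR"])).to_numpy())
        n_r = int((sub.table["response"] == "R").sum())
        n_nr = int((sub.table["response"] == "NR").sum())
        if n_r < cfg.min_per_class or n_nr < cfg.min_per_class:
            raise ValueError(f"need both classes at {tp}")
        counts_tp = counts.subset_samples(sub.sample_ids)
        sig, _, _ = _fit_on_candidates(counts_tp, sub, lengths, cand, cfg, tp,
                                       name=f"TimeANLS-{tp}")
        sigs.append(sig)
    return sigs[0], sigs[1]
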