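"""End-to-end orchestration: training, validation, comparison, run-all.

Every public entry point is deterministic under its configuration: a single
master seed fans out to per-stage seeds through a fixed counter scheme, and
each written artifact embeds the configuration hash and seed so reruns can
be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr_mod
from .datamodel import (ExpressionMatrix, GeneLengthTable,
                        SampleTable, counts_to_tpm, read_counts, read_gmt,
                        read_lengths, read_sample_table, write_counts,
                        write_gmt, write_lengths, write_sample_table)
from .metrics import (compare_signatures_resampling, confusion_metrics,
                      rank_sum_test, roc_auc)
from .model import (PassSignature, TrainSettings, pass_score, sample_odds,
                    train_signature, train_time_signatures)
from .sim import SimulationConfig, simulate_cohort
from .surv import cox_hr_binary, km_fit, logrank_test, stratify_by_mean_odds

__all__ = ["RunConfig", "load_config", "config_hash", "run_train",
           "run_validate", "run_compare", "run_all", "validate_signature"]

# stage keys for seed fan-out (master_seed * 1000 + key, mod 2^31)
STAGE_SIM_TRAIN = 1
STAGE_SIM_TEST = 2
STAGE_TRAIN = 3
STAGE_COMPARE = 4


def stage_seed(master: int, key: int) -> int:
    return (master * 1000 + key) % (2**31)


@dataclass
class RunConfig:
    """Paths, thresholds and seeds for a full pipeline run."""

    counts_path: str | None = None
    samples_path: str | None = None
    gmt_path: str | None = None
    lengths_path: str | None = None
    timepoint: str = "PRE"
    out_dir: str = "passig_out"
    seed: int = 0
    train: TrainSettings = field(default_factory=TrainSettings)
    simulation: SimulationConfig | None = None

    @classmethod
    def from_dict(cls, obj: dict) -> "RunConfig":
        train = TrainSettings(**obj.pop("train", {}))
        sim = obj.pop("simulation", None)
        sim_cfg = SimulationConfig(**sim) if sim is not None else None
        return cls(train=train, simulation=sim_cfg, **obj)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(path) -> RunConfig:
    with open(path, "rt", encoding="utf-8") as fh:
        obj = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(obj)


def config_hash(cfg: RunConfig) -> str:
    """Hash of the scientific configuration (output location excluded)."""
    d = cfg.to_dict()
    d.pop("out_dir", None)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(cfg: RunConfig) -> dict:
    return {"config_hash": config_hash(cfg), "seed": cfg.seed}


def _load_inputs(cfg: RunConfig):
    if cfg.simulation is not None:
        counts, samples, truth, genesets, lengths = simulate_cohort(cfg.simulation)
        return counts, samples, genesets, lengths, truth
    missing = [n for n, p in [("counts_path", cfg.counts_path),
                              ("samples_path", cfg.samples_path),
                              ("gmt_path", cfg.gmt_path),
                              ("lengths_path", cfg.lengths_path)] if p is None]
    if missing:
        raise FileNotFoundError(f"config missing input paths: {missing}")
    return (read_counts(cfg.counts_path), read_sample_table(cfg.samples_path),
            read_gmt(cfg.gmt_path), read_lengths(cfg.lengths_path), None)


# ---------------------------------------------------------------------------
# Validation of a trained signature on a cohort
# ---------------------------------------------------------------------------

def validate_signature(sig: PassSignature, counts: ExpressionMatrix,
                       samples: SampleTable, lengths: GeneLengthTable,
                       timepoint: str | None = None) -> dict:
    """Score a cohort with a trained signature — no refitting.

    ssGSEA is computed within the cohort's own matrix (per-cohort
    normalization); the prediction table, AUC, accuracy/MCC at the training
    cutoff, the one-sided R-vs-NR rank-sum p, and mean-odds survival
    stratification (KM, log-rank, Cox) are returned in one dict. When the
    cohort carries a single class, metrics are reported as None but the
    prediction table is still produced.
    """
    tp = timepoint or sig.timepoint
    sub = samples.at_timepoint(tp)
    sub = sub.subset((sub.table["response"].isin(["R", "NR"])).to_numpy())
    if not len(sub.table):
        raise ValueError(f"no labeled samples at timepoint {tp}")
    cohort_counts = counts.subset_samples(sub.sample_ids)
    tpm = counts_to_tpm(cohort_counts, lengths)
    scores = enr_mod.ssgsea_score(tpm, sig.genesets(),
                                  alpha=sig.ssgsea_alpha,
                                  normalize=sig.ssgsea_normalize)
    ps = pass_score(sig, scores)
    odds = sample_odds(sig, scores)
    strata = stratify_by_mean_odds(odds)
    predicted = pd.Series(np.where(ps > sig.cutoff, "R", "NR"),
                          index=ps.index, name="predicted")
    y = sub.labels(list(ps.index))
    pred_table = pd.DataFrame({
        "sample_id": ps.index, "pass_score": ps.to_numpy(),
        "odds": odds.to_numpy(), "predicted": predicted.to_numpy(),
        "stratum": strata.to_numpy(), "response": y.to_numpy(),
    }).reset_index(drop=True)

    out: dict = {"prediction_table": pred_table, "timepoint": tp,
                 "signature": sig.name}
    if y.nunique() == 2:
        roc = roc_auc(ps.to_numpy(), y.to_numpy())
        cm = confusion_metrics(predicted.to_numpy(), y.to_numpy())
        _, p_rs = rank_sum_test(ps[y == "R"], ps[y == "NR"],
                                alternative="greater")
        out.update(auc=roc.auc, accuracy=cm.accuracy, mcc=cm.mcc,
                   rank_sum_p=p_rs)
    else:
        out.update(auc=None, accuracy=None, mcc=None, rank_sum_p=None)

    surv: dict = {}
    t = sub.table.set_index("sample_id").reindex(ps.index)
    for endpoint in ("pfs", "os"):
        times = t[f"{endpoint}_days"]
        events = t[f"{endpoint}_event"]
        ok = times.notna() & events.notna()
        hi = ok & (strata == "high")
        lo = ok & (strata == "low")
        if hi.sum() == 0 or lo.sum() == 0 or events[ok].sum() == 0:
            surv[endpoint] = None
            continue
        km_high = km_fit(times[hi], events[hi])
        km_low = km_fit(times[lo], events[lo])
        lr = logrank_test(times[hi], events[hi], times[lo], events[lo])
        # group = 1 for the LOW stratum: HR > 1 means low-odds samples fail faster
        cox = cox_hr_binary(times[ok], events[ok],
                            (strata[ok] == "low").astype(int))
        surv[endpoint] = {"km_high": km_high, "km_low": km_low,
                          "logrank": lr, "cox": cox}
    out["survival"] = surv
    return out


# ---------------------------------------------------------------------------
# Top-level runs
# ---------------------------------------------------------------------------

def run_train(cfg: RunConfig, write: bool = True):
    """Train a PASS signature per the config; returns (signature, report)."""
    counts, samples, genesets, lengths, _ = _load_inputs(cfg)
    settings = dataclasses.replace(cfg.train,
                                   seed=stage_seed(cfg.seed, STAGE_TRAIN))
    sig, model, report = train_signature(counts, samples, genesets, lengths,
                                         cfg.timepoint, settings)
    if write:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sig.to_json(out / f"signature_{cfg.timepoint}.json")
        rep = dataclasses.asdict(report) | _provenance(cfg)
        with open(out / f"train_report_{cfg.timepoint}.json", "wt") as fh:
            json.dump(rep, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return sig, report


def run_validate(sig: PassSignature, cfg: RunConfig, write: bool = True) -> dict:
    """Validate a signature on the cohort the config points to."""
    counts, samples, _, lengths, _ = _load_inputs(cfg)
    res = validate_signature(sig, counts, samples, lengths,
                             timepoint=cfg.timepoint)
    if write:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        res["prediction_table"].to_csv(
            out / f"predictions_{sig.name}_{cfg.timepoint}.tsv",
            sep="\t", index=False)
        summary = {k: res[k] for k in ("auc", "accuracy", "mcc", "rank_sum_p")}
        for endpoint, block in (res.get("survival") or {}).items():
            if block is None:
                continue
            summary[f"{endpoint}_logrank_p"] = block["logrank"].pvalue
            summary[f"{endpoint}_hr_low_vs_high"] = block["cox"].hr
        summary |= _provenance(cfg)
        with open(out / f"validate_{sig.name}_{cfg.timepoint}.json", "wt") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return res


def run_compare(score_table: pd.DataFrame, labels: pd.Series,
                cohorts: pd.Series, target: str, cfg: RunConfig,
                n_rep: int = 1000, write: bool = True):
    """Resampling AUC comparison of a target signature vs comparators."""
    comp = compare_signatures_resampling(
        score_table, labels, cohorts, target, n_rep=n_rep,
        seed=stage_seed(cfg.seed, STAGE_COMPARE))
    if write:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary = pd.DataFrame({"mean_auc": comp.mean_auc,
                                "sd_auc": comp.sd_auc})
        summary.to_csv(out / "compare_auc_summary.tsv", sep="\t",
                       index_label="signature")
        comp.pvalues.to_csv(out / "compare_pvalues.tsv", sep="\t",
                            index_label="target")
    return comp


def run_all(cfg: RunConfig) -> dict:
    """Simulate -> train (PRE, ON, time-response) -> validate -> compare.

    Requires a ``simulation`` block in the config; produces every artifact
    under ``out_dir`` and returns the in-memory results.
    """
    if cfg.simulation is None:
        raise ValueError("run_all requires a simulation block in the config")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim_train = dataclasses.replace(cfg.simulation,
                                    seed=stage_seed(cfg.seed, STAGE_SIM_TRAIN))
    sim_test = dataclasses.replace(cfg.simulation,
                                   seed=stage_seed(cfg.seed, STAGE_SIM_TEST))
    counts, samples, truth, genesets, lengths = simulate_cohort(sim_train)
    t_counts, t_samples, _, _, _ = simulate_cohort(sim_test, genesets, lengths)

    write_counts(counts, out / "train_counts.tsv")
    write_sample_table(samples, out / "train_samples.tsv")
    write_gmt(genesets, out / "genesets.gmt")
    write_lengths(lengths, out / "gene_lengths.tsv")
    with open(out / "truth.json", "wt") as fh:
        json.dump(truth.to_dict() | _provenance(cfg), fh, indent=2,
                  sort_keys=True)
        fh.write("\n")

    settings = dataclasses.replace(cfg.train,
                                   seed=stage_seed(cfg.seed, STAGE_TRAIN))
    results: dict = {"truth": truth}
    signatures = {}
    for tp in ("PRE", "ON"):
        sig, model, report = train_signature(counts, samples, genesets,
                                             lengths, tp, settings)
        sig.to_json(out / f"signature_{tp}.json")
        with open(out / f"train_report_{tp}.json", "wt") as fh:
            json.dump(dataclasses.asdict(report) | _provenance(cfg), fh,
                      indent=2, sort_keys=True)
            fh.write("\n")
        signatures[tp] = sig
        results[f"train_{tp}"] = report

    sig_tpre, sig_ton = train_time_signatures(counts, samples, genesets,
                                              lengths, settings)
    sig_tpre.to_json(out / "signature_TimeANLS_PRE.json")
    sig_ton.to_json(out / "signature_TimeANLS_ON.json")
    signatures["TimeANLS-PRE"] = sig_tpre
    signatures["TimeANLS-ON"] = sig_ton

    validations = {}
    score_cols = {}
    labels = None
    for name, sig in signatures.items():
        res = validate_signature(sig, t_counts, t_samples, lengths)
        res["prediction_table"].to_csv(out / f"predictions_{name}.tsv",
                                       sep="\t", index=False)
        validations[name] = {k: res[k] for k in ("auc", "accuracy", "mcc",
                                                 "rank_sum_p")}
        pt = res["prediction_table"].set_index("sample_id")
        if sig.timepoint == "ON":
            score_cols[name] = pt["pass_score"]
            if labels is None:
                labels = pt["response"]
    results["validation"] = validations
    with open(out / "validation_summary.json", "wt") as fh:
        json.dump(validations | _provenance(cfg), fh, indent=2, sort_keys=True)
        fh.write("\n")

    if len(score_cols) >= 2 and labels is not None:
        table = pd.DataFrame(score_cols).dropna()
        cohorts = pd.Series("sim", index=table.index)
        comp = run_compare(table, labels, cohorts,
                           target=next(iter(score_cols)), cfg=cfg,
                           n_rep=200, write=True)
        results["comparison"] = comp
    results["signatures"] = signatures
    return results
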