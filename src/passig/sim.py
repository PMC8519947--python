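"""Synthetic anti-PD1 cohort generator.

Emulates the statistical structure the downstream pipeline assumes: negative
binomial counts with library-size variation and patient-level random effects,
a small number of "driver" pathways whose member genes are upregulated in
responders (with separate pre- and on-treatment effect sizes), RECIST labels
consistent with the 180-day stable-disease rule, and exponential PFS/OS with
a responder hazard ratio and independent censoring.

The defaults define the study conditions used throughout the test suite:
2,000 genes, 50 pathways of 20-100 genes, 3 driver pathways, 100 patients at
40% responders with paired PRE/ON biopsies, on-treatment driver effect
delta_on = 1.5 log2 units against a weaker pre-treatment effect of 0.3
(responder biology is expected to sharpen under therapy), NB dispersion 0.2,
and a nonresponder/responder hazard ratio of 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    ExpressionMatrix,
    GeneLengthTable,
    GeneSetCollection,
    SampleTable,
    classify_response,
    PFS_RESPONSE_DAYS,
)

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_genesets",
           "simulate_cohort", "simulate_survival"]


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fixes every random draw."""

    n_genes: int = 2000
    n_pathways: int = 50
    pathway_size_min: int = 20
    pathway_size_max: int = 100
    pathway_overlap: float = 0.0       # fraction of each set shared with a common pool
    n_patients: int = 100
    r_fraction: float = 0.4
    timepoints: str = "both"           # "PRE", "ON", or "both" (paired biopsies)
    n_driver_pathways: int = 3
    delta_pre: float = 0.3             # log2FC added to driver genes in R, PRE samples
    delta_on: float = 1.5              # log2FC added to driver genes in R, ON samples
    log_mean_loc: float = 4.0          # baseline log2 mean expression ~ N(loc, scale)
    log_mean_scale: float = 2.0
    dispersion: float = 0.2            # NB dispersion phi, Var = mu + phi*mu^2
    libsize_log_sd: float = 0.3        # log-normal library-size factor sd
    patient_effect_sd: float = 0.2     # patient-level log2 offset (pairs PRE/ON)
    pathway_patient_sd: float = 0.5    # per-patient per-pathway log2 offset:
                                       # correlated within-module biological
                                       # noise that does not average away in
                                       # pathway-level scores
    hazard_nr: float = 1.0 / 150.0     # per-day exponential hazard, nonresponders
    hazard_ratio: float = 3.0          # hazard_nr / hazard_r
    censor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r_fraction < 1:
            raise ValueError("r_fraction must be in (0, 1)")
        if self.delta_on < 0 or self.dispersion <= 0:
            raise ValueError("delta_on must be >= 0 and dispersion > 0")
        if self.pathway_size_max > self.n_genes:
            raise ValueError("pathway size range exceeds gene universe")
        if not 0 <= self.pathway_overlap < 1:
            raise ValueError("pathway_overlap must be in [0, 1)")
        if self.timepoints not in ("PRE", "ON", "both"):
            raise ValueError("timepoints must be PRE, ON or both")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")


@dataclass
class SimulationTruth:
    """Generative ground truth retained for parameter-recovery tests."""

    driver_pathways: list[str]
    log2fc_pre: pd.Series          # per-gene true log2FC (R vs NR), PRE
    log2fc_on: pd.Series
    response: pd.Series            # per patient, R/NR
    hazard_r: float
    hazard_nr: float

    def to_dict(self) -> dict:
        return {
            "driver_pathways": list(self.driver_pathways),
            "log2fc_pre": {g: float(v) for g, v in self.log2fc_pre.items() if v != 0},
            "log2fc_on": {g: float(v) for g, v in self.log2fc_on.items() if v != 0},
            "response": self.response.to_dict(),
            "hazard_r": self.hazard_r,
            "hazard_nr": self.hazard_nr,
        }


def _spawn(seed: int, key: int) -> np.random.Generator:
    """Deterministic per-stage generator: stage `key` under master `seed`."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, key])))


def simulate_genesets(config: SimulationConfig) -> tuple[GeneSetCollection, GeneLengthTable]:
    """Draw a gene-set collection and gene lengths over the simulated universe.

    Sets are sampled without replacement from the gene universe; a configurable
    fraction of each set comes from a shared "overlap pool", the rest from
    genes reserved for that set where capacity allows (so overlap 0 yields
    pairwise-disjoint sets until the universe is exhausted).
    """
    rng = _spawn(config.seed, 1)
    genes = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    sizes = rng.integers(config.pathway_size_min, config.pathway_size_max + 1,
                         size=config.n_pathways)
    n_pool = int(round(config.pathway_overlap * config.pathway_size_max * 2))
    pool = rng.choice(config.n_genes, size=min(n_pool, config.n_genes), replace=False)
    pool_set = set(pool.tolist())
    free = [i for i in range(config.n_genes) if i not in pool_set]
    rng.shuffle(free)
    need_private = int(np.sum(np.ceil(sizes * (1 - config.pathway_overlap))))
    if config.pathway_overlap > 0 and n_pool == 0:
        raise ValueError("overlap requested but pool capacity is zero")
    sets: dict[str, set[str]] = {}
    cursor = 0
    for k, size in enumerate(sizes):
        n_shared = int(round(size * config.pathway_overlap))
        n_shared = min(n_shared, len(pool))
        n_private = int(size) - n_shared
        if cursor + n_private > len(free):
            # universe exhausted: reuse random genes outside the pool
            private = rng.choice(len(free), size=n_private, replace=False)
            members = [free[i] for i in private]
        else:
            members = free[cursor:cursor + n_private]
            cursor += n_private
        if n_shared:
            members = members + rng.choice(pool, size=n_shared, replace=False).tolist()
        sets[f"PW{k:03d}"] = set(genes[members].tolist())
    lengths = pd.Series(rng.integers(200, 20001, size=config.n_genes),
                        index=genes, name="length_bp")
    return GeneSetCollection(sets), GeneLengthTable(lengths.astype(float))


def simulate_survival(n: int, hazard_r: float, hazard_nr: float,
                      response: np.ndarray, censor_rate: float,
                      seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with independent exponential censoring.

    `response` is a boolean array (True = responder); responders get hazard
    `hazard_r`, nonresponders `hazard_nr`. Censoring hazard is tuned so the
    marginal censoring probability is roughly `censor_rate`.
    """
    if hazard_r <= 0 or hazard_nr <= 0:
        raise ValueError("hazards must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 97])))
    haz = np.where(response, hazard_r, hazard_nr)
    event_times = rng.exponential(1.0 / haz)
    if censor_rate == 0:
        return event_times, np.ones(n, dtype=int)
    # P(censor first) = hc/(hc+h) for exponential censoring at hazard hc
    mean_h = float(np.mean(haz))
    hc = mean_h * censor_rate / (1 - censor_rate)
    censor_times = rng.exponential(1.0 / hc, size=n)
    observed = np.minimum(event_times, censor_times)
    events = (event_times <= censor_times).astype(int)
    return observed, events


def _assign_recist(response: np.ndarray, pfs_days: np.ndarray,
                   rng: np.random.Generator) -> list[str]:
    """RECIST codes consistent with true response under the 180-day SD rule."""
    codes = []
    for is_r, pfs in zip(response, pfs_days):
        if is_r:
            choices = ["CR", "PR"]
            if pfs > PFS_RESPONSE_DAYS:
                choices.append("SD")
            codes.append(choices[rng.integers(len(choices))])
        else:
            choices = ["PD"]
            if pfs <= PFS_RESPONSE_DAYS:
                choices.append("SD")
            codes.append(choices[rng.integers(len(choices))])
    return codes


def simulate_cohort(config: SimulationConfig,
                    genesets: GeneSetCollection | None = None,
                    lengths: GeneLengthTable | None = None,
                    ) -> tuple[ExpressionMatrix, SampleTable, SimulationTruth,
                               GeneSetCollection, GeneLengthTable]:
    """Generate counts, annotations and ground truth for one cohort.

    Counts follow ``NB(mean = s_j * 2^(mu_i + a_p + Delta_i), dispersion phi)``
    where ``s_j`` is a log-normal library-size factor, ``a_p`` a patient-level
    offset shared by paired biopsies, and ``Delta_i`` equals ``delta_pre`` /
    ``delta_on`` for driver-pathway genes in responder samples at the matching
    timepoint and 0 otherwise.
    """
    if genesets is None or lengths is None:
        genesets, lengths = simulate_genesets(config)
    rng = _spawn(config.seed, 2)
    genes = lengths.lengths.index.to_numpy()
    n_genes = len(genes)

    driver_names = genesets.names()[: config.n_driver_pathways]
    driver_genes = sorted(set().union(*(genesets[n] for n in driver_names))) \
        if driver_names else []
    is_driver = np.isin(genes, driver_genes)

    n_r = int(round(config.n_patients * config.r_fraction))
    response = np.zeros(config.n_patients, dtype=bool)
    response[:n_r] = True
    rng.shuffle(response)

    timepoints = ["PRE", "ON"] if config.timepoints == "both" else [config.timepoints]
    mu = rng.normal(config.log_mean_loc, config.log_mean_scale, size=n_genes)
    patient_offsets = rng.normal(0.0, config.patient_effect_sd, size=config.n_patients)

    # correlated within-pathway biological variation: a per-(patient, pathway)
    # log2 offset shared by member genes (and by paired PRE/ON biopsies)
    pw_names = genesets.names()
    membership = np.zeros((n_genes, len(pw_names)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for j, name in enumerate(pw_names):
        for g in genesets[name]:
            if g in gene_pos:
                membership[gene_pos[g], j] = 1.0
    pw_offsets = rng.normal(0.0, config.pathway_patient_sd,
                            size=(config.n_patients, len(pw_names)))

    sample_rows = []
    cols = []
    col_names = []
    for p in range(config.n_patients):
        for tp in timepoints:
            sid = f"P{p:03d}_{tp}"
            delta = config.delta_pre if tp == "PRE" else config.delta_on
            shift = np.where(is_driver & response[p], delta, 0.0)
            log_mean = mu + patient_offsets[p] + membership @ pw_offsets[p] + shift
            libsize = rng.lognormal(0.0, config.libsize_log_sd)
            mean = libsize * np.exp2(log_mean)
            phi = config.dispersion
            # NB via gamma-Poisson: shape 1/phi, scale mean*phi
            lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
            counts = rng.poisson(lam)
            cols.append(counts)
            col_names.append(sid)
            sample_rows.append({"sample_id": sid, "patient_id": f"P{p:03d}",
                                "timepoint": tp, "patient_index": p})

    values = pd.DataFrame(np.column_stack(cols).astype("int64"),
                          index=genes, columns=col_names)
    counts = ExpressionMatrix(values, unit="counts")

    hazard_nr = config.hazard_nr
    hazard_r = hazard_nr / config.hazard_ratio
    pfs_time, pfs_event = simulate_survival(
        config.n_patients, hazard_r, hazard_nr, response,
        config.censor_rate, config.seed)
    os_time, os_event = simulate_survival(
        config.n_patients, hazard_r * 0.7, hazard_nr * 0.7, response,
        config.censor_rate, config.seed + 1)

    recist_rng = _spawn(config.seed, 3)
    recist = _assign_recist(response, pfs_time, recist_rng)

    meta = pd.DataFrame(sample_rows)
    pidx = meta["patient_index"].to_numpy()
    meta["cohort"] = "sim"
    meta["recist"] = [recist[i] for i in pidx]
    meta["pfs_days"] = pfs_time[pidx]
    meta["pfs_event"] = pfs_event[pidx]
    meta["os_days"] = os_time[pidx]
    meta["os_event"] = os_event[pidx]
    meta["response"] = [classify_response(r, p)
                        for r, p in zip(meta["recist"], meta["pfs_days"])]
    meta = meta.drop(columns=["patient_index"])
    samples = SampleTable(meta)

    lfc_pre = pd.Series(np.where(is_driver, config.delta_pre, 0.0), index=genes)
    lfc_on = pd.Series(np.where(is_driver, config.delta_on, 0.0), index=genes)
    truth = SimulationTruth(
        driver_pathways=driver_names,
        log2fc_pre=lfc_pre,
        log2fc_on=lfc_on,
        response=pd.Series(np.where(response, "R", "NR"),
                           index=[f"P{p:03d}" for p in range(config.n_patients)]),
        hazard_r=hazard_r,
        hazard_nr=hazard_nr,
    )
    return counts, samples, truth, genesets, lengths
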