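"""Core data containers, standard-format IO, TPM conversion and response labeling.

The containers are thin, validated wrappers around :class:`pandas.DataFrame`:
an expression matrix (genes x samples, raw counts or TPM), a gene-length
table, a per-sample clinical annotation table, and a named gene-set
collection (GMT). Readers validate invariants and raise rather than repair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PassigError",
    "ParseError",
    "LabelingError",
    "DegenerateSampleError",
    "ExpressionMatrix",
    "GeneLengthTable",
    "SampleTable",
    "GeneSetCollection",
    "classify_response",
    "counts_to_tpm",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_sample_table",
    "write_sample_table",
    "read_lengths",
    "write_lengths",
]

RECIST_CODES = ("CR", "PR", "SD", "PD", "NE")
TIMEPOINTS = ("PRE", "ON")

#: Progression-free survival (days) above which stable disease counts as response.
PFS_RESPONSE_DAYS = 180.0


class PassigError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(PassigError):
    """A file violated its format or an invariant of the target container."""


class LabelingError(PassigError):
    """Response labeling could not be applied (e.g. SD without a PFS time)."""


class DegenerateSampleError(PassigError):
    """A sample column is unusable (e.g. all-zero counts in TPM conversion)."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples expression values.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns. All values
        must be finite and non-negative; the ``counts`` variant must hold
        integers.
    unit
        Either ``"counts"`` (raw counts) or ``"tpm"``.
    """

    values: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "tpm"):
            raise ParseError(f"unknown expression unit {self.unit!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ParseError(f"duplicate gene ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise ParseError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ParseError("expression matrix contains non-numeric values")
        if np.isnan(arr).any():
            raise ParseError("expression matrix contains missing values")
        if not np.isfinite(arr).all():
            raise ParseError("expression matrix contains non-finite values")
        if (arr < 0).any():
            raise ParseError("expression matrix contains negative values")
        if self.unit == "counts" and not np.array_equal(arr, np.round(arr)):
            raise ParseError("counts matrix contains non-integer values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values[list(sample_ids)].copy(), unit=self.unit)


@dataclass
class GeneLengthTable:
    """Effective gene lengths in base pairs, keyed by gene id."""

    lengths: pd.Series

    def __post_init__(self) -> None:
        if self.lengths.index.has_duplicates:
            raise ParseError("duplicate gene ids in length table")
        if (self.lengths <= 0).any() or self.lengths.isna().any():
            raise ParseError("gene lengths must be positive")

    def __getitem__(self, gene: str) -> float:
        return float(self.lengths[gene])

    def for_genes(self, genes: list[str]) -> np.ndarray:
        missing = [g for g in genes if g not in self.lengths.index]
        if missing:
            raise ParseError(f"genes missing from length table: {missing[:5]}")
        return self.lengths.reindex(genes).to_numpy(dtype=float)


SAMPLE_COLUMNS = [
    "sample_id", "patient_id", "cohort", "timepoint", "recist",
    "pfs_days", "pfs_event", "os_days", "os_event", "response",
]


@dataclass
class SampleTable:
    """Per-sample clinical annotations (timepoint, RECIST, response, survival)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["sample_id", "patient_id", "timepoint", "recist"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ParseError(f"sample table missing required columns: {missing}")
        if t["sample_id"].duplicated().any():
            dups = sorted(t.loc[t["sample_id"].duplicated(), "sample_id"].unique())
            raise ParseError(f"duplicate sample ids: {dups[:5]}")
        bad_tp = set(t["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ParseError(f"invalid timepoint values: {sorted(bad_tp)}")
        bad_rc = set(t["recist"]) - set(RECIST_CODES)
        if bad_rc:
            raise ParseError(f"invalid RECIST values: {sorted(bad_rc)}")
        for col in ("cohort",):
            if col not in t.columns:
                t[col] = "cohort1"
        for col in ("pfs_days", "pfs_event", "os_days", "os_event"):
            if col not in t.columns:
                t[col] = np.nan
        for col in ("pfs_event", "os_event"):
            vals = t[col].dropna().unique()
            if not set(vals) <= {0, 1, 0.0, 1.0}:
                raise ParseError(f"{col} must be 0/1, got {sorted(vals)[:5]}")
        if "response" not in t.columns or t["response"].isna().all():
            t["response"] = [
                classify_response(r, p)
                for r, p in zip(t["recist"], t["pfs_days"])
            ]
        bad_resp = set(t["response"].dropna()) - {"R", "NR", "NE"}
        if bad_resp:
            raise ParseError(f"invalid response labels: {sorted(bad_resp)}")
        ne_mismatch = t[(t["recist"] == "NE") & (t["response"] != "NE")]
        if len(ne_mismatch):
            raise ParseError("response must be NE whenever recist is NE")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def subset(self, mask_or_ids) -> "SampleTable":
        t = self.table
        if isinstance(mask_or_ids, (list, tuple, set, pd.Index)):
            sub = t[t["sample_id"].isin(list(mask_or_ids))]
        else:
            sub = t[np.asarray(mask_or_ids)]
        return SampleTable(sub.copy())

    def at_timepoint(self, timepoint: str) -> "SampleTable":
        if timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        return self.subset((self.table["timepoint"] == timepoint).to_numpy())

    def labels(self, samples: list[str] | None = None) -> pd.Series:
        """Response labels (R/NR/NE) indexed by sample id."""
        s = self.table.set_index("sample_id")["response"]
        return s if samples is None else s.reindex(samples)


@dataclass
class GeneSetCollection:
    """Ordered mapping of pathway name -> set of gene ids, with descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ParseError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def items(self):
        return self.sets.items()

    def subset(self, names: list[str]) -> "GeneSetCollection":
        missing = [n for n in names if n not in self.sets]
        if missing:
            raise KeyError(f"pathways not in collection: {missing[:5]}")
        return GeneSetCollection(
            {n: set(self.sets[n]) for n in names},
            {n: self.descriptions.get(n, "") for n in names},
        )


# ---------------------------------------------------------------------------
# Response labeling
# ---------------------------------------------------------------------------

def classify_response(recist: str, pfs_days: float | None = None) -> str:
    """Label a patient R/NR/NE from RECIST and progression-free survival.

    CR and PR are responders; PD is a nonresponder; SD is a responder only
    when PFS exceeds 180 days (strictly), otherwise a nonresponder; NE stays
    NE. SD without a PFS time cannot be labeled.
    """
    if recist not in RECIST_CODES:
        raise ParseError(f"unknown RECIST code {recist!r}")
    if recist in ("CR", "PR"):
        return "R"
    if recist == "PD":
        return "NR"
    if recist == "NE":
        return "NE"
    # SD: requires PFS
    if pfs_days is None or (isinstance(pfs_days, float) and math.isnan(pfs_days)):
        raise LabelingError("SD requires pfs_days to assign a response label")
    return "R" if float(pfs_days) > PFS_RESPONSE_DAYS else "NR"


# ---------------------------------------------------------------------------
# TPM conversion
# ---------------------------------------------------------------------------

def counts_to_tpm(counts: ExpressionMatrix, lengths: GeneLengthTable) -> ExpressionMatrix:
    """Convert raw counts to transcripts-per-million using gene lengths.

    Per sample j: ``tpm_ij = (c_ij / L_i) / sum_k (c_kj / L_k) * 1e6`` with
    lengths in base pairs. Every column of the result sums to 1e6.
    """
    if counts.unit != "counts":
        raise ValueError("counts_to_tpm expects a counts matrix")
    L = lengths.for_genes(counts.gene_ids)
    arr = counts.values.to_numpy(dtype=float)
    col_sums = arr.sum(axis=0)
    if (col_sums == 0).any():
        bad = [s for s, c in zip(counts.sample_ids, col_sums) if c == 0]
        raise DegenerateSampleError(f"all-zero count columns: {bad[:5]}")
    rate = arr / L[:, None]
    tpm = rate / rate.sum(axis=0, keepdims=True) * 1e6
    out = pd.DataFrame(tpm, index=counts.values.index, columns=counts.values.columns)
    return ExpressionMatrix(out, unit="tpm")


# ---------------------------------------------------------------------------
# Readers / writers (TSV, GMT)
# ---------------------------------------------------------------------------

def read_counts(path, unit: str = "counts") -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column gene ids, header sample ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse expression TSV {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float if unit == "tpm" else "int64")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"non-numeric cell in {path}: {exc}") from exc
    return ExpressionMatrix(df, unit=unit)


def write_counts(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (name TAB description TAB gene TAB gene ...)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene set {name!r}")
            sets[name] = set(genes)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + sorted(genes)) + "\n")


def read_sample_table(path) -> SampleTable:
    """Read a sample annotation TSV; derives response labels when absent."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"cannot parse sample TSV {path}: {exc}") from exc
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path) -> None:
    cols = [c for c in SAMPLE_COLUMNS if c in samples.table.columns]
    samples.table[cols].to_csv(path, sep="\t", index=False)


def read_lengths(path) -> GeneLengthTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df.iloc[:, 0]
    s.index = s.index.astype(str)
    return GeneLengthTable(s.astype(float))


def write_lengths(lengths: GeneLengthTable, path) -> None:
    lengths.lengths.rename("length_bp").to_csv(path, sep="\t", index_label="gene_id")
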