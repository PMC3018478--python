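"""Domain containers and TSV/GEO readers and writers.

Matrices are thin wrappers around a pandas DataFrame (rows = probes,
columns = samples). Missing beta values are NaN in the frame and tracked
explicitly; they are never encoded as a sentinel number.
"""

from __future__ import annotations

import dataclasses
import io
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Type, TypeVar

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_NA_STRINGS = ["", "NA", "NaN", "nan", "null"]


# ---------------------------------------------------------------------------
# matrices


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what}: {dups}")


@dataclass
class BetaMatrix:
    """CpG probes x samples methylation fractions, beta in [0, 1]."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe id")
        _check_unique(self.values.columns, "sample id")
        arr = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValueError(
                "beta out of range [0, 1] at probe "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


@dataclass
class ExpressionMatrix:
    """Expression probes x samples, log2-scale intensities."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe id")
        _check_unique(self.values.columns, "sample id")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                "non-finite expression value at probe "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ProbeAnnotation:
    """Probe-to-gene maps for both platforms.

    ``meth`` is indexed by methylation probe id with columns entrez_id,
    symbol, cgi_flag, prc2_flag; ``expr`` by expression probe id with
    entrez_id and symbol. Probes without a gene mapping carry an empty
    entrez_id and are excluded from gene-level pairing.
    """

    meth: pd.DataFrame
    expr: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.meth.index, "methylation probe id")
        _check_unique(self.expr.index, "expression probe id")
        for col in ("cgi_flag", "prc2_flag"):
            if not self.meth[col].isin([True, False]).all():
                raise ValueError(f"{col} must be boolean")

    def meth_genes(self) -> pd.Series:
        """entrez_id per mapped methylation probe (unmapped dropped)."""
        g = self.meth["entrez_id"]
        return g[g != ""]

    def expr_genes(self) -> pd.Series:
        g = self.expr["entrez_id"]
        return g[g != ""]


@dataclass
class ClinicalTable:
    """Per-sample clinical record, indexed by sample id.

    Columns: group ({tumor, control}), age, sex, kps, os_months, event,
    treatment, and (optionally) mgmt_methylated. os_months/event may be NaN
    for samples outside the survival cohort.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample id")
        if not self.data["group"].isin(["tumor", "control"]).all():
            bad = sorted(set(self.data["group"]) - {"tumor", "control"})
            raise ValueError(f"unknown group labels: {bad}")
        ev = self.data["event"].dropna()
        if not ev.isin([0, 1]).all():
            raise ValueError("event values must be 0 (censored) or 1 (death)")
        os_m = self.data["os_months"].dropna()
        if (os_m < 0).any():
            raise ValueError("os_months must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def has_mgmt(self) -> bool:
        return "mgmt_methylated" in self.data.columns

    def tumor_samples(self) -> list[str]:
        return list(self.data.index[self.data["group"] == "tumor"])

    def control_samples(self) -> list[str]:
        return list(self.data.index[self.data["group"] == "control"])

    def survival_samples(self) -> list[str]:
        ok = self.data["os_months"].notna() & self.data["event"].notna()
        return list(self.data.index[ok])


# ---------------------------------------------------------------------------
# result records


@dataclass
class DMRecord:
    """One differentially methylated CpG site (tumor vs control)."""

    probe_id: str
    entrez_id: str
    mean_beta_tumor: float
    mean_beta_control: float
    delta_beta: float
    t_stat: float
    df: float
    p_value: float
    p_adjusted: float
    direction: str  # hyper | hypo


@dataclass
class DERecord:
    """One differentially expressed gene (rank-product call)."""

    entrez_id: str
    probe_id: str
    fold_change: float
    rp_up: float
    rp_down: float
    pfp_up: float
    pfp_down: float
    direction: str  # up | down


@dataclass
class CorrPair:
    """Pearson correlation of one methylation/expression probe pair."""

    meth_probe: str
    expr_probe: str
    entrez_id: str
    r: float
    p_value: float
    n: int
    inverse_flag: bool


@dataclass
class SurvivalMarker:
    """One CpG site surviving the full prognostic-marker screen."""

    probe_id: str
    symbol: str
    hr: float
    ci_low: float
    ci_high: float
    z: float
    p_cox: float
    cutoff: float
    p_logrank: float
    n_low: int
    n_high: int
    auc: float
    surv18_low: float
    surv18_high: float
    hr_multivariate: float
    p_multivariate: float
    mgmt_independent: bool


# ---------------------------------------------------------------------------
# matrix IO


def _read_table_body(path: str | Path, dialect: str) -> pd.DataFrame:
    path = Path(path)
    if dialect == "tsv":
        buf: io.StringIO | Path = path
    elif dialect == "geo_series_matrix":
        lines: list[str] = []
        inside = False
        with open(path) as fh:
            for line in fh:
                if line.startswith("!series_matrix_table_begin"):
                    inside = True
                    continue
                if line.startswith("!series_matrix_table_end"):
                    inside = False
                    continue
                if inside:
                    lines.append(line.replace('"', ""))
        if not lines:
            raise ValueError(f"no series-matrix table body found in {path}")
        buf = io.StringIO("".join(lines))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(buf, sep="\t", dtype=str, keep_default_na=False,
                      index_col=0)
    raw.index = raw.index.astype(str)
    return raw


def _to_numeric(raw: pd.DataFrame, what: str) -> pd.DataFrame:
    out = raw.mask(raw.isin(_NA_STRINGS))
    num = out.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & out.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric {what} value {raw.iat[i, j]!r} at row "
            f"{raw.index[i]!r}, column {raw.columns[j]!r}"
        )
    return num.astype(float)


def read_beta_matrix(path: str | Path, dialect: str = "tsv") -> BetaMatrix:
    """Read a beta-value matrix from plain TSV or a GEO series-matrix file.

    Header row holds sample ids, first column probe ids. Empty cells and
    "NA" are recorded as missing, never as zero.
    """
    raw = _read_table_body(path, dialect)
    return BetaMatrix(_to_numeric(raw, "beta"))


def read_expression_matrix(path: str | Path,
                           dialect: str = "tsv") -> ExpressionMatrix:
    """Read a log2 expression matrix (same table layout as beta matrices)."""
    raw = _read_table_body(path, dialect)
    return ExpressionMatrix(_to_numeric(raw, "expression"))


def write_matrix(matrix: BetaMatrix | ExpressionMatrix,
                 path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id",
                         float_format="%.6g", na_rep="NA")


def read_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a probe annotation TSV.

    Columns: probe_id, platform ({meth, expr}), entrez_id, symbol,
    cgi_flag (0/1, meth only), prc2_flag (0/1, meth only).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"probe_id", "platform", "entrez_id", "symbol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file misses columns {sorted(missing)}")
    meth = df[df["platform"] == "meth"].set_index("probe_id")
    expr = df[df["platform"] == "expr"].set_index("probe_id")
    meth = meth.assign(
        cgi_flag=meth.get("cgi_flag", "0").replace("", "0").astype(int).astype(bool),
        prc2_flag=meth.get("prc2_flag", "0").replace("", "0").astype(int).astype(bool),
    )[["entrez_id", "symbol", "cgi_flag", "prc2_flag"]]
    expr = expr[["entrez_id", "symbol"]]
    return ProbeAnnotation(meth=meth, expr=expr)


def write_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    meth = ann.meth.reset_index(names="probe_id").assign(platform="meth")
    meth["cgi_flag"] = meth["cgi_flag"].astype(int)
    meth["prc2_flag"] = meth["prc2_flag"].astype(int)
    expr = ann.expr.reset_index(names="probe_id").assign(
        platform="expr", cgi_flag="", prc2_flag="")
    cols = ["probe_id", "platform", "entrez_id", "symbol", "cgi_flag",
            "prc2_flag"]
    pd.concat([meth[cols], expr[cols]]).to_csv(path, sep="\t", index=False)


_CLINICAL_COLS = ["group", "age", "sex", "kps", "os_months", "event",
                  "treatment"]


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read the per-sample clinical TSV.

    Columns: sample_id, group, age, sex, kps, os_months, event, treatment,
    mgmt_methylated (0/1, optional). Absent optional columns stay absent.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValueError("clinical table misses sample_id column")
    df = df.set_index("sample_id")
    missing = set(_CLINICAL_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"clinical table misses columns {sorted(missing)}")
    out = pd.DataFrame(index=df.index)
    out["group"] = df["group"]
    for col in ("age", "kps", "os_months", "event"):
        out[col] = pd.to_numeric(df[col].mask(df[col].isin(_NA_STRINGS)))
    out["sex"] = df["sex"]
    out["treatment"] = df["treatment"]
    if "mgmt_methylated" in df.columns:
        mm = df["mgmt_methylated"]
        out["mgmt_methylated"] = pd.to_numeric(mm.mask(mm.isin(_NA_STRINGS)))
    return ClinicalTable(out)


def write_clinical_table(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.data.to_csv(path, sep="\t", index_label="sample_id",
                         float_format="%.6g", na_rep="NA")


# ---------------------------------------------------------------------------
# record-list IO

R = TypeVar("R")


def write_results_table(records: Sequence, path: str | Path,
                        record_type: Optional[Type] = None) -> None:
    """Write a homogeneous list of result records as TSV.

    Column order follows field declaration order; floats use 6 significant
    digits (p-values below 1e-300 are floored there upstream). An empty list
    needs ``record_type`` to emit a header-only file.
    """
    if not records and record_type is None:
        raise ValueError("empty record list requires record_type for header")
    cls = record_type if record_type is not None else type(records[0])
    names = [f.name for f in dataclasses.fields(cls)]
    if any(type(r) is not cls for r in records):
        raise ValueError("records must be a homogeneous list")
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        for rec in records:
            cells = []
            for name in names:
                v = getattr(rec, name)
                if isinstance(v, bool):
                    cells.append(str(int(v)))
                elif isinstance(v, float):
                    cells.append("NA" if math.isnan(v) else f"{v:.6g}")
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def read_results_table(path: str | Path, record_type: Type[R]) -> list[R]:
    """Re-read a table written by :func:`write_results_table`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: list[R] = []
    for _, row in df.iterrows():
        kwargs = {}
        for f in dataclasses.fields(record_type):
            raw = row[f.name]
            if f.type in ("float", float):
                kwargs[f.name] = float("nan") if raw == "NA" else float(raw)
            elif f.type in ("int", int):
                kwargs[f.name] = int(raw)
            elif f.type in ("bool", bool):
                kwargs[f.name] = bool(int(raw))
            else:
                kwargs[f.name] = raw
        out.append(record_type(**kwargs))
    return out


def align_samples(beta: BetaMatrix, *others: pd.Index | Iterable[str]
                  ) -> list[str]:
    """Shared sample ids, ordered as in the methylation matrix.

    Samples absent from any input are dropped; the drop count is logged
    because every stage of the study runs on a different cohort subset.
    """
    shared = list(beta.sample_ids)
    for other in others:
        keep = set(other)
        shared = [s for s in shared if s in keep]
    dropped = len(beta.sample_ids) - len(shared)
    if dropped:
        logger.info("align_samples: dropped %d of %d samples not shared "
                    "by all inputs", dropped, len(beta.sample_ids))
    return shared
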