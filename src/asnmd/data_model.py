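"""Domain types, table readers/writers and run configuration.

All tabular inputs are UTF-8 TSV with a mandatory header row; missing
values are the literal ``NA``.  Genomic coordinates follow the BED
convention (0-based, half-open).  Junction tables come in two dialects:

* *split* — columns ``incl_up``, ``incl_down``, ``excl`` (the two
  inclusion junctions counted separately), or
* *combined* — columns ``inclusive``, ``excl`` where ``inclusive`` is the
  total inclusion-junction read count I.  Combined tables are loaded with
  ``incl_up = inclusive``, ``incl_down = 0`` and ``combined = True``.

Readers validate invariants row by row and raise :class:`TableError`
naming the offending row and field.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExonEvent",
    "SampleMeta",
    "RunConfig",
    "TableError",
    "read_events",
    "read_samples",
    "read_junctions",
    "read_expression",
    "read_tables",
    "validate_panel",
    "write_report",
    "write_tsv",
]

#: significant digits preserved by :func:`write_report` / :func:`write_tsv`
FLOAT_FMT = "%.12g"

NA = "NA"


class TableError(ValueError):
    """Raised for malformed or invariant-violating table content."""


@dataclass(frozen=True)
class ExonEvent:
    """A cassette-exon event with its NMD/frame consequences.

    ``nmd_on_inclusion`` marks events whose inclusion introduces a
    premature termination codon (the exon-8-like event);
    ``frameshift_on_skipping`` marks events whose skipping changes the
    C-terminal reading frame (the exon-10-like event).  The flags are
    independent.
    """

    event_id: str
    gene_id: str
    chrom: str
    exon_start: int
    exon_end: int
    strand: str
    upstream_exon: str = ""
    downstream_exon: str = ""
    nmd_on_inclusion: bool = False
    frameshift_on_skipping: bool = False

    def __post_init__(self) -> None:
        if not self.exon_start < self.exon_end:
            raise TableError(
                f"event {self.event_id}: exon_start ({self.exon_start}) must be "
                f"< exon_end ({self.exon_end})"
            )
        if self.strand not in {"+", "-"}:
            raise TableError(f"event {self.event_id}: strand must be + or -")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata (tissue, group, condition, stage, replicate)."""

    sample_id: str
    tissue: str
    tissue_group: str
    condition: str = "WT"
    stage: str = "adult"
    replicate: int = 1

    VALID_GROUPS = frozenset({"neural", "non_neural"})
    VALID_CONDITIONS = frozenset(
        {"WT", "NMD_KO", "splicing_factor_KO", "E8_KO", "E10_KO", "treatment"}
    )

    def __post_init__(self) -> None:
        if self.tissue_group not in self.VALID_GROUPS:
            raise TableError(
                f"sample {self.sample_id}: tissue_group {self.tissue_group!r} "
                f"not in {sorted(self.VALID_GROUPS)}"
            )
        if self.condition not in self.VALID_CONDITIONS:
            raise TableError(
                f"sample {self.sample_id}: condition {self.condition!r} "
                f"not in {sorted(self.VALID_CONDITIONS)}"
            )
        if self.replicate < 1:
            raise TableError(f"sample {self.sample_id}: replicate must be >= 1")


@dataclass
class RunConfig:
    """Configuration shared by all pipeline stages.

    ``brain_tissues`` has no default: which tissues collapse into a single
    brain entry is an analysis decision the caller must make.
    """

    brain_tissues: frozenset[str] = frozenset()
    min_informative_reads: float = 10.0
    lambda_method: str = "geometric"
    log_pseudocount: float = 1.0
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        self.brain_tissues = frozenset(self.brain_tissues)
        if self.min_informative_reads < 1:
            raise ValueError("min_informative_reads must be >= 1")
        if self.log_pseudocount <= 0:
            raise ValueError("log_pseudocount must be > 0")
        if self.lambda_method not in {"geometric", "arithmetic"}:
            raise ValueError("lambda_method must be 'geometric' or 'arithmetic'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["brain_tissues"] = sorted(self.brain_tissues)
        return d


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableError(f"missing file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA], keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing required column(s) {missing}")
    return df


def _numeric(df: pd.DataFrame, col: str, path, *, allow_na: bool = False) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based, plus header
        raise TableError(f"{path}: row {row}: malformed numeric field {col!r}")
    if not allow_na and out.isna().any():
        row = int(out.isna().idxmax()) + 2
        raise TableError(f"{path}: row {row}: missing value in field {col!r}")
    return out


def _nonneg(values: pd.Series, col: str, path) -> pd.Series:
    neg = values < 0
    if neg.any():
        row = int(neg.idxmax()) + 2
        raise TableError(f"{path}: row {row}: negative value in field {col!r}")
    return values


def read_events(path: str | Path) -> dict[str, ExonEvent]:
    """Read a BED-like event definition table into ``{event_id: ExonEvent}``."""
    df = _read_tsv(path, ["chrom", "start", "end", "event_id", "gene_id", "strand"])
    events: dict[str, ExonEvent] = {}
    for i, row in df.iterrows():
        if row["event_id"] in events:
            raise TableError(f"{path}: row {i + 2}: duplicate event_id {row['event_id']!r}")
        events[row["event_id"]] = ExonEvent(
            event_id=row["event_id"],
            gene_id=row["gene_id"],
            chrom=row["chrom"],
            exon_start=int(row["start"]),
            exon_end=int(row["end"]),
            strand=row["strand"],
            upstream_exon=row.get("upstream_exon", ""),
            downstream_exon=row.get("downstream_exon", ""),
            nmd_on_inclusion=_parse_bool(row.get("nmd_on_inclusion", "false")),
            frameshift_on_skipping=_parse_bool(row.get("frameshift_on_skipping", "false")),
        )
    return events


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    return str(v).strip().lower() in {"1", "true", "yes"}


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read sample metadata; enforces unique sample ids and one group per tissue."""
    df = _read_tsv(path, ["sample_id", "tissue", "tissue_group"])
    dup = df["sample_id"].duplicated()
    if dup.any():
        row = int(dup.idxmax()) + 2
        raise TableError(f"{path}: row {row}: duplicate sample_id {df['sample_id'][dup.idxmax()]!r}")
    groups = df.groupby("tissue")["tissue_group"].nunique()
    ambiguous = groups[groups > 1]
    if not ambiguous.empty:
        raise TableError(f"{path}: tissue(s) {list(ambiguous.index)} map to multiple groups")
    for col, default in (("condition", "WT"), ("stage", "adult"), ("replicate", "1")):
        if col not in df.columns:
            df[col] = default
    df["replicate"] = _numeric(df, "replicate", path).astype(int)
    for _, row in df.iterrows():
        SampleMeta(
            sample_id=row["sample_id"],
            tissue=row["tissue"],
            tissue_group=row["tissue_group"],
            condition=row["condition"],
            stage=row["stage"],
            replicate=int(row["replicate"]),
        )
    return df.reset_index(drop=True)


def read_junctions(path: str | Path) -> pd.DataFrame:
    """Read a junction-count table in either the split or combined dialect.

    Returns columns ``sample_id, event_id, incl_up, incl_down, excl,
    combined``; the total inclusion count is ``incl_up + incl_down``.
    """
    df = _read_tsv(path, ["sample_id", "event_id"])
    if "inclusive" in df.columns:
        incl = _nonneg(_numeric(df, "inclusive", path), "inclusive", path)
        out = pd.DataFrame(
            {
                "sample_id": df["sample_id"],
                "event_id": df["event_id"],
                "incl_up": incl,
                "incl_down": 0.0,
                "combined": True,
            }
        )
    elif {"incl_up", "incl_down"}.issubset(df.columns):
        out = pd.DataFrame(
            {
                "sample_id": df["sample_id"],
                "event_id": df["event_id"],
                "incl_up": _nonneg(_numeric(df, "incl_up", path), "incl_up", path),
                "incl_down": _nonneg(_numeric(df, "incl_down", path), "incl_down", path),
                "combined": False,
            }
        )
    else:
        raise TableError(
            f"{path}: junction table needs either 'inclusive' or 'incl_up'+'incl_down'"
        )
    if "excl" not in df.columns:
        raise TableError(f"{path}: missing required column(s) ['excl']")
    out["excl"] = _nonneg(_numeric(df, "excl", path), "excl", path)
    return out[["sample_id", "event_id", "incl_up", "incl_down", "excl", "combined"]]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read gene-level TPM expression records."""
    df = _read_tsv(path, ["sample_id", "gene_id", "tpm"])
    out = df[["sample_id", "gene_id"]].copy()
    out["tpm"] = _nonneg(_numeric(df, "tpm", path), "tpm", path)
    return out


_READERS = {
    "events": read_events,
    "samples": read_samples,
    "junctions": read_junctions,
    "expression": read_expression,
}


def read_tables(paths: Mapping[str, str | Path]) -> dict:
    """Read several tables at once; keys select the schema (``events``,
    ``samples``, ``junctions``, ``expression``)."""
    unknown = set(paths) - set(_READERS)
    if unknown:
        raise TableError(f"unknown table kind(s): {sorted(unknown)}")
    return {kind: _READERS[kind](p) for kind, p in paths.items()}


def validate_panel(
    samples: pd.DataFrame,
    junctions: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
) -> None:
    """Referential integrity: every sample referenced by a data table must
    exist in the sample metadata."""
    known = set(samples["sample_id"])
    for name, tbl in (("junctions", junctions), ("expression", expression)):
        if tbl is None:
            continue
        orphans = sorted(set(tbl["sample_id"]) - known)
        if orphans:
            raise TableError(f"{name} table references unknown sample_id(s): {orphans}")


# ---------------------------------------------------------------------------
# writers


def _format_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(
                lambda v: NA if (isinstance(v, float) and math.isnan(v)) else FLOAT_FMT % v
            )
    return out


def write_report(results: pd.DataFrame, path: str | Path) -> Path:
    """Serialize a result table to CSV (or JSON for ``.json`` paths).

    Floating-point fields are written with 12 significant digits so that a
    read-back reproduces the values; writing is deterministic, so
    write→read→write is byte-identical.  Empty results are an error.
    """
    path = Path(path)
    if results is None or len(results) == 0:
        raise ValueError(f"refusing to write empty result set to {path}")
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".json":
        payload = json.loads(_format_frame(results).to_json(orient="records"))
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8")
    else:
        _format_frame(results).to_csv(path, index=False, na_rep=NA)
    return path


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a TSV in the same dialect the readers consume."""
    path = Path(path)
    if df is None or len(df) == 0:
        raise ValueError(f"refusing to write empty table to {path}")
    path.parent.mkdir(parents=True, exist_ok=True)
    _format_frame(df).to_csv(path, sep="\t", index=False, na_rep=NA)
    return path
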