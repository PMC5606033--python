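"""TSV readers for omics tables, driven by a column→role schema.

A ``TableSchema`` names the record kind and maps header columns to semantic
roles; rows that fail type coercion or a record invariant are reported with
their row number, never silently dropped.  Strictness (fail vs skip-and-
report) is the caller's choice, defaulting to skip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
import yaml

from .records import (
    AnnotationRecord,
    CNVRecord,
    ExpressionRecord,
    Locus,
    MethylationRecord,
    MutationRecord,
    RecordError,
)

__all__ = [
    "TableSchema",
    "RowIssue",
    "TableReadResult",
    "SchemaError",
    "read_table",
    "REQUIRED_ROLES",
]


class SchemaError(ValueError):
    """The schema and the table header disagree."""


#: Roles that must be mapped (and non-empty) for each record kind.
REQUIRED_ROLES = {
    "mutation": {"sample_id", "gene_symbol", "chrom", "start", "end",
                 "mutation_type"},
    "cnv": {"sample_id", "chrom", "start", "end", "cnv_type"},
    "expression": {"gene_symbol", "sample_id", "value"},
    "methylation": {"gene_symbol", "composite_element_ref", "chrom", "start",
                    "end", "beta_value"},
    "annotation": set(),
}

_OPTIONAL_ROLES = {
    "mutation": {"ensembl_id", "pmid"},
    "cnv": set(),
    "expression": {"regulation"},
    "methylation": {"tumour_purity", "sample_id"},
    "annotation": {"gene_symbol", "ensembl_id", "go_id", "go_process",
                   "kegg_id", "reactome_id"},
}


@dataclass(frozen=True)
class TableSchema:
    """Declares how to interpret one TSV dialect.

    ``beta_is_delta`` records whether beta values are raw levels or changes;
    it is carried through for provenance and does not alter parsing (both
    dialects live in [-1, 1]).
    """

    kind: str
    columns: dict = field(default_factory=dict)  # column name -> role
    beta_is_delta: bool = False

    def __post_init__(self) -> None:
        if self.kind not in REQUIRED_ROLES:
            raise SchemaError(f"unknown record kind {self.kind!r}")
        allowed = REQUIRED_ROLES[self.kind] | _OPTIONAL_ROLES[self.kind]
        for col, role in self.columns.items():
            if role not in allowed:
                raise SchemaError(
                    f"role {role!r} (column {col!r}) is not valid for "
                    f"kind {self.kind!r}"
                )
        missing = REQUIRED_ROLES[self.kind] - set(self.columns.values())
        if missing:
            raise SchemaError(
                f"schema for kind {self.kind!r} lacks required roles: "
                f"{sorted(missing)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "TableSchema":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(
            kind=cfg["kind"],
            columns=dict(cfg["columns"]),
            beta_is_delta=bool(cfg.get("beta_is_delta", False)),
        )


@dataclass(frozen=True)
class RowIssue:
    row_number: int  # 1-based data-row number (header excluded)
    reason: str


@dataclass
class TableReadResult:
    records: list
    rejects: list

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _coerce_int(raw: str, role: str) -> int:
    try:
        return int(raw)
    except ValueError:
        raise RecordError(f"unparseable {role} coordinate {raw!r}") from None


def _coerce_float(raw: str, role: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise RecordError(f"unparseable {role} value {raw!r}") from None


def _build_record(kind: str, roles: dict):
    if kind in ("mutation", "cnv", "methylation"):
        locus = Locus(
            chrom=roles.pop("chrom"),
            start=_coerce_int(roles.pop("start"), "start"),
            end=_coerce_int(roles.pop("end"), "end"),
        )
        roles["locus"] = locus
    if kind == "mutation":
        return MutationRecord(**roles)
    if kind == "cnv":
        return CNVRecord(**roles)
    if kind == "expression":
        roles["value"] = _coerce_float(roles["value"], "value")
        return ExpressionRecord(**roles)
    if kind == "methylation":
        roles["beta_value"] = _coerce_float(roles["beta_value"], "beta_value")
        if "tumour_purity" in roles:
            roles["tumour_purity"] = _coerce_float(
                roles["tumour_purity"], "tumour_purity"
            )
        return MethylationRecord(**roles)
    return AnnotationRecord(**roles)


def read_table(path, schema: TableSchema, strict: bool = False) -> TableReadResult:
    """Read a TSV table into typed records.

    Returns a :class:`TableReadResult` whose ``rejects`` lists every row that
    failed coercion or an invariant, with its 1-based row number and reason.
    With ``strict=True`` the first bad row raises instead.
    """
    df = pd.read_csv(
        str(path), sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
    )
    missing_cols = set(schema.columns) - set(df.columns)
    if missing_cols:
        raise SchemaError(
            f"required columns missing from {path}: {sorted(missing_cols)}"
        )
    records, rejects = [], []
    required = REQUIRED_ROLES[schema.kind]
    for i, row in enumerate(df.itertuples(index=False), start=1):
        values = dict(zip(df.columns, row))
        roles = {
            role: values[col].strip()
            for col, role in schema.columns.items()
            if values[col].strip() != ""
        }
        try:
            lacking = required - set(roles)
            if lacking:
                raise RecordError(f"empty required fields: {sorted(lacking)}")
            records.append(_build_record(schema.kind, roles))
        except RecordError as exc:
            if strict:
                raise RecordError(f"row {i}: {exc}") from exc
            rejects.append(RowIssue(row_number=i, reason=str(exc)))
    return TableReadResult(records=records, rejects=rejects)
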