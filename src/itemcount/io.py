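"""Respondent-table reading, writing and validation.

The canonical on-disk format is a wide, comma-separated, UTF-8 table with a
header row and one row per respondent:

``respondent_id, arm, stratum, truth_hiv_negative, truth_refused,
truth_<item>..., count_block{b}, pos_block{b}, ctrl_b{b}_i{k}, direct_b{b}``

Arm A (list format) rows carry a block count (0..J+1) and the randomized
position of the sensitive item (1..J+1) for every block, and leave the
item-level columns empty.  Arm B (direct questioning) rows carry the J
control answers and the direct sensitive answer per block, and leave the
count/position columns empty.  Booleans are serialized as 0/1 and missing
values as empty strings, so the format is unambiguous under delimited-text
dialects.  Any additional columns (demographic covariates, say) are carried
through untouched.

External files whose headers differ from the canonical schema — e.g. a
study's deposited survey export — are ingested through a
:class:`ColumnMapping`, which renames columns and recodes values explicitly.
Nothing is ever guessed from unknown headers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .design import SurveyDesign, truth_column

__all__ = [
    "ColumnMapping",
    "SchemaError",
    "ValidationError",
    "canonical_columns",
    "read_respondents",
    "write_respondents",
    "validate_respondents",
    "arm_a_columns",
    "arm_b_columns",
]

ARMS = ("A", "B")


class SchemaError(ValueError):
    """A required column is absent or a mapping is incomplete."""


class ValidationError(ValueError):
    """One or more rows violate the respondent-record invariants."""

    def __init__(self, messages: list[str]):
        self.messages = list(messages)
        preview = "\n  ".join(self.messages[:20])
        more = "" if len(self.messages) <= 20 else f"\n  ... {len(self.messages) - 20} more"
        super().__init__(f"{len(self.messages)} invalid row(s):\n  {preview}{more}")


def arm_a_columns(design: SurveyDesign) -> list[str]:
    """Count and sensitive-position columns, one pair per block."""
    cols = []
    for b in design.block_ids:
        cols += [f"count_block{b}", f"pos_block{b}"]
    return cols


def arm_b_columns(design: SurveyDesign) -> list[str]:
    """Item-level answer columns: J controls plus the direct sensitive answer."""
    cols = []
    for blk in design.blocks:
        cols += [f"ctrl_b{blk.block_id}_i{k}" for k in range(1, blk.n_controls + 1)]
        cols.append(f"direct_b{blk.block_id}")
    return cols


def truth_columns(design: SurveyDesign) -> list[str]:
    return [truth_column(item) for item in design.sensitive_items]


def canonical_columns(design: SurveyDesign) -> list[str]:
    """Full canonical column order for a design."""
    return (
        ["respondent_id", "arm", "stratum"]
        + truth_columns(design)
        + arm_a_columns(design)
        + arm_b_columns(design)
    )


@dataclass
class ColumnMapping:
    """Schema map from canonical field names to a source file's columns.

    Parameters
    ----------
    columns
        ``canonical_name -> source_column_name``.  Canonical names absent
        from the map are assumed to appear under their own name in the
        source file (identity mapping); a canonical column that exists in
        neither place is reported by :func:`read_respondents` when an
        operation requires it.
    recodes
        ``canonical_name -> {source_value: canonical_value}`` applied after
        renaming.  Source values are compared as strings, so ``{"1": "A"}``
        recodes an arm coded numerically.
    """

    columns: dict[str, str] = field(default_factory=dict)
    recodes: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def identity(cls) -> "ColumnMapping":
        return cls()

    @classmethod
    def from_file(cls, path) -> "ColumnMapping":
        """Load a mapping from YAML or JSON (keys ``columns``, ``recodes``)."""
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
        data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        data = data or {}
        return cls(columns=data.get("columns", {}) or {},
                   recodes=data.get("recodes", {}) or {})

    def apply(self, frame: pd.DataFrame) -> pd.DataFrame:
        """Rename mapped columns and apply value recodes; missing source
        columns raise :class:`SchemaError` naming the column."""
        missing = [src for src in self.columns.values() if src not in frame.columns]
        if missing:
            raise SchemaError(
                f"mapped source column(s) not in file: {sorted(missing)}; "
                f"file has {list(frame.columns)}"
            )
        renamed = frame.rename(columns={v: k for k, v in self.columns.items()})
        for canon, table in self.recodes.items():
            if canon not in renamed.columns:
                raise SchemaError(f"recode given for absent column {canon!r}")
            strtable = {str(k): v for k, v in table.items()}
            col = renamed[canon].astype("string").str.strip()
            renamed[canon] = col.map(lambda v: strtable.get(v, v))
        return renamed


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _is_missing(s: pd.Series) -> pd.Series:
    return s.isna() | (s.astype("string").str.strip().fillna("") == "")


def _to_num(s: pd.Series) -> pd.Series:
    if pd.api.types.is_numeric_dtype(s):
        return pd.to_numeric(s, errors="coerce").astype("float64")
    ss = s.astype("string").replace("", pd.NA)
    return pd.to_numeric(ss, errors="coerce").astype("float64")


def validate_respondents(
    frame: pd.DataFrame,
    design: SurveyDesign,
    *,
    lenient: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Check a canonical-schema table against the record invariants.

    Returns the validated (and dtype-normalised) table plus the list of
    row-indexed error messages.  In strict mode (default) any error raises
    :class:`ValidationError`; in lenient mode offending rows are dropped and
    the messages returned for logging.
    """
    J = design.n_controls
    required = ["respondent_id", "arm", "stratum"]
    absent = [c for c in required if c not in frame.columns]
    if absent:
        raise SchemaError(f"canonical column(s) missing from table: {absent}")

    df = frame.copy()
    errors: list[str] = []
    bad = pd.Series(False, index=df.index)

    def flag(mask: pd.Series, msg: str, col: str) -> None:
        nonlocal bad
        mask = mask.fillna(False).astype(bool)
        for i in df.index[mask]:
            errors.append(f"row {i}: {msg} (field {col!r})")
        bad |= mask

    arm = df["arm"].astype("string").str.strip()
    df["arm"] = arm
    flag(~arm.isin(ARMS), f"arm must be one of {ARMS}", "arm")
    stratum = df["stratum"].astype("string").str.strip()
    df["stratum"] = stratum
    flag(~stratum.isin(design.strata), f"stratum must be one of {design.strata}", "stratum")

    # truth consistency -----------------------------------------------------
    if "truth_refused" in df.columns:
        tr = _to_num(df["truth_refused"])
        df["truth_refused"] = tr
        flag(~_is_missing(df["truth_refused"]) & ~tr.isin([0, 1]),
             "truth_refused must be 0/1", "truth_refused")
        flag((stratum == "refused") & (tr != 1), "stratum 'refused' requires truth_refused = 1",
             "truth_refused")
        flag((stratum != "refused") & stratum.isin(design.strata) & (tr == 1),
             "truth_refused = 1 requires stratum 'refused'", "truth_refused")
    if "truth_hiv_negative" in df.columns:
        th = _to_num(df["truth_hiv_negative"])
        df["truth_hiv_negative"] = th
        present = ~th.isna()
        flag(present & ~th.isin([0, 1]), "truth_hiv_negative must be 0/1 or empty",
             "truth_hiv_negative")
        flag((stratum == "negative") & present & (th != 1),
             "stratum 'negative' requires truth_hiv_negative = 1", "truth_hiv_negative")
        flag((stratum == "negative") & ~present,
             "truth_hiv_negative missing outside the 'refused' stratum", "truth_hiv_negative")
        flag(stratum.isin(["pos_linked", "pos_unlinked"]) & present & (th != 0),
             "HIV-positive strata require truth_hiv_negative = 0", "truth_hiv_negative")
        flag(stratum.isin(["pos_linked", "pos_unlinked"]) & ~present,
             "truth_hiv_negative missing outside the 'refused' stratum", "truth_hiv_negative")
    for c in truth_columns(design):
        if c in df.columns and c not in ("truth_refused", "truth_hiv_negative"):
            num = _to_num(df[c])
            df[c] = num
            flag(~num.isna() & ~num.isin([0, 1]), "truth value must be 0/1 or empty", c)

    # arm exclusivity and ranges -------------------------------------------
    a_cols = [c for c in arm_a_columns(design) if c in df.columns]
    b_cols = [c for c in arm_b_columns(design) if c in df.columns]
    is_a, is_b = arm == "A", arm == "B"
    for c in a_cols:
        num = _to_num(df[c])
        df[c] = num
        miss = _is_missing(frame[c]) if c in frame.columns else pd.Series(True, index=df.index)
        flag(is_b & ~miss, "arm B record carries a list-format count/position", c)
        flag(is_a & miss, "arm A record missing a count/position", c)
        if c.startswith("count_"):
            flag(is_a & ~miss & ~num.between(0, J + 1), f"count outside [0, {J + 1}]", c)
        else:
            flag(is_a & ~miss & ~num.between(1, J + 1), f"position outside [1, {J + 1}]", c)
        flag(is_a & ~miss & (num != num.round()), "value is not an integer", c)
    for c in b_cols:
        num = _to_num(df[c])
        df[c] = num
        miss = _is_missing(frame[c]) if c in frame.columns else pd.Series(True, index=df.index)
        flag(is_a & ~miss, "arm A record carries item-level answers", c)
        flag(is_b & miss, "arm B record missing an item-level answer", c)
        flag(is_b & ~miss & ~num.isin([0, 1]), "answer must be 0/1", c)

    if errors and not lenient:
        raise ValidationError(errors)
    return df.loc[~bad].copy(), errors


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------

def read_respondents(
    path,
    design: SurveyDesign,
    mapping: ColumnMapping | None = None,
    *,
    lenient: bool = False,
) -> pd.DataFrame:
    """Read a respondent table, map it onto the canonical schema, validate.

    Parameters
    ----------
    path
        Delimited text file (comma-separated, header row).
    design
        Instrument the table refers to; drives the expected columns.
    mapping
        Schema map for non-canonical files.  ``None`` means identity.
    lenient
        Drop invalid rows (collecting row-indexed messages on the returned
        frame's ``attrs['rejected']``) instead of raising.

    Returns
    -------
    pandas.DataFrame
        Canonical-schema table.  ``attrs`` carries ``n_read``, ``n_accepted``
        and ``rejected`` (list of messages) for manifest logging.
    """
    raw = pd.read_csv(path, dtype="string", keep_default_na=False)
    n_read = len(raw)
    mapped = (mapping or ColumnMapping.identity()).apply(raw)
    validated, errors = validate_respondents(mapped, design, lenient=lenient)
    validated = validated.reset_index(drop=True)
    # covariate columns: numeric where fully parseable, else left as text
    known = set(canonical_columns(design))
    for c in validated.columns:
        if c in known:
            continue
        num = _to_num(validated[c])
        if not (num.isna() & ~_is_missing(validated[c])).any():
            validated[c] = num
    validated.attrs.update(n_read=n_read, n_accepted=len(validated), rejected=errors)
    return validated


def write_respondents(records: pd.DataFrame, path, design: SurveyDesign) -> None:
    """Write a canonical-schema table; round-trips through
    :func:`read_respondents` exactly.

    Booleans/ints are serialized as integers, missing values as empty
    strings.  Columns are emitted in canonical order followed by any extra
    (covariate) columns in their existing order.
    """
    cols = [c for c in canonical_columns(design) if c in records.columns]
    extra = [c for c in records.columns if c not in cols]
    out = records[cols + extra].copy()
    for c in out.columns:
        if pd.api.types.is_float_dtype(out[c]):
            as_int = out[c].round()
            if ((out[c].dropna() == as_int.dropna()).all()):
                out[c] = as_int.astype("Int64")
    out.to_csv(path, index=False)
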