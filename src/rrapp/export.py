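"""Serialization of schemes: audit table, REDCap allocation table, metadata.

Three artifacts make a scheme usable and auditable:

* the **audit table** — one row per allocation slot with sequence, stratum,
  block structure and arm; CSV is the primary dialect (bit-exact, diffable),
  XLSX a secondary writer with the metadata mirrored on a second sheet;
* the **REDCap allocation table** — the target arm code plus one coded
  column per stratification factor, directly importable into REDCap's
  randomization module, with a sidecar JSON mapping codes to labels;
* the **metadata record** — a JSON document carrying every input element,
  the pinned RNG identifier, tool version, timestamp and a checksum, from
  which the identical scheme can be regenerated.
"""
from __future__ import annotations

import hashlib
import json
import re
from datetime import datetime
from pathlib import Path
from typing import Optional

import pandas as pd

from ._version import __version__
from .model import (
    Assignment,
    ExportError,
    RandomizationSpec,
    Scheme,
    enumerate_strata,
)

AUDIT_COLUMNS = ["sequence", "stratum_label", "block_index", "block_size_used", "arm_code", "arm_label"]

#: Default REDCap randomization target field name; override per project.
DEFAULT_TARGET_FIELD = "randomization_group"

METADATA_FORMAT_VERSION = 1


def scheme_frame(scheme: Scheme) -> pd.DataFrame:
    """Audit table as a DataFrame (nullable ints for the block columns)."""
    df = pd.DataFrame(
        [
            (a.sequence, a.stratum_label, a.block_index, a.block_size_used, a.arm_code, a.arm_label)
            for a in scheme.assignments
        ],
        columns=AUDIT_COLUMNS,
    )
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in AUDIT_COLUMNS})
    df["block_index"] = df["block_index"].astype("Int64")
    df["block_size_used"] = df["block_size_used"].astype("Int64")
    return df


def _metadata_record(scheme: Scheme) -> dict:
    return {
        "format_version": METADATA_FORMAT_VERSION,
        "tool": "rrapp",
        "tool_version": scheme.tool_version,
        "generator": scheme.generator,
        "generated_at": scheme.generated_at.isoformat(),
        "truncated": scheme.truncated,
        "spec": scheme.spec_echo.model_dump(mode="json"),
        "checksum": scheme_checksum(scheme),
    }


def scheme_checksum(scheme: Scheme) -> str:
    """SHA-256 over the resolved spec and the full assignment list.

    Timestamps are excluded, so two generations from the same spec carry
    the same checksum; a tampered metadata record (e.g. an edited seed)
    regenerates to a different checksum and is flagged.
    """
    payload = {
        "spec": scheme.spec_echo.model_dump(mode="json"),
        "assignments": [
            [a.sequence, a.stratum_label, a.block_index, a.block_size_used, a.arm_code, a.arm_label]
            for a in scheme.assignments
        ],
    }
    blob = json.dumps(payload, sort_keys=True, separators=(",", ":")).encode()
    return hashlib.sha256(blob).hexdigest()


def write_audit_table(scheme: Scheme, path: str | Path) -> Path:
    """Write the audit table; dialect chosen by extension (.csv or .xlsx).

    CSV is UTF-8, comma-separated, header row, LF line endings; missing
    block fields (simple techniques) are empty cells, never 0.  The XLSX
    workbook adds a ``metadata`` sheet mirroring the metadata record.
    """
    path = Path(path)
    df = scheme_frame(scheme)
    try:
        if path.suffix.lower() in {".xlsx", ".xls"}:
            meta = _metadata_record(scheme)
            meta_df = pd.DataFrame(
                {"key": list(meta.keys()),
                 "value": [v if isinstance(v, str) else json.dumps(v) for v in meta.values()]}
            )
            with pd.ExcelWriter(path, engine="openpyxl") as xw:
                df.to_excel(xw, sheet_name="scheme", index=False)
                meta_df.to_excel(xw, sheet_name="metadata", index=False)
        else:
            df.to_csv(path, index=False, lineterminator="\n")
    except OSError as e:
        raise OSError(f"cannot write audit table to {path}: {e}") from e
    return path


def read_audit_table(path: str | Path) -> list[Assignment]:
    """Read an audit table (CSV or XLSX) back into assignments, losslessly."""
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path, sheet_name="scheme")
    else:
        df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Assignment(
                sequence=int(row.sequence),
                stratum_label=str(row.stratum_label),
                block_index=None if pd.isna(row.block_index) else int(row.block_index),
                block_size_used=None if pd.isna(row.block_size_used) else int(row.block_size_used),
                arm_code=int(row.arm_code),
                arm_label=str(row.arm_label),
            )
        )
    return out


def _snake(name: str) -> str:
    return re.sub(r"\W+", "_", name.strip().lower()).strip("_")


def redcap_code_maps(spec: RandomizationSpec, target_field: str = DEFAULT_TARGET_FIELD) -> dict:
    """Integer code ↔ label maps for the arm field and every factor column."""
    maps: dict[str, dict[str, str]] = {
        target_field: {str(i + 1): lab for i, lab in enumerate(spec.resolved_arm_labels())}
    }
    if spec.strata is not None and spec.strata.factors is not None:
        for name, levels in spec.strata.factors:
            maps[_snake(name)] = {str(i + 1): lv for i, lv in enumerate(levels)}
    return maps


def write_redcap_allocation(
    scheme: Scheme,
    spec: Optional[RandomizationSpec] = None,
    path: str | Path = "allocation.csv",
    target_field: str = DEFAULT_TARGET_FIELD,
) -> Path:
    """Write a REDCap-importable allocation table plus a sidecar code map.

    One row per allocation slot, no subject identifiers: the target field
    (coded arm) first, then one column per stratification factor holding
    the 1-based level code.  Count-based strata carry no real factor
    fields for REDCap to match on and are rejected.  The sidecar
    ``<stem>_codes.json`` documents every integer code ↔ label pair.
    """
    spec = spec if spec is not None else scheme.spec_echo
    path = Path(path)
    factor_cols: list[str] = []
    label_to_codes: dict[str, list[int]] = {}
    if spec.strata is not None:
        if spec.strata.factors is None:
            raise ExportError(
                "REDCAP_NEEDS_FACTORS",
                "REDCap allocation tables need factor-based strata (count-based strata have no fields to match on)",
            )
        factor_cols = [_snake(name) for name, _ in spec.strata.factors]
        level_index = {name: {lv: i + 1 for i, lv in enumerate(levels)}
                       for name, levels in spec.strata.factors}
        for stratum in enumerate_strata(spec.strata):
            label_to_codes[stratum.label] = [
                level_index[name][stratum.factor_levels[name]]
                for name, _ in spec.strata.factors
            ]
    rows = []
    for a in scheme.assignments:
        rows.append([a.arm_code] + (label_to_codes[a.stratum_label] if factor_cols else []))
    df = pd.DataFrame(rows, columns=[target_field] + factor_cols)
    try:
        df.to_csv(path, index=False, lineterminator="\n")
        sidecar = path.with_name(path.stem + "_codes.json")
        sidecar.write_text(
            json.dumps(redcap_code_maps(spec, target_field), indent=2, sort_keys=True) + "\n"
        )
    except OSError as e:
        raise OSError(f"cannot write REDCap allocation table to {path}: {e}") from e
    return path


def write_metadata(scheme: Scheme, path: str | Path) -> Path:
    """Write the JSON metadata record that fully documents the inputs.

    Feeding the record back through :func:`spec_from_metadata` and the
    generator reproduces the scheme bit-for-bit (same seed, same pinned
    RNG); the embedded checksum detects tampering.
    """
    path = Path(path)
    try:
        path.write_text(json.dumps(_metadata_record(scheme), indent=2) + "\n")
    except OSError as e:
        raise OSError(f"cannot write metadata to {path}: {e}") from e
    return path


def read_metadata(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def spec_from_metadata(record: dict) -> RandomizationSpec:
    """Rebuild the spec from a metadata record (structural validation applies)."""
    return RandomizationSpec.model_validate(record["spec"])


def check_metadata_compatibility(record: dict) -> None:
    """Refuse records this generator version cannot reproduce exactly.

    Compatibility requires the same RNG algorithm identifier, the same
    metadata format version, and the same tool major version — anything
    else could silently yield a different scheme.
    """
    from .engines import GENERATOR_ID

    if record.get("format_version") != METADATA_FORMAT_VERSION:
        raise ExportError("GENERATOR_VERSION_MISMATCH",
                          f"unsupported metadata format version {record.get('format_version')!r}")
    if record.get("generator") != GENERATOR_ID:
        raise ExportError("GENERATOR_VERSION_MISMATCH",
                          f"scheme was generated with {record.get('generator')!r}, this tool uses {GENERATOR_ID!r}")
    theirs = str(record.get("tool_version", "")).split(".")[0]
    ours = __version__.split(".")[0]
    if theirs != ours:
        raise ExportError("GENERATOR_VERSION_MISMATCH",
                          f"metadata from tool version {record.get('tool_version')!r}, this is {__version__}")


def format_filename(technique, timestamp: datetime, ext: str = "csv") -> str:
    """``rrapp_<technique>_<YYYYMMDD-HHMMSS>.<ext>`` — sorts chronologically."""
    tech = technique.value if hasattr(technique, "value") else str(technique)
    return f"rrapp_{tech}_{timestamp.strftime('%Y%m%d-%H%M%S')}.{ext}"
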