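"""Tabular writers and run manifests for reproducible CLI runs."""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path
from typing import Sequence

import pandas as pd

from .parameters import ParameterSet, parameter_digest

__all__ = ["ColumnSchema", "RunManifest", "write_table", "write_manifest"]

# column kind -> fixed decimal places (locale-independent)
_FORMATS = {"money": 2, "probability": 6, "effect": 6, "count": 0, "text": None, "raw": None}


@dataclass
class ColumnSchema:
    name: str
    kind: str = "raw"

    def __post_init__(self) -> None:
        if self.kind not in _FORMATS:
            raise ValueError(f"unknown column kind {self.kind!r}")


@dataclass
class RunManifest:
    """Everything needed to reproduce a CLI run bit-for-bit."""

    command: str
    parameter_digest: str
    seeds: dict[str, int] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    package_version: str = ""
    timestamp: str = ""

    @classmethod
    def for_run(
        cls, command: str, params: ParameterSet, seeds: dict[str, int] | None = None
    ) -> "RunManifest":
        try:
            version = metadata.version("deafcea")
        except metadata.PackageNotFoundError:  # pragma: no cover
            version = "unknown"
        return cls(
            command=command,
            parameter_digest=parameter_digest(params),
            seeds=dict(seeds or {}),
            package_version=version,
            timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        )


def write_table(
    rows: Sequence[dict] | pd.DataFrame,
    schema: Sequence[ColumnSchema],
    path: str | Path,
) -> Path:
    """Write rows as CSV with a fixed column order and per-kind rounding.

    Money columns print with 2 decimals, probabilities and effects with 6;
    every row must supply exactly the schema's columns.
    """
    names = [c.name for c in schema]
    if isinstance(rows, pd.DataFrame):
        records = rows.to_dict("records")
    else:
        records = list(rows)
    for i, row in enumerate(records):
        if set(row) != set(names):
            raise ValueError(
                f"row {i} does not match schema: got {sorted(row)}, want {sorted(names)}"
            )

    def fmt(value, kind: str) -> str:
        places = _FORMATS[kind]
        if value is None:
            return ""
        if places is None:
            return str(value)
        if isinstance(value, str):  # e.g. "Dominated" in an ICER column
            return value
        return f"{value:.{places}f}"

    path = Path(path)
    lines = [",".join(names)]
    for row in records:
        lines.append(",".join(fmt(row[c.name], c.kind) for c in schema))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_manifest(manifest: RunManifest, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "command": manifest.command,
        "parameter_digest": manifest.parameter_digest,
        "seeds": manifest.seeds,
        "outputs": manifest.outputs,
        "package_version": manifest.package_version,
        "timestamp": manifest.timestamp,
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path
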