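"""Trial-table CSV schema, validation, and run manifests.

CSV is the single interchange format. The column set is fixed and
validated on read; enum-valued columns reject unknown values with
line-numbered errors so malformed exports fail loudly rather than skewing
downstream counts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .simulate import TRIAL_COLUMNS

__all__ = ["TrialTableError", "read_trials", "write_trials", "RunManifest"]

_ENUM_COLUMNS = {
    "order": {"prenominal", "postnominal"},
    "phase": {"train", "test", "slider"},
    "meaning_type": {"descriptive", "possessive"},
    "experiment": {"1", "2"},
    "instruction_order": {"item-first", "modifier-first", ""},
}

_BOOL_COLUMNS = ("is_majority", "is_natural")


class TrialTableError(ValueError):
    """Schema violation in a trial CSV, with file line number."""


def write_trials(trials: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = trials.loc[:, TRIAL_COLUMNS].copy()
    out.to_csv(path, index=False)
    return path


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial CSV into the canonical typed frame."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != TRIAL_COLUMNS:
        raise TrialTableError(
            f"{path}: header mismatch; expected columns {TRIAL_COLUMNS}, got {list(df.columns)}"
        )
    for col, allowed in _ENUM_COLUMNS.items():
        bad = ~df[col].isin(allowed)
        if bad.any():
            i = int(bad.idxmax())
            raise TrialTableError(
                f"{path}, line {i + 2}: invalid value {df.at[i, col]!r} in column {col!r}"
            )
    typed = df.copy()
    typed["experiment"] = df["experiment"].astype(int)
    typed["trial_index"] = pd.to_numeric(df["trial_index"], errors="coerce").astype("Int64")
    for col in ("rt_ms", "slider_raw"):
        typed[col] = pd.to_numeric(df[col].replace("", None), errors="coerce")
    for col in _BOOL_COLUMNS:
        typed[col] = df[col].map({"True": True, "False": False, "": None})
    typed["instruction_order"] = df["instruction_order"].replace("", None)
    return typed


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every CLI command's outputs."""

    command: str
    seed: int
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def record_file(self, role: str, path, kind: str = "output") -> None:
        digest = _sha256(Path(path))
        (self.outputs if kind == "output" else self.inputs)[role] = {
            "path": str(path),
            "sha256": digest,
        }

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path
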