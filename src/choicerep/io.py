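"""Choice-log CSV schema and run configuration files.

The single interchange format is a comma-separated UTF-8 table with a header
row and a leading ``# schema=...`` comment line carrying the schema version.
``ChoiceRecord`` is the source of truth for the row schema; logs are read
into validated pandas DataFrames.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .agent import CHOICE_LOG_COLUMNS, AgentParams, DesignConfig, PopulationSpec
from .design import LONG_ITI, SHORT_ITI

__all__ = [
    "SCHEMA_VERSION",
    "ChoiceRecord",
    "RunConfig",
    "read_choice_log",
    "write_choice_log",
    "config_hash",
]

SCHEMA_VERSION = "choicerep-log-v1"

_STIM_LABELS = {"sham", "anodal", "cathodal"}
_ROLES = {"measurement", "bias_SN", "bias_LF", "target"}
_CHOICES = {"SN", "LF"}
_SHAM_ORDERS = {"sham_first", "sham_second"}


@dataclass(frozen=True)
class ChoiceRecord:
    """One played trial; the canonical row schema of a choice log."""

    participant_id: int
    session: int
    block: int
    stim: str
    sham_order: str
    trial_index: int
    triplet_id: Optional[int]
    role: str
    sn_value: int
    lf_value: int
    sn_distance: int
    extra_distance: int
    iti_before_ms: Optional[int]
    choice: str
    dt_ms: float
    timed_out: bool


def write_choice_log(records: pd.DataFrame, path) -> None:
    """Write a choice log with the schema-version comment line."""
    missing = [c for c in CHOICE_LOG_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records are missing columns {missing}")
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# schema={SCHEMA_VERSION}\n")
        records[CHOICE_LOG_COLUMNS].to_csv(fh, index=False)


def read_choice_log(path) -> pd.DataFrame:
    """Read and validate a choice log written by :func:`write_choice_log`.

    Raises a ValueError naming the first offending row for malformed values;
    unknown stimulation labels are a schema error.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
        body = fh.read()
    if first != f"# schema={SCHEMA_VERSION}":
        raise ValueError(f"{path}: unrecognised schema header {first!r}")
    df = pd.read_csv(_io.StringIO(body), dtype={"triplet_id": "Float64", "iti_before_ms": "Float64"})
    missing = [c for c in CHOICE_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        return df

    def first_bad(mask, what):
        idx = int(np.flatnonzero(mask.to_numpy())[0])
        # +3: schema comment line, header row, 1-based numbering
        raise ValueError(f"{path}: row {idx + 3}: {what}")

    bad = ~df["stim"].isin(_STIM_LABELS)
    if bad.any():
        first_bad(bad, f"unknown stim label {df.loc[bad, 'stim'].iloc[0]!r}")
    bad = ~df["role"].isin(_ROLES)
    if bad.any():
        first_bad(bad, f"unknown trial role {df.loc[bad, 'role'].iloc[0]!r}")
    bad = ~df["choice"].isin(_CHOICES)
    if bad.any():
        first_bad(bad, f"unknown choice {df.loc[bad, 'choice'].iloc[0]!r}")
    bad = ~df["sham_order"].isin(_SHAM_ORDERS)
    if bad.any():
        first_bad(bad, f"unknown sham_order {df.loc[bad, 'sham_order'].iloc[0]!r}")
    iti = df["iti_before_ms"]
    bad = iti.notna() & ~iti.isin([SHORT_ITI, LONG_ITI])
    if bad.any():
        first_bad(bad, f"iti_before_ms={iti[bad].iloc[0]} not in {{{SHORT_ITI}, {LONG_ITI}}}")
    bad = ~(df["dt_ms"] > 0)
    if bad.any():
        first_bad(bad, "non-positive decision time")
    bad = ~(df["sn_value"] < df["lf_value"])
    if bad.any():
        first_bad(bad, "sn_value must be smaller than lf_value")
    return df


_SECTION_TYPES = {
    "agent": AgentParams,
    "population": PopulationSpec,
    "design": DesignConfig,
}


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of an end-to-end run."""

    master_seed: int = 0
    n_participants: int = 8
    design: DesignConfig = field(default_factory=DesignConfig)
    agent: AgentParams = field(default_factory=AgentParams)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    filter_mode: str = "preceding"  # bias-success filter: preceding | both

    def __post_init__(self):
        if self.filter_mode not in ("preceding", "both"):
            raise ValueError("filter_mode must be 'preceding' or 'both'")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("population",):
            for tup in ("k_bounds", "tau_bounds"):
                d[key][tup] = list(d[key][tup])
        return d

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        kwargs = {}
        for name, typ in _SECTION_TYPES.items():
            if name in payload:
                section = payload.pop(name)
                allowed = {f.name for f in dataclasses.fields(typ)}
                unknown = set(section) - allowed
                if unknown:
                    raise ValueError(f"unknown keys in section {name!r}: {sorted(unknown)}")
                for tup in ("k_bounds", "tau_bounds"):
                    if tup in section:
                        section[tup] = tuple(section[tup])
                kwargs[name] = typ(**section)
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - allowed
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs.update(payload)
        return cls(**kwargs)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(payload, dict):
            raise ValueError("configuration file must contain a mapping")
        return cls.from_dict(payload)


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.to_yaml().encode()).hexdigest()[:16]
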