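"""Audit configuration: study window, intervention boundary, thresholds.

The configuration is a flat key-value mapping (YAML on disk).  Defaults
describe a 22-month study window with the intervention boundary at the
start of month 12, i.e. an 11-month pre period and an 11-month post
period; prescriptions ordered strictly before the boundary are "pre".
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from datetime import datetime
from typing import Optional

import yaml

from .duration import DEFAULT_TOLERANCE_DAYS

__all__ = ["AuditConfig", "load_flat_config"]


def _ts(value) -> datetime:
    if isinstance(value, datetime):
        return value
    return datetime.fromisoformat(str(value))


@dataclass(frozen=True)
class AuditConfig:
    """Resolved audit settings.

    tolerance_days is the written-vs-calculated equality tolerance
    (default effectively exact); round_calculated optionally rounds
    calculated durations to whole days before classification, for
    sensitivity analysis.
    """

    study_start: datetime = datetime(2017, 10, 1)
    intervention_datetime: datetime = datetime(2018, 9, 1)
    study_end: datetime = datetime(2019, 8, 1)
    tolerance_days: float = DEFAULT_TOLERANCE_DAYS
    round_calculated: bool = False
    excluded_drugs: tuple[str, ...] = ("buprenorphine", "methadone")
    lexicon_path: Optional[str] = None
    ci_method: str = "wald"
    chi2_correction: bool = False
    welch: bool = True

    def __post_init__(self) -> None:
        if not (self.study_start <= self.intervention_datetime <= self.study_end):
            raise ValueError("intervention_datetime must fall inside the study window")
        if self.tolerance_days < 0:
            raise ValueError("tolerance_days must be nonnegative")

    @classmethod
    def from_file(cls, path) -> "AuditConfig":
        return cls.from_mapping(load_flat_config(path))

    @classmethod
    def from_mapping(cls, mapping: dict) -> "AuditConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown audit config keys: {', '.join(sorted(unknown))}")
        kwargs = dict(mapping)
        for key in ("study_start", "intervention_datetime", "study_end"):
            if key in kwargs:
                kwargs[key] = _ts(kwargs[key])
        if "excluded_drugs" in kwargs:
            kwargs["excluded_drugs"] = tuple(kwargs["excluded_drugs"])
        return cls(**kwargs)

    def echo(self) -> dict:
        """Serializable copy of the resolved configuration."""
        out = asdict(self)
        for key in ("study_start", "intervention_datetime", "study_end"):
            out[key] = out[key].isoformat()
        out["excluded_drugs"] = list(out["excluded_drugs"])
        return out


def load_flat_config(path) -> dict:
    """Read a flat key-value YAML file; empty file means all defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config must be a flat key-value mapping, got {type(data).__name__}")
    return data
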