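"""Parameter registry: every tunable constant of the pipeline in one place.

Defaults follow the published workflow this package implements: contigs
classified *complete* need a profile hit covering more than 70 % of the
profile's match states; contigs with fewer than five mapped reads are
discarded; assembly integration deduplicates at 99 % identity (word size 8)
and clusters at 95 % identity over at least 50 bp; mates are truncated to
their first 50 nt before insert-size inference; candidate ORFs must encode
at least 30 aa; the length criterion is mean +/- 2 standard deviations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping


class ConfigurationError(ValueError):
    """Raised when a parameter value is outside its valid domain."""


@dataclass
class ParameterSet:
    """Effective parameter values for a pipeline run.

    All fractions live in (0, 1]; counts are non-negative. ``adapter_total``
    is the summed length of the ligated sequencing adapters (bp), added to
    inferred insert sizes to obtain fragment sizes; the default corresponds
    to standard paired-end adapters.
    """

    coverage_threshold: float = 0.70
    min_mapping_count: int = 5
    dedup_identity: float = 0.99
    dedup_word: int = 8
    cluster_identity: float = 0.95
    min_overlap: int = 50
    mate_truncation: int = 50
    min_orf: int = 30
    adapter_total: int = 122
    length_sd_multiplier: float = 2.0
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("coverage_threshold", "dedup_identity", "cluster_identity"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigurationError(f"{name} must be in (0, 1], got {v!r}")
        for name in (
            "min_mapping_count",
            "dedup_word",
            "min_overlap",
            "mate_truncation",
            "min_orf",
            "adapter_total",
        ):
            v = getattr(self, name)
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v!r}")
        if self.length_sd_multiplier < 0:
            raise ConfigurationError("length_sd_multiplier must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d.pop("extra")
        d.update(self.extra)
        return d

    @classmethod
    def from_sources(
        cls,
        config_file: str | Path | None = None,
        overrides: Mapping[str, Any] | None = None,
    ) -> "ParameterSet":
        """Merge defaults < config file < explicit overrides (flags win)."""
        values: dict[str, Any] = {}
        if config_file is not None:
            with open(config_file) as fh:
                loaded = json.load(fh)
            if not isinstance(loaded, dict):
                raise ConfigurationError("config file must contain a JSON object")
            values.update(loaded)
        if overrides:
            values.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls) if f.name != "extra"}
        extra = {k: v for k, v in values.items() if k not in known}
        kwargs = {k: v for k, v in values.items() if k in known}
        return cls(extra=extra, **kwargs)
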