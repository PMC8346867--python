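"""Flat key=value run configuration for the command-line interface.

The config file is INI-without-sections: one ``key = value`` pair per line,
``#`` comments allowed.  Unknown keys are rejected; flags override file
values; every threshold defaults to its module default.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional

from .chip import DEFAULT_FDR_MAX, DEFAULT_MIN_FOLD, DEFAULT_TOP_FRACTION
from .rnaseq import DEFAULT_LFC_MIN
from .types import FormatError


@dataclass
class RunConfig:
    indir: str = "."
    outdir: str = "out"
    seed: int = 0
    fdr_max: float = DEFAULT_FDR_MAX
    min_fold: float = DEFAULT_MIN_FOLD
    top_fraction: float = DEFAULT_TOP_FRACTION
    lfc_min: float = DEFAULT_LFC_MIN
    lfc_thresh: float = DEFAULT_LFC_MIN  # perturbation-contrast threshold
    motif_threshold: Optional[float] = None  # None -> PWM default

    def validate(self) -> None:
        if not (0 < self.fdr_max <= 1):
            raise ValueError("fdr_max must lie in (0, 1]")
        if self.min_fold <= 0 or self.top_fraction <= 0 or self.top_fraction > 1:
            raise ValueError("min_fold must be > 0 and top_fraction in (0, 1]")
        if self.lfc_min < 0 or self.lfc_thresh < 0:
            raise ValueError("log2 fold-change thresholds must be >= 0")


_FIELD_TYPES = {f.name: f.type for f in fields(RunConfig)}


def _coerce(key: str, value: str):
    if key in ("indir", "outdir"):
        return value
    if key == "seed":
        return int(value)
    if key == "motif_threshold":
        return None if value.lower() in ("none", "") else float(value)
    return float(value)


def parse_config_file(path: str) -> RunConfig:
    cfg = RunConfig()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key = value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in _FIELD_TYPES:
                raise FormatError(f"{path}:{lineno}: unknown key {key!r}")
            try:
                setattr(cfg, key, _coerce(key, value))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    cfg.validate()
    return cfg


def dump_defaults() -> str:
    cfg = RunConfig()
    lines = []
    for f in fields(RunConfig):
        value = getattr(cfg, f.name)
        if isinstance(value, float) and not math.isnan(value):
            value = f"{value:.6g}"
        lines.append(f"{f.name} = {value}")
    return "\n".join(lines) + "\n"
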