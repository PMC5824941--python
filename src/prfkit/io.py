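"""Tables, configuration, manifests, and JSON-lines logging.

All tabular artifacts are tab-delimited text with an optional block of
``# key: value`` comment lines; arrays travel as compressed npz containers
with plain-text sidecars (see :mod:`prfkit.stimulus`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml


class SchemaError(ValueError):
    """A table is missing a required column."""


def write_table(df: pd.DataFrame, path, meta: dict | None = None,
                float_format: str = "%.6f") -> None:
    """Tab-delimited table with commented header; fixed decimal places so
    identical runs diff cleanly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)


def read_table(path, required=None) -> tuple[pd.DataFrame, dict]:
    """Read a tab table; returns (frame, meta). Unknown columns are kept.

    Raises :class:`SchemaError` naming the first missing required column.
    """
    path = Path(path)
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                k, _, v = line[1:].partition(":")
                meta[k.strip()] = v.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t")
    for col in required or ():
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    return df, meta


def append_jsonl(path, record: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "a") as fh:
        fh.write(json.dumps(record, sort_keys=True, default=str) + "\n")


@dataclass
class PipelineConfig:
    """Every tunable constant of the analysis, with documented defaults.

    Thresholds mirror the standard analysis: voxels kept above 5% variance
    explained, centers within the 7 dva stimulated field, sigma above the
    0.21 dva fitting floor; coverage binarized at 0.01; AFZ at 70% adult
    overlap; blink pad 100 ms; density smoothing 18.75 px; 50 coverage
    bootstrap iterations. Each stochastic stage has its own named seed.
    """

    # geometry / acquisition
    field_radius: float = 7.0
    tr: float = 2.0
    bar_width: float = 2.0
    bar_length: float = 14.0
    steps_per_sweep: int = 12
    grid_px: int = 101
    coverage_grid_n: int = 128
    # thresholds
    ve_min: float = 0.05
    ecc_max: float = 7.0
    sigma_floor: float = 0.21
    binarize_at: float = 0.01
    afz_overlap: float = 0.70
    blink_pad_ms: float = 100.0
    smoothing_sigma_px: float = 18.75
    n_boot: int = 50
    n_permutations: int = 500
    combine_rule: str = "mean"
    # synthetic-study sizes
    n_participants_per_group: int = 3
    n_voxels_per_roi: int = 30
    noise_sd: float = 0.1
    n_runs: int = 4
    n_gaze_fixations: int = 25
    gaze_spread_px: float = 40.0
    child_gaze_offset: tuple = (40.0, -40.0)
    # fitting
    refine: bool = True
    fit_grid_nxy: int = 13
    fit_grid_nsigma: int = 6
    # seeds (one per stochastic stage; no hidden global randomness)
    seed_truth: int = 101
    seed_bold: int = 202
    seed_coverage: int = 303
    seed_gaze: int = 404
    seed_stats: int = 505

    def __post_init__(self):
        if not (0 <= self.ve_min <= 1 and 0 <= self.binarize_at <= 1
                and 0 <= self.afz_overlap <= 1):
            raise ValueError("fraction thresholds must lie in [0, 1]")
        if min(self.field_radius, self.tr, self.sigma_floor,
               self.smoothing_sigma_px) <= 0 or self.blink_pad_ms < 0:
            raise ValueError("scale parameters must be positive")
        if self.n_boot < 1 or self.n_permutations < 1:
            raise ValueError("iteration counts must be >= 1")
        if isinstance(self.child_gaze_offset, list):
            self.child_gaze_offset = tuple(self.child_gaze_offset)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        """Build from a flat key:value mapping; dotted namespaces allowed
        (``fit.ve_min`` and ``ve_min`` both address ve_min); missing keys
        take the documented defaults; unknown keys are rejected."""
        names = {f.name for f in dataclasses.fields(cls)}
        kw = {}
        for k, v in (mapping or {}).items():
            short = k.split(".")[-1]
            if short not in names:
                raise KeyError(f"unknown config key: {k}")
            kw[short] = v
        return cls(**kw)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record: identical manifests (ignoring timestamp) imply
    bit-identical deterministic outputs."""

    config_hash: str
    seeds: dict
    tool_version: str
    input_digests: dict = field(default_factory=dict)
    timestamp: str = ""

    def identity(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("timestamp")
        return d

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def for_config(cls, config: PipelineConfig, version: str) -> "RunManifest":
        seeds = {k: v for k, v in config.to_dict().items()
                 if k.startswith("seed_")}
        return cls(config_hash=config_hash(config), seeds=seeds,
                   tool_version=version,
                   timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))
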