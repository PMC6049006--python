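"""Pipeline configuration: typed, strict (unknown keys rejected), with
two bundled scale profiles.

``full_scale`` mirrors a hologenome-scale study design;
``smoke`` is a desk-scale community (500 kb host, two symbionts, 40x)
small enough for an end-to-end run in seconds to minutes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError as PydanticValidationError

from .errors import ValidationError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    host_length: int = 500_000
    host_het_rate: float = 0.005
    host_repeat_fraction: float = 0.15
    host_repeat_unit_length: int = 500
    host_gc: float = 0.4
    host_depth: float = 40.0
    symbiont_lengths: list[int] = Field(default_factory=lambda: [150_000, 100_000])
    symbiont_gcs: list[float] = Field(default_factory=lambda: [0.62, 0.30])
    symbiont_depths: list[float] = Field(default_factory=lambda: [20.0, 12.0])
    read_length: int = 250
    error_rate: float = 0.005
    paired: bool = True
    insert_size: int = 600
    contig_n50: int = 5_000
    contig_min_length: int = 2_000


class SpectrumConfig(_Strict):
    k: int = 21
    k_grid: list[int] = Field(default_factory=lambda: [17, 19, 21, 23, 25])
    smoothing_window: int = 5
    error_cutoff: int | None = None
    repeat_cutoff: float | None = None
    m_poisson: int = 2
    m_nb: int = 4


class BinningConfig(_Strict):
    w: float = 0.7
    tau: float = 0.05
    min_bin_size: int = 20_000
    min_contig_length: int = 2_000
    host_mode: Literal["truth", "heuristic"] = "heuristic"
    gc_window: float = 0.03
    depth_factor: float = 2.0


class RecruitConfig(_Strict):
    k: int = 21
    theta: float = 0.5


class AssessConfig(_Strict):
    n_split: int = 10
    marker_k: int = 21
    marker_complete_threshold: float = 0.9
    n_markers: int = 50
    marker_length: int = 1_000


class PipelineConfig(_Strict):
    profile: str = "smoke"
    seed: int = 0
    outdir: str = "holopipe_run"
    # binning precedes the spectrum stage so genomic features are
    # estimated from the recruited host reads, not the whole hologenome
    stages: list[str] = Field(
        default_factory=lambda: ["simulate", "count", "bin", "recruit", "spectrum", "assess"]
    )
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    spectrum: SpectrumConfig = Field(default_factory=SpectrumConfig)
    binning: BinningConfig = Field(default_factory=BinningConfig)
    recruit: RecruitConfig = Field(default_factory=RecruitConfig)
    assess: AssessConfig = Field(default_factory=AssessConfig)


PROFILES: dict[str, dict] = {
    "smoke": {},  # the defaults above
    "full_scale": {
        # hologenome-scale study design: large diploid host, several
        # symbionts, 2x250 paired reads; only usable with cluster-scale
        # resources, kept for documentation of intent
        "simulate": {
            "host_length": 400_000_000,
            "host_depth": 63.0,
            "symbiont_lengths": [1_500_000_000, 5_000_000, 4_000_000],
            "symbiont_gcs": [0.50, 0.45, 0.60],
            "symbiont_depths": [10.0, 30.0, 20.0],
        },
        "binning": {"min_bin_size": 200_000},
    },
}


def load_config(path=None, profile: str | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Build a config from (optionally) a YAML file, a named profile and
    explicit overrides, rejecting unknown keys."""
    data: dict = {}
    if profile is not None:
        if profile not in PROFILES:
            raise ValidationError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
        data = _deep_merge(data, PROFILES[profile])
        data["profile"] = profile
    if path is not None:
        with open(path) as fh:
            file_data = yaml.safe_load(fh) or {}
        if not isinstance(file_data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        data = _deep_merge(data, file_data)
    if overrides:
        data = _deep_merge(data, overrides)
    try:
        return PipelineConfig(**data)
    except PydanticValidationError as exc:
        raise ValidationError(str(exc)) from exc


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for key, val in extra.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def dump_config(cfg: PipelineConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=True)
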