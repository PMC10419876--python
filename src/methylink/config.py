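"""Run configuration: simulation + pipeline parameters from a YAML file.

The file has two mappings, ``sim`` (fields of
:class:`methylink.simulate.SimConfig`; ``seed`` is mandatory) and
``pipeline`` (fields of :class:`PipelineParams`).  Unknown keys are
rejected, and the resolved configuration is echoed into the output
directory of every run so results are reproducible from the artifact tree
alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .simulate import SimConfig


@dataclass
class PipelineParams:
    """Analysis-stage parameters (defaults mirror common plant-methylome
    practice; every one is exposed here and on the CLI)."""

    window: int = 200            # DMR sliding window, bp
    step: int = 50               # window step, bp
    delta_min: float = 0.1       # minimum |delta ML| for a DMR
    dmr_alpha: float = 0.05      # DMR FDR level
    merge_gap: int = 100         # max gap between merged windows, bp
    promoter_length: int = 2000  # upstream-of-TSS promoter, bp
    bin_width: int = 10_000      # genome bin width for ML profiles
    site_alpha: float = 0.05     # site-call FDR level
    min_coverage: int = 4        # reads needed to test a site
    fc_min: float = 1.0          # minimum |log2FC| for a DEG
    deg_alpha: float = 0.05      # DEG FDR level
    pseudocount: float = 1.0     # added to RPKM before log2
    r: float | None = None       # non-conversion rate; None = estimate from control contig


@dataclass
class RunConfig:
    sim: SimConfig
    pipeline: PipelineParams


def _from_mapping(cls, mapping: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown key(s) in config section {section!r}: {sorted(unknown)}")
    return cls(**mapping)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - {"sim", "pipeline"}
    if unknown:
        raise ValueError(f"{path}: unknown top-level section(s) {sorted(unknown)}")
    sim_raw = raw.get("sim", {}) or {}
    if "seed" not in sim_raw:
        raise ValueError(f"{path}: sim.seed is mandatory")
    sim = _from_mapping(SimConfig, sim_raw, "sim")
    sim.validate()
    pipeline = _from_mapping(PipelineParams, raw.get("pipeline", {}) or {}, "pipeline")
    return RunConfig(sim=sim, pipeline=pipeline)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Echo the fully resolved configuration (all defaults materialised)."""
    payload = {
        "sim": dataclasses.asdict(config.sim),
        "pipeline": dataclasses.asdict(config.pipeline),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
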