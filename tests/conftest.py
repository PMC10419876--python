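"""Shared fixtures: small simulated datasets, cached pipeline runs."""

from __future__ import annotations

import pytest

from methylink.dmr import call_dmrs
from methylink.simulate import SimConfig, simulate_dataset


def small_config(seed: int = 11, **overrides) -> SimConfig:
    """A fast single-chromosome study for I/O and bookkeeping tests."""
    defaults = dict(
        seed=seed,
        n_chroms=1,
        chrom_length=30_000,
        n_genes=6,
        n_planted_dmrs=6,
        n_planted_degs=4,
        coverage_mean=10.0,
        control_length=5_000,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config())


@pytest.fixture(scope="session")
def pipeline_cache():
    """Memoised (scenario, seed, coupled) -> (dataset, dmrs) at default scale.

    Several acceptance properties interrogate the same simulated runs; the
    cache keeps the suite inside its time budget without changing any
    study condition.
    """
    cache: dict[tuple, tuple] = {}

    def get(scenario: str, seed: int, coupled_fraction: float = 0.5):
        key = (scenario, seed, coupled_fraction)
        if key not in cache:
            cfg = SimConfig(seed=seed, scenario=scenario, coupled_fraction=coupled_fraction)
            ds = simulate_dataset(cfg)
            dmrs = call_dmrs(
                ds.methyl_counts, ds.case_samples, ds.control_samples, ds.chrom_lengths
            )
            cache[key] = (ds, dmrs)
        return cache[key]

    return get


def dmr_overlaps_truth(dmr, truth_row) -> bool:
    return (
        dmr.chrom == truth_row.chrom
        and dmr.start < truth_row.end
        and dmr.end > truth_row.start
        and dmr.context == truth_row.context
    )
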