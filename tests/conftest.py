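"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cpgdrift.simulate import SimConfig, simulate_beta, simulate_manifest
from cpgdrift.types import BetaMatrix, CpGRecord


@pytest.fixture
def toy_manifest() -> list[CpGRecord]:
    """Four CpGs on one gene plus an intergenic one."""
    return [
        CpGRecord("cg01", "chr1", 100, "+", frozenset({"G1"}), frozenset({"TSS200"}), "Island"),
        CpGRecord("cg02", "chr1", 300, "+", frozenset({"G1"}), frozenset({"Exon1"}), "Island"),
        CpGRecord("cg03", "chr1", 900, "+", frozenset({"G1"}), frozenset({"Body"}), "Shore"),
        CpGRecord("cg04", "chr1", 2500, "+", frozenset({"G1"}), frozenset({"UTR3"}), "Shelf"),
        CpGRecord("cg05", "chr1", 9000, "+", frozenset(), frozenset({"Intergenic"}), "OpenSea"),
    ]


def make_beta(values: np.ndarray, site_ids, conditions, donors) -> BetaMatrix:
    """Beta matrix with columns ordered condition-major, donor-minor."""
    cols = [f"{c}_{d}" for c in conditions for d in donors]
    sheet = pd.DataFrame(
        {
            "sample_id": cols,
            "donor": [d for _ in conditions for d in donors],
            "condition": [c for c in conditions for _ in donors],
        }
    ).set_index("sample_id")
    return BetaMatrix(pd.DataFrame(values, index=list(site_ids), columns=cols), sheet)


@pytest.fixture
def paired_beta(toy_manifest) -> BetaMatrix:
    """5 sites x (2 conditions x 3 donors) with a known hyper shift on cg01."""
    rng = np.random.default_rng(42)
    base = rng.uniform(0.2, 0.6, size=(5, 1))
    vals = np.clip(base + rng.normal(0, 0.01, size=(5, 6)), 0, 1)
    vals[0, 3:] += 0.3  # cg01 shifted up in condition B
    return make_beta(vals, [r.cpg_id for r in toy_manifest], ["A", "B"], ["D1", "D2", "D3"])


@pytest.fixture(scope="session")
def small_genome():
    """A 1,000-CpG synthetic genome shared across read-only tests."""
    return simulate_manifest(SimConfig(n_cpg=1_000, seed=11))


@pytest.fixture(scope="session")
def small_study(small_genome):
    config = SimConfig(n_cpg=1_000, seed=11)
    beta, truth = simulate_beta(config, small_genome)
    return config, small_genome, beta, truth
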