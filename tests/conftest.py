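"""Shared fixtures for the genesisnet test suite."""

from __future__ import annotations

import numpy as np
import pytest

from genesisnet.classification import GROUPS
from genesisnet.dataio import EdgeTable, GeneCatalog, GeneRecord
from genesisnet.synthetic_data import SyntheticConfig, neutral_mixing


def make_record(gene_id, length=100, **kwargs):
    return GeneRecord(gene_id=gene_id, length_aa=length, **kwargs)


@pytest.fixture
def tiny_catalog():
    return GeneCatalog(
        [
            make_record("g1", 200, essential=True,
                        terms={"function": frozenset({"T1"})}),
            make_record("g2", 400),
            make_record("g3", 150, subtelomeric=True),
            make_record("g4", 300, dubious=True),
            make_record("g5", 250),
        ]
    )


@pytest.fixture
def tiny_edges():
    return EdgeTable(edges=[("g1", "g2", "small_scale"),
                            ("g2", "g3", "high_throughput"),
                            ("g3", "g5", "unknown")])


def small_sim_config(seed=0, **overrides) -> SyntheticConfig:
    """Five groups at ~1/10 of the default scale; fast to generate."""
    defaults = dict(
        group_sizes={
            ("pre_wgd", "duplicate"): 143,
            ("pre_wgd", "novel"): 270,
            ("wgd", "duplicate"): 108,
            ("post_wgd", "duplicate"): 31,
            ("post_wgd", "novel"): 24,
        },
        n_dubious=10,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def flat_sim_config(group_size=100, mixing=None, seed=0, **overrides) -> SyntheticConfig:
    """Equal-size groups with full interaction participation (network tests)."""
    defaults = dict(
        group_sizes={g: group_size for g in GROUPS},
        interaction_prob={g: 1.0 for g in GROUPS},
        mixing=mixing or neutral_mixing(),
        n_dubious=0,
        subtelomeric_prob=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
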