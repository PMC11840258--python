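"""Shared fixtures: synthetic families and tiny hand-built genes."""

import numpy as np
import pytest

from defchimera.chimera import DefensinGene
from defchimera.simulate import FamilyConfig, make_family

#: configuration for small oracle-scale families (exon-2 CDS under 60 nt)
SMALL_FAMILY_KWARGS = dict(
    prepro_len=20, signal_len=2, mature_len=13, n_cys=6,
    exon1_frac=0.3, identity=0.90,
)


def small_family(n_genes: int, seed: int, **overrides):
    kwargs = {**SMALL_FAMILY_KWARGS, **overrides}
    return make_family(FamilyConfig(n_genes=n_genes, seed=seed, **kwargs))


@pytest.fixture(scope="session")
def family_small():
    """Three-gene synthetic family (seed 7) used across modules."""
    return small_family(3, seed=7)


@pytest.fixture(scope="session")
def family_five():
    return small_family(5, seed=11)


@pytest.fixture(scope="session")
def family_default():
    """A 5-gene family at full defensin geometry (92-aa pre-pro-protein)."""
    return make_family(FamilyConfig(n_genes=5, seed=7, identity=0.95))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
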