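import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from miniexome.effect_model import TraitModelConfig, packaged_effect_table
from miniexome.genotype_synth import (
    functional_mafs,
    functional_only_map,
    generate_founder_haplotypes,
)
from miniexome.pedigree import generate_pedigree_set, kinship

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tables():
    return {t: packaged_effect_table(t) for t in ("Q1", "Q2", "LIABILITY")}


@pytest.fixture(scope="session")
def cfg():
    return TraitModelConfig()


@pytest.fixture(scope="session")
def functional_panel(tables):
    """697 unrelated individuals genotyped at the functional markers only."""
    fmap, genes = functional_only_map(tuple(tables.values()))
    panel = generate_founder_haplotypes(
        functional_mafs(fmap, tuple(tables.values())), 697, fmap, seed=20_260,
    )
    return panel, genes


@pytest.fixture(scope="session")
def default_ped():
    return generate_pedigree_set(8, 697, 202, 4, seed=91)


@pytest.fixture(scope="session")
def default_kin(default_ped):
    return kinship(default_ped)
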