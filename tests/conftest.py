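"""Shared fixtures: one small simulated universe reused across test modules.

Everything is generated at test time by :mod:`corevert.fixtures` with fixed
seeds; session scope keeps the expensive steps (derivation, profile HMM
construction) to a single run.
"""

from __future__ import annotations

import pytest

from corevert import fixtures
from corevert.align import Blosum62LocalScorer
from corevert.ortho_core import derive_core_set
from corevert.profiles import HmmerEngine, StackAligner, build_dataset

SEED = 11


@pytest.fixture(scope="session")
def scorer():
    return Blosum62LocalScorer()


@pytest.fixture(scope="session")
def engine():
    return HmmerEngine(seed=42)


@pytest.fixture(scope="session")
def sim_families(scorer):
    """20 families with two of each defect class, rest defect-free."""
    scenarios = fixtures.standard_scenarios(
        20,
        n_missing=2,
        n_no_outgroup=2,
        n_rbh=2,
        n_duplication=3,
        n_pre_vertebrate=2,
        seed=SEED,
    )
    return fixtures.simulate_gene_families(20, scenarios=scenarios, seed=SEED)


@pytest.fixture(scope="session")
def core_set(sim_families, scorer):
    return derive_core_set(
        groups=sim_families.groups,
        trees=sim_families.trees,
        new_proteome=sim_families.late_proteome,
        taxonomy=sim_families.taxonomy,
        panel=sim_families.panel,
        scorer=scorer,
        reference_proteins=sim_families.reference_proteins,
    )


@pytest.fixture(scope="session")
def all_proteins(sim_families):
    return sim_families.reference_proteins.merged(sim_families.late_proteome)


@pytest.fixture(scope="session")
def dataset(core_set, all_proteins, engine):
    """Profiles + cutoffs for every derived gene (busco-like: has consensus)."""
    return build_dataset(
        core_set, all_proteins, aligner=StackAligner(), engine=engine,
        flavor="busco-like",
    )
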