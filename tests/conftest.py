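from __future__ import annotations

import pytest

import interolog as il


@pytest.fixture(scope="session")
def small_fixture():
    """One modest 3-species fixture shared by read-only tests."""
    spec = il.FixtureSpec(
        n_species=3,
        genes_per_species=30,
        n_ortholog_groups=20,
        interaction_density=2.0,
        conservation_probability=0.5,
        seed=42,
    )
    truth, dataset, report = il.generate_dataset(spec)
    return spec, truth, dataset, report
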