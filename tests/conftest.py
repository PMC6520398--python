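import numpy as np
import pandas as pd
import pytest

from modelfidelity.simulate import GeneratorConfig, generate_cohort


def small_config(seed: int = 7, **overrides) -> GeneratorConfig:
    """A shrunken study for fast wiring tests (not the default conditions)."""
    base = dict(
        seed=seed,
        n_genes=400,
        n_panel_genes=200,
        tumors_per_subtype={"LuminalA": 5, "LuminalB": 5, "Her2": 5, "Basal": 5},
        site_sizes={"liver": 9, "lymph_node": 6, "bone": 5},
        n_primary_tumors=150,
        n_breast_cell_lines=16,
        n_nonbreast_cell_lines=40,
        n_organoids=8,
        n_metastatic_derived=10,
        n_subtype_genes=80,
        n_lineage_genes=120,
        n_site_genes=40,
        n_culture_genes=140,
        gain_region=(2, 10, 25),
        loss_region=(3, 5, 25),
        n_culture_sets=2,
        n_control_sets=2,
        set_size=10,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    return generate_cohort(small_config())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def expr3x2():
    return pd.DataFrame(
        [[1.0, 4.0], [2.0, 5.0], [3.0, 0.5]],
        index=pd.Index(["GA", "GB", "GC"], name="gene"),
        columns=["S1", "S2"],
    )
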