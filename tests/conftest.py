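import numpy as np
import pandas as pd
import pytest

import graftaxis as ga


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def tiny_expression():
    """3 genes x 3 samples, hand-checkable."""
    data = pd.DataFrame(
        [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [0.0, 10.0, 20.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3"],
    )
    return ga.ExpressionMatrix(data, normalized=True)


@pytest.fixture()
def tiny_panel():
    """4 proteins x 4 samples with known pairwise Spearman structure:
    A vs B = -1, A vs C = 0.8, B vs C = -0.8; D is constant-free filler."""
    data = pd.DataFrame(
        {
            "s1": [1.0, 4.0, 1.0, 2.0],
            "s2": [2.0, 3.0, 3.0, 1.0],
            "s3": [3.0, 2.0, 2.0, 4.0],
            "s4": [4.0, 1.0, 4.0, 3.0],
        },
        index=["A", "B", "C", "D"],
    )
    return ga.ProteinPanel(data)


@pytest.fixture()
def small_config():
    """A fast synthetic scenario: 4 modules (2 MB / 2 INF), 240 member genes,
    60 background, 40 proteins of which 3 INJURY-like and 3 HEALTH-like."""
    couplings = []
    for j, r in enumerate((0.85, 0.8, 0.75)):
        couplings.append(ga.ProteinCoupling(j, "MB", -r))
        couplings.append(ga.ProteinCoupling(j, "INF", r))
        couplings.append(ga.ProteinCoupling(3 + j, "MB", r))
        couplings.append(ga.ProteinCoupling(3 + j, "INF", -r))
    return ga.SyntheticConfig(
        n_samples=30,
        n_modules=4,
        genes_per_module=60,
        n_background_genes=60,
        module_loading=0.9,
        axis_map={1: "MB", 2: "MB", 3: "INF", 4: "INF"},
        n_proteins=40,
        protein_couplings=couplings,
        clinical_couplings=(0.6, -0.6),
        noise_sd=0.3,
        seed=0,
    )


@pytest.fixture(scope="session")
def reference_cohort():
    """One reference-scenario cohort, shared across read-only tests."""
    return ga.generate_cohort(ga.reference_scenario(), seed=7)
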