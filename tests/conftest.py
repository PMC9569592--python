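import numpy as np
import pandas as pd
import pytest

from fusionlab import clinical_bn as cb
from fusionlab import (
    GeneratorConfig,
    discretize_clinical,
    extract_malignancy_risk,
    generate_clinical,
    generate_expression,
)


@pytest.fixture(scope="session")
def clinical_net():
    """Hand-built 5-node network mirroring the clinical graph: Risk has
    parents Age and Bethesda; Sex and Size are isolated."""
    domains = {
        "Sex": ["F", "M"],
        "Age": list(cb.AGE_BANDS),
        "Size": list(cb.SIZE_BANDS),
        "Bethesda": ["II", "III", "IV", "V", "VI"],
        "Risk": ["benign", "malignant"],
    }
    parents = {"Sex": (), "Age": (), "Size": (), "Bethesda": (), "Risk": ("Age", "Bethesda")}
    cpts = {
        "Sex": np.array([[0.8], [0.2]]),
        "Age": np.array([[0.05], [0.4], [0.35], [0.2]]),
        "Size": np.full((6, 1), 1 / 6),
        "Bethesda": np.array([[0.2], [0.3], [0.25], [0.18], [0.07]]),
    }
    tab = np.zeros((2, 20))
    for ai in range(4):
        for bi in range(5):
            j = np.ravel_multi_index((ai, bi), (4, 5))
            p = 1.0 / (1.0 + np.exp(-(-2.5 + 1.2 * bi + 0.25 * ai)))
            tab[:, j] = [1 - p, p]
    cpts["Risk"] = tab
    return cb.BayesNet(nodes=sorted(domains), domains=domains, parents=parents, cpts=cpts)


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-sample synthetic cohort with a modest 30-gene panel plus its
    discretized clinical table and cross-fitted risk."""
    cfg = GeneratorConfig(seed=7, n_genes=30, n_informative=5)
    clin = generate_clinical(cfg)
    expr = generate_expression(cfg, clin["label"])
    table = discretize_clinical(clin)
    risk = extract_malignancy_risk(table, k=10, seed=0, method="exact")
    y = (clin["label"] == "malignant").astype(int).to_numpy()
    return cfg, expr, table, risk.to_numpy(), y


@pytest.fixture(scope="session")
def study_cohort():
    """The default study conditions: 200 samples, 163-gene unimodal panel,
    complementary clinical channel, cross-fitted risk."""
    cfg = GeneratorConfig(seed=1)
    clin = generate_clinical(cfg)
    expr = generate_expression(cfg, clin["label"])
    table = discretize_clinical(clin)
    risk = extract_malignancy_risk(table, k=10, seed=1, method="exact")
    y = (clin["label"] == "malignant").astype(int).to_numpy()
    return cfg, expr, table, risk.to_numpy(), y
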