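import numpy as np
import pandas as pd
import pytest

import blpanel as bl


@pytest.fixture(scope="session")
def small_panel() -> bl.PanelDefinition:
    return bl.PanelDefinition(
        target_genes=("FGFR3", "KRT5", "KRT14", "GATA3", "PPARG"),
        housekeeping_genes=("ACTB", "GAPDH"),
        pathway_tags={"FGFR3": frozenset({"FGFR-RTK-MAPK-PI3K"})},
    )


@pytest.fixture(scope="session")
def strong_cohort() -> bl.SyntheticCohort:
    """50+50 samples, 30 DE genes at effect = 2 * noise_sd: the separable
    regime in which subtype structure should be fully recoverable."""
    spec = bl.CohortSpec(n_basal=50, n_luminal=50, n_de=30, effect=2.0,
                         noise_sd=1.0, seed=20160901)
    return bl.generate_cohort(spec)


@pytest.fixture(scope="session")
def reference_cohort() -> bl.SyntheticCohort:
    """Independent labeled cohort (18 basal / 12 luminal) used to derive
    reference profiles, emulating profile transfer between datasets."""
    spec = bl.CohortSpec(n_basal=18, n_luminal=12, n_de=30, effect=2.0,
                         noise_sd=1.0, seed=777)
    return bl.generate_cohort(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def expr(values, genes=None, samples=None, scale="log2") -> bl.ExpressionMatrix:
    """Shorthand ExpressionMatrix constructor for tests."""
    a = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(a.shape[0])]
    samples = samples or [f"s{j}" for j in range(a.shape[1])]
    return bl.ExpressionMatrix(pd.DataFrame(a, index=genes, columns=samples), scale)
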