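import numpy as np
import pandas as pd
import pytest

from sigresp.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One study-sized cohort (18 patients x 2000 genes), shared read-only."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast pipeline-level tests."""
    cfg = CohortConfig(
        n_patients=8,
        n_genes=300,
        n_treatment_genes=60,
        n_gf_genes=40,
        n_causal_genes=4,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_design():
    """Balanced 3-patient 2x2 factorial design."""
    rows = []
    for p in ("A", "B", "C"):
        for treated in (False, True):
            for gf in (False, True):
                rows.append((f"{p}_{int(treated)}{int(gf)}", p, treated, gf))
    df = pd.DataFrame(rows, columns=["sample", "patient", "treated", "gf"])
    return df.set_index("sample")
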