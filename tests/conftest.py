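import numpy as np
import pandas as pd
import pytest

from caninegbv import (
    Cohort,
    MarkerDefinition,
    MarkerPanel,
    bundled_panel,
    default_config,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def panel17() -> MarkerPanel:
    return bundled_panel()


@pytest.fixture(scope="session")
def toy_panel() -> MarkerPanel:
    """Three hand-built markers with simple weights for arithmetic checks."""
    return MarkerPanel(
        (
            MarkerDefinition("M1", "A", "G", "ACGT[A]TTGC", "ACGT[G]TTGC", 1.2, 0.4),
            MarkerDefinition("M2", "T", "C", "GGAA[T]CCTT", "GGAA[C]CCTT", 0.5, 0.1),
            MarkerDefinition("M3", "C", "A", "TTGC[C]AGGA", "TTGC[A]AGGA", 0.8, 0.3),
        )
    )


@pytest.fixture()
def toy_cohort(toy_panel) -> Cohort:
    """Five animals over the toy panel, with one missing call and phenotypes 1-5."""
    geno = pd.DataFrame(
        {
            "M1": ["A/A", "A/G", "G/G", "A/A", "G/A"],
            "M2": ["T/T", "T/C", "C/C", np.nan, "T/T"],
            "M3": ["C/C", "C/A", "A/A", "C/C", "A/A"],
        },
        index=pd.Index([f"d{i}" for i in range(1, 6)], name="animal_id"),
    )
    pheno = pd.DataFrame(
        {"chd_class": [1, 2, 5, 3, 1], "ced_class": [1, 1, 4, pd.NA, 2]},
        index=geno.index,
        dtype="Int64",
    )
    return Cohort(geno, pheno, toy_panel)


@pytest.fixture(scope="session")
def null_cohort(panel17) -> Cohort:
    """Study-shaped all-null synthetic cohort (n=935, no planted effects)."""
    return simulate_cohort(default_config(seed=20170803), panel17)
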