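import numpy as np
import pandas as pd
import pytest

from gxepower import CohortSpec, GenotypeMatrix, simulate_cohort
from gxepower.grs import PANEL_RSIDS


@pytest.fixture(scope="session")
def base_cohort():
    """Moderate cohort under the default study conditions."""
    return simulate_cohort(CohortSpec(n_participants=20_000, seed=11))


@pytest.fixture()
def tiny_genotypes():
    """Five participants x 12 loci with hand-placed dosages and one NaN."""
    rng = np.random.default_rng(42)
    dosages = rng.integers(0, 3, size=(5, 12)).astype(float)
    dosages[0, 3] = np.nan
    frame = pd.DataFrame(dosages, columns=list(PANEL_RSIDS))
    return GenotypeMatrix(frame, coded_alleles={r: "A" for r in PANEL_RSIDS})
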