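import numpy as np
import pytest

from metalclique.cliques import ThresholdedClique
from metalclique.synthetic import SynthConfig, generate_cohort

#: SD of the log outcome implied by the default t-score calibration
LOG_SD = float(np.sqrt(np.log1p((8.1 / 53.0) ** 2)))

PLANTED = ThresholdedClique.parse("Zn_T2+@20 & Co_T3-@80 & Cr_T2-@55")


@pytest.fixture(scope="session")
def cohort112():
    """Default-size cohort with a little covariate missingness."""
    return generate_cohort(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def cohort_complete():
    """Complete 200-row cohort (no missingness, no planted effect)."""
    return generate_cohort(
        SynthConfig(n_participants=200, missing_rate=0.0, seed=42)
    )


@pytest.fixture(scope="session")
def cohort_planted():
    """300-row cohort with a planted clique effect in both microbe strata."""
    cfg = SynthConfig(
        n_participants=300,
        planted_clique=PLANTED,
        effect_in_absent=0.5 * LOG_SD,
        effect_in_present=0.5 * LOG_SD,
        missing_rate=0.0,
        seed=11,
    )
    return generate_cohort(cfg)
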