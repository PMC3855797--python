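import numpy as np
import pandas as pd
import pytest

from twinglyco.simulate import (
    CovariateModel,
    MethylModel,
    PlantedEffect,
    SimulationConfig,
    TraitSpec,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60+60-pair cohort with known structure, shared across tests."""
    cfg = SimulationConfig(
        n_mz=60,
        n_dz=60,
        seed=12345,
        trait_specs=(
            TraitSpec("high_a", 0.8, 0.0, 0.2),
            TraitSpec("mid_ace", 0.45, 0.29, 0.26),
            TraitSpec("shared_env", 0.0, 0.6, 0.4),
            TraitSpec("noise", 0.0, 0.0, 1.0),
        ),
        methyl_model=MethylModel(
            n_probes=40,
            family_var=0.2,
            planted=(PlantedEffect("cg00000007", "noise", 0.5),),
        ),
        covariate_model=CovariateModel(age_beta=0.02, batch_sd=0.15),
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def peak_row():
    """A single hand-constructed 24-peak raw profile (sums to 100)."""
    values = {f"GP{i}": 0.0 for i in range(1, 25)}
    # neutral block: GP4 (F) 6.0, GP6 (FB) 1.5, GP13 (B) 0.05
    values.update({"GP4": 6.0, "GP6": 1.5, "GP13": 0.05})
    # sialylated block: FBS2=GP24 2.0, FS2=GP23 4.0, remainder on GP21
    values.update({"GP24": 2.0, "GP23": 4.0})
    values["GP21"] = 100.0 - sum(values.values())
    return pd.DataFrame([values], index=pd.Index(["s1"], name="sample_id"))
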