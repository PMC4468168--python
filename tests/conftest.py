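import numpy as np
import pandas as pd
import pytest

from thermotol.synthetic import GroupSpec, ViabilityCurveSpec, generate_viability_data


@pytest.fixture
def rng():
    return np.random.default_rng(20131217)


@pytest.fixture
def cold_ramp_specs():
    """Female cold-ramp groups at the published medians (lab25 vs field)."""
    return [
        GroupSpec("lab25", "female", "cold_ramp", target_median=6.19,
                  spread=1.3, skew=0.8, n=25),
        GroupSpec("field", "female", "cold_ramp", target_median=0.62,
                  spread=0.9, skew=0.8, n=25),
    ]


@pytest.fixture
def small_viability_fixture():
    """40-vial two-treatment fixture with overdispersion (deterministic)."""
    specs = [
        ViabilityCurveSpec("field", (1.0, -0.8, -1.5, -0.3),
                           overdispersion_rho=0.1, vials_per_temp=2),
        ViabilityCurveSpec("lab25", (1.6, -0.2, -1.8, -0.5),
                           overdispersion_rho=0.1, vials_per_temp=2),
    ]
    return pd.concat(
        [generate_viability_data(s, seed=11 + i) for i, s in enumerate(specs)],
        ignore_index=True,
    )
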