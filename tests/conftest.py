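from dataclasses import replace

import pytest
from hypothesis import HealthCheck, settings

from sglt2mbma.parameters import default_truth

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth():
    """Published fixed-effect estimates as simulation truth."""
    return default_truth()


@pytest.fixture(scope="session")
def noiseless_truth(truth):
    """Same truth with all residual variances and inter-study effects off."""
    pk = {name: replace(p, sigma2_prop=0.0, sigma2_add=0.0, iiv={})
          for name, p in truth.pk.items()}
    biomarker = replace(truth.biomarker, sigma2_prop=0.0, sigma2_add=0.0,
                        iiv={})
    endpoints = replace(truth.endpoints, sigma2_fpg=0.0, sigma2_hba1c=0.0,
                        iiv={})
    return replace(truth, pk=pk, biomarker=biomarker, endpoints=endpoints)
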