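import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from nichespace.comparison import combined_space  # noqa: E402
from nichespace.simulate import generate_community  # noqa: E402

#: single fixed seed used by every fixture-level simulation
SEED = 1


@pytest.fixture(scope="session")
def community():
    """Default synthetic four-biome community (215 species rows)."""
    return generate_community(seed=SEED)


@pytest.fixture(scope="session")
def pooled_analysis(community):
    """(per-dimension PcaResults, pooled NicheSpace) of the default community."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return combined_space(community.per_biome_tables())
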