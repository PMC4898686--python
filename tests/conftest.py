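import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Published per-class extents (ha): all forest and unprotected forest.
ALL_FOREST_EXTENTS = {1: 26_000, 2: 26_308, 3: 91_012, 4: 53_621, 5: 40_103, 6: 14_472}
UNPROTECTED_EXTENTS = {1: 4_249, 2: 3_989, 3: 15_387, 4: 3_851, 5: 1_841, 6: 856}


def strata_from_extents(extents, suitability="full_stand", tenure="native_title"):
    return pd.DataFrame(
        [
            {
                "stratum_id": f"c{c}",
                "extent_ha": e,
                "carbon_class": c,
                "suitability": suitability,
                "tenure": tenure,
            }
            for c, e in sorted(extents.items())
        ]
    )


@pytest.fixture
def unprotected_strata():
    return strata_from_extents(UNPROTECTED_EXTENTS)


@pytest.fixture
def all_forest_strata():
    return strata_from_extents(ALL_FOREST_EXTENTS)
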