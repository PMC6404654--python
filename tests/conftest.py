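import itertools

import pytest
from hypothesis import HealthCheck, settings

from poolmelt import DegeneratePrimer

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# Earth Microbiome Project V4 primers (Parada 515F / Apprill 806R)
SEQ_515F = "GTGYCAGCMGCCGCGGTAA"
SEQ_806R = "GGACTACNVGGGTWTCTAAT"


@pytest.fixture
def primer_515f():
    return DegeneratePrimer(name="515F", iupac_sequence=SEQ_515F, orientation="forward")


@pytest.fixture
def primer_806r():
    return DegeneratePrimer(name="806R", iupac_sequence=SEQ_806R, orientation="reverse")


def brute_force_smallest_range(lists):
    """Exhaustive minimum of max-min over one-per-list selections."""
    return min(
        max(combo) - min(combo) for combo in itertools.product(*lists)
    )
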