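import pytest
from hypothesis import HealthCheck, settings

from tetrarms.fixtures import (
    ASSAY_ANNEALING_C,
    build_template,
    published_assays,
)
from tetrarms.model import PcrPolicy

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def assays():
    return {a.locus_id: a for a in published_assays()}


@pytest.fixture(scope="session")
def policies():
    return {
        locus: PcrPolicy(annealing_temp_c=temp)
        for locus, temp in ASSAY_ANNEALING_C.items()
    }


@pytest.fixture(scope="session")
def templates():
    """Diploid fixture templates for all species presets (seed 42)."""
    return {
        sp: build_template(sp, seed=42)
        for sp in ("sika", "red", "hybrid", "reindeer")
    }
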