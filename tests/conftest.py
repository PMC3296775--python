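import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cnadiff as cd

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def uniform_panel():
    """Two chromosomes, strict 1 kbp spacing, no jitter: 1000 + 2000 probes."""
    model = cd.GenomeModel(
        chromosomes=(("chr1", 1_000_000), ("chr2", 2_000_000)),
        probe_spacing=1_000.0,
        spacing_jitter=0.0,
    )
    return cd.build_probe_panel(model, seed=0)


@pytest.fixture(scope="session")
def jittered_panel():
    model = cd.GenomeModel(
        chromosomes=(("chr1", 1_500_000), ("chr2", 1_000_000)),
        probe_spacing=1_000.0,
        spacing_jitter=0.5,
    )
    return cd.build_probe_panel(model, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact simulated cohort reused by the heavier integration tests."""
    model = cd.GenomeModel(
        chromosomes=(("chr1", 12_000_000), ("chr2", 12_000_000)),
        probe_spacing=10_000.0,
        spacing_jitter=0.2,
    )
    panel = cd.build_probe_panel(model, seed=3)
    event = cd.InjectedEvent(
        chrom="chr1", start=3_000_000, end=6_000_000,
        etype="gain", freq_group_a=0.8, freq_group_b=0.1,
    )
    spec = cd.default_cohort_spec(
        events=[event], seed=42, n_group_a=16, n_group_b=20, background_event_rate=3.0,
        background_length_range=(500_000, 3_000_000),
    )
    return cd.simulate_cohort(spec, panel), event
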