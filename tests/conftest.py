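import numpy as np
import pytest

from lungdx import fixtures
from lungdx.fusion import (
    CallerThresholds,
    CountProfile,
    Probe,
    ProbeSet,
    default_probe_set,
)
from lungdx.simulate import generate_nanostring_batch
from lungdx.variants import default_panel, load_rules


@pytest.fixture(scope="session")
def probe_set() -> ProbeSet:
    return default_probe_set()


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def rules(panel):
    return load_rules(panel=panel)


@pytest.fixture(scope="session")
def thresholds() -> CallerThresholds:
    return CallerThresholds()


@pytest.fixture(scope="session")
def prospective_batch():
    """The 169-profile batch emulating the prospective fusion-assay run."""
    return generate_nanostring_batch(fixtures.prospective_batch_spec(seed=11))


@pytest.fixture(scope="session")
def mini_probe_set() -> ProbeSet:
    """A hand-sized design for arithmetic-oracle tests: one gene, tiny."""
    return ProbeSet(
        [
            Probe("G5a", "five_prime", gene="ALK"),
            Probe("G5b", "five_prime", gene="ALK"),
            Probe("G3a", "three_prime", gene="ALK"),
            Probe("G3b", "three_prime", gene="ALK"),
            Probe("FSa", "fusion_specific", gene="ALK", fusion_id="AA-ALK_1:2"),
            Probe("FSb", "fusion_specific", gene="ALK", fusion_id="BB-ALK_3:4"),
            Probe("HK1", "housekeeping"),
            Probe("HK2", "housekeeping"),
            Probe("P1", "pos_control", nominal_amount=100.0),
            Probe("P2", "pos_control", nominal_amount=400.0),
            Probe("N1", "neg_control"),
            Probe("N2", "neg_control"),
            Probe("N3", "neg_control"),
        ]
    )


def make_profile(mini_probe_set: ProbeSet, **overrides) -> CountProfile:
    """Baseline profile on the mini design; override any probe count."""
    counts = {
        "G5a": 50.0, "G5b": 50.0, "G3a": 50.0, "G3b": 50.0,
        "FSa": 0.0, "FSb": 0.0,
        "HK1": 1000.0, "HK2": 1000.0,
        "P1": 100.0, "P2": 400.0,
        "N1": 10.0, "N2": 10.0, "N3": 10.0,
    }
    counts.update(overrides)
    return CountProfile(sample_id="T1", counts=counts)


@pytest.fixture()
def base_profile(mini_probe_set) -> CountProfile:
    return make_profile(mini_probe_set)
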