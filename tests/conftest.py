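import numpy as np
import pytest

from trnatempo import (
    CodonFractions,
    NormalizedRatios,
    Probe,
    ProbePanel,
    default_panel,
)
from trnatempo.genetic_code import SENSE_CODONS


@pytest.fixture(scope="session")
def panel() -> ProbePanel:
    """The default synthetic human-like panel (41 tRNA probes + 3 spikes)."""
    return default_panel()


@pytest.fixture(scope="session")
def tiny_panel() -> ProbePanel:
    """Three tRNA probes and two spikes; enough structure for unit tests."""
    return ProbePanel(
        (
            Probe("t1", ("AGU",), "T", ("ACU", "ACC")),
            Probe("t2", ("CGU",), "T", ("ACG",)),
            Probe("t3", ("UUU",), "K", ("AAA",)),
            Probe("spike_1", is_spike=True),
            Probe("spike_2", is_spike=True),
        )
    )


def make_ratios(values: dict[str, float], model="m", rep=1) -> NormalizedRatios:
    return NormalizedRatios(model_id=model, bio_replicate=rep, ratio=dict(values))


def uniformish_codon_fractions(model_id="m", overrides=None, ambiguous=()):
    """A full 61-codon fraction table, uniform except for explicit overrides."""
    per = {c: 1.0 / 61.0 for c in SENSE_CODONS}
    per.update(overrides or {})
    total = sum(per.values())
    return CodonFractions(
        model_id=model_id,
        per_codon={c: v / total for c, v in per.items()},
        ambiguous_codons=frozenset(ambiguous),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
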