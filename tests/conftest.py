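import numpy as np
import pytest

from sifneuron import (
    ProtocolConfig,
    SpikeTrainSet,
    default_sif_spec,
    make_cfbp,
    make_lif,
)


@pytest.fixture
def sif_spec():
    """Two saturating groups, sources {1,2}->group 1, {3,4}->group 2."""
    return default_sif_spec()


@pytest.fixture
def lif_spec(sif_spec):
    return make_lif(sif_spec)


@pytest.fixture
def cfbp():
    return make_cfbp(2)


@pytest.fixture
def spike_config(cfbp):
    return ProtocolConfig(table=cfbp, mode="spike", seed=0)


@pytest.fixture
def rate_config(cfbp):
    return ProtocolConfig(table=cfbp, mode="rate", seed=0)


def trains_from(mapping: dict, horizon_ms: float = 50.0) -> SpikeTrainSet:
    return SpikeTrainSet(
        trains={s: np.asarray(t, dtype=float) for s, t in mapping.items()},
        horizon_ms=horizon_ms,
    )
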