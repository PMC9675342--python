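import numpy as np
import pytest

from playseq.io_model import (
    Ethogram,
    EthogramElement,
    IndividualBout,
    PipelineConfig,
    Step,
)


def make_ethogram(names, states=(), lumps=None):
    lumps = lumps or {}
    return Ethogram(
        tuple(
            EthogramElement(
                name=n,
                kind="state" if n in states else "event",
                is_continuous_state=n in states,
                lump_target=lumps.get(n),
            )
            for n in names
        )
    )


def make_bout(token_steps, bout_id="b1", player_id="p1"):
    """Build a bout from a list of steps: each a set of tokens or 'BREAK'/'MISSING'."""
    steps = []
    for t, item in enumerate(token_steps, start=1):
        if isinstance(item, str):
            steps.append(Step(onset_s=float(t), marker=item))
        else:
            steps.append(Step(onset_s=float(t), active=frozenset(item)))
    return IndividualBout(bout_id, player_id, tuple(steps))


@pytest.fixture
def abc_ethogram():
    return make_ethogram(["A", "B", "C"])


@pytest.fixture
def small_config():
    return PipelineConfig(
        lump_min_count=1,
        n_linearizations=20,
        n_permutations=200,
        n_bootstrap=100,
        kfold_reps=10,
        n_embedding_runs=3,
        mean_epochs=300,
        n_label_perms=100,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
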