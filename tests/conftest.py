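import io

import numpy as np
import pytest

from psfopt import load_default_model, load_model, make_signal_set


def model_from_text(reactions: str, concs: str, **kwargs):
    """Build a model from inline TSV text (exercises the real parser)."""
    return load_model(io.StringIO(reactions), io.StringIO(concs), **kwargs)


@pytest.fixture(scope="session")
def default_model():
    return load_default_model()


@pytest.fixture(scope="session")
def small_signals():
    """Cheap 2-baseline ensemble for unit tests of the evaluation pipeline."""
    return make_signal_set(10, 100, folds=(1.5,), n_baselines=2)


@pytest.fixture()
def toy_binding():
    """A + B <-> C with Kd = koff/kon = 333.33 nM; A is the clamped input."""
    return model_from_text(
        "reaction_string\tkon\tkoff\tkcat\n"
        "A + B <-> C\t0.0003\t0.1\t\n",
        "species\tconc0_nM\nB\t100\n",
        input_species="A",
        output_species="C",
    )


@pytest.fixture()
def toy_conversion():
    """First-order decay A -> B with kcat = 0.1 /s."""
    return model_from_text(
        "reaction_string\tkon\tkoff\tkcat\n"
        "A -> B\t\t\t0.1\n",
        "species\tconc0_nM\nA\t100\n",
        input_species="L",  # no clamped input present
        output_species="B",
    )
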