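import numpy as np
import pytest

import mcdm_survey as ms
from mcdm_survey.protocol import InputVariable, ProtocolConfig, VariableCategory
from mcdm_survey.synthetic import GeneratorSpec, generate_survey


@pytest.fixture(scope="session")
def protocol():
    return ms.default_protocol()


@pytest.fixture(scope="session")
def small_protocol():
    """A 3-category, 8-variable, 2-stage protocol for fast pipeline tests."""
    cats = (
        VariableCategory(
            code="A",
            label="alpha",
            variables=(
                InputVariable("a1", "A", 1),
                InputVariable("a2", "A", 1),
                InputVariable("a3", "A", 2),
            ),
        ),
        VariableCategory(
            code="B",
            label="beta",
            variables=(InputVariable("b1", "B", 1), InputVariable("b2", "B", 2)),
        ),
        VariableCategory(
            code="C",
            label="gamma",
            variables=(
                InputVariable("c1", "C", 1),
                InputVariable("c2", "C", 2),
                InputVariable("c3", "C", 2),
            ),
        ),
    )
    return ProtocolConfig(categories=cats, n_stages=2)


@pytest.fixture(scope="session")
def small_bundle(small_protocol):
    spec = GeneratorSpec(protocol=small_protocol, n_modelers=4, seed=7)
    return generate_survey(spec)


def random_pcm(rng: np.random.Generator, n: int, sigma: float = 0.0):
    """A random reciprocal comparison matrix from Dirichlet latent weights."""
    from mcdm_survey.synthetic import generate_pcm, _compress_ratio

    w = _compress_ratio(rng.dirichlet(np.full(n, 3.0)))
    return generate_pcm(w, sigma, rng)
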