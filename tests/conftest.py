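import numpy as np
import pytest

from profci.fixtures import toy_problems


@pytest.fixture(scope="session")
def problems():
    return toy_problems()


@pytest.fixture()
def quadratic(problems):
    return problems["readme_quadratic"]


@pytest.fixture()
def booth_problem(problems):
    return problems["booth"]


@pytest.fixture()
def rosenbrock_problem(problems):
    return problems["rosenbrock"]
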