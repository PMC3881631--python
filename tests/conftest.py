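import numpy as np
import pytest

from fermdoe import datasets


@pytest.fixture(scope="session")
def taguchi_table():
    return datasets.load_taguchi_pgase()


@pytest.fixture(scope="session")
def ccd_table():
    return datasets.load_ccd_pgase()


@pytest.fixture(scope="session")
def pectin_table():
    return datasets.load_ccd_pectin()


@pytest.fixture(scope="session")
def eq6_model():
    return datasets.load_model("eq6")


@pytest.fixture(scope="session")
def eq7_yield_model():
    return datasets.load_model("eq7_yield")


def random_quadratic(seed, k=4, concave=False, symbols=None):
    """Seeded random quadratic model; optionally strictly concave."""
    from fermdoe.rsm import QuadraticModel

    rng = np.random.default_rng(seed)
    lin = rng.normal(0, 1, k)
    if concave:
        A = rng.normal(0, 0.5, (k, k))
        B = -(A @ A.T + 0.3 * np.eye(k))  # negative definite
    else:
        A = rng.normal(0, 0.5, (k, k))
        B = (A + A.T) / 2.0
    quad = np.diag(B).copy()
    inter = np.array([2.0 * B[i, j] for i in range(k) for j in range(i + 1, k)])
    syms = symbols or [f"x{i+1}" for i in range(k)]
    return QuadraticModel(syms, float(rng.normal(20, 2)), lin, quad, inter, alpha=2.0)
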