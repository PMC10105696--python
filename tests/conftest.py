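import numpy as np
import pytest

from molargm import default_role_layout, make_template


@pytest.fixture(scope="session")
def template():
    """Default 75-point molar-like template (9 fixed + 66 semilandmarks)."""
    return make_template(seed=0)


@pytest.fixture(scope="session")
def small_template():
    """Toy 8-point closed outline (4 fixed + 4 semilandmarks)."""
    return make_template(n_fixed=4, n_semi=4, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def square():
    return np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


def random_rotation(rng):
    th = rng.uniform(0, 2 * np.pi)
    return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])


@pytest.fixture()
def metadata_row():
    def _row(**overrides):
        base = dict(
            specimen_id="x", tooth="m1", wear_class=2, subspecies="tarandus",
            status="domestic", sex="F", population="Etelä-Lappi", provenance="modern",
        )
        base.update(overrides)
        return base

    return _row


@pytest.fixture(scope="session")
def toy_roles():
    return default_role_layout(n_fixed=4, n_semi=4)
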