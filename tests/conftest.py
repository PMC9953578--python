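import numpy as np
import pandas as pd
import pytest

from resurvey.records import FilterRules, SpeciesRegistry


@pytest.fixture
def registry():
    return SpeciesRegistry(
        canonical=frozenset(
            {"B. alpinus", "B. monticola", "B. pratorum", "B. hortorum",
             "B. lucorum/cryptarum complex", "B. mesomelas", "B. campestris"}
        ),
        synonyms={"B. pratorum var. alpicola": "B. pratorum"},
        complexes={
            "B. lucorum": "B. lucorum/cryptarum complex",
            "B. cryptarum": "B. lucorum/cryptarum complex",
        },
        parasites=frozenset({"B. campestris"}),
        drop=frozenset({"B. sp."}),
    )


@pytest.fixture
def rules():
    return FilterRules(
        excluded_species={"1935/1936": ("B. mesomelas", "B. campestris")}
    )


def make_record(**kw):
    base = dict(
        species="B. alpinus", count=1, site="KBT", year=1935, month=7,
        day=15, elev_low=1900.0, elev_high=2000.0,
    )
    base.update(kw)
    return base


@pytest.fixture
def record_factory():
    return make_record


def random_incidence(rng, n_units=8, n_species=12, p=0.4):
    """Random binary matrix guaranteed to have no empty row or column."""
    while True:
        m = (rng.random((n_units, n_species)) < p).astype(int)
        if m.sum(axis=0).all() and m.sum(axis=1).all():
            return pd.DataFrame(
                m,
                index=[f"u{i}" for i in range(n_units)],
                columns=[f"s{j}" for j in range(n_species)],
            )


@pytest.fixture
def random_incidence_factory():
    return random_incidence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
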