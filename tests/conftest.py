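import numpy as np
import pytest

from thermoflux.model import MetabolicModel, Metabolite, Reaction
from thermoflux.synthetic import build_core_network


@pytest.fixture(scope="session")
def core_model():
    return build_core_network()


@pytest.fixture()
def chain_model():
    """uptake(<=10) -> A -> B -> export."""
    m = MetabolicModel(
        id="chain",
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("R_in", {"A": -1.0}, reversible=True,
                     lower_bound=-10.0, upper_bound=0.0, subsystem="exchange"),
            Reaction("R_ab", {"A": -1.0, "B": 1.0}),
            Reaction("R_out", {"B": -1.0}, subsystem="exchange"),
        ],
        objective_id="R_out",
    )
    m.validate()
    return m


def make_model(mets, rxns, objective=None):
    """Terse helper: rxns as (id, stoich, reversible, lb, ub)."""
    model = MetabolicModel(
        metabolites=[Metabolite(x) for x in mets],
        reactions=[
            Reaction(rid, st, reversible=rev, lower_bound=lb, upper_bound=ub)
            for rid, st, rev, lb, ub in rxns
        ],
        objective_id=objective,
    )
    model.validate()
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(20160906)
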