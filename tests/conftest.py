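from __future__ import annotations

import numpy as np
import pytest
from cobra import Metabolite, Model, Reaction

from debranch.constraints import cs5_preset
from debranch.synth import TOY_CS5_ALIASES, ToySpec, make_toy_model, make_wild_type


def build_model(reactions: dict[str, tuple[dict[str, float], float, float]],
                objective: str | None = None,
                formulas: dict[str, str] | None = None) -> Model:
    """Compact model builder: {rxn_id: (stoich {met: coeff}, lb, ub)}."""
    model = Model("test")
    mets: dict[str, Metabolite] = {}
    formulas = formulas or {}
    for rid, (stoich, lb, ub) in reactions.items():
        rxn = Reaction(rid, lower_bound=lb, upper_bound=ub)
        rxn.add_metabolites(
            {
                mets.setdefault(
                    mid,
                    Metabolite(mid, compartment=mid.rsplit("_", 1)[-1],
                               formula=formulas.get(mid)),
                ): coeff
                for mid, coeff in stoich.items()
            }
        )
        model.add_reactions([rxn])
    if objective:
        model.objective = objective
    return model


@pytest.fixture(scope="session")
def toy():
    """Full engineered toy model + ground truth (session-shared, copy to mutate)."""
    return make_toy_model(ToySpec())


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def ground_truth(toy):
    return toy[1]


@pytest.fixture(scope="session")
def wt_model():
    return make_wild_type(ToySpec())


@pytest.fixture(scope="session")
def cs5(toy_model):
    return cs5_preset(toy_model, aliases=TOY_CS5_ALIASES)


@pytest.fixture()
def chain_model():
    """EX_A (ub 10) -> A -> B -> EX_B; the uptake bound is the bottleneck."""
    return build_model(
        {
            "EX_A": ({"a_c": 1}, 0, 10),
            "AB": ({"a_c": -1, "b_c": 1}, 0, 1000),
            "EX_B": ({"b_c": -1}, 0, 1000),
        },
        objective="EX_B",
    )


@pytest.fixture()
def two_path_model():
    """Two symmetric parallel routes feeding one fixed demand of 10."""
    return build_model(
        {
            "SRC": ({"a_c": 1}, 0, 1000),
            "P1": ({"a_c": -1, "b_c": 1}, 0, 10),
            "P2": ({"a_c": -1, "b_c": 1}, 0, 10),
            "DEMAND": ({"b_c": -1}, 10, 10),
        },
        objective="DEMAND",
    )


def as_matrices(model: Model):
    """(S, lb, ub, reaction ids) arrays for oracle code."""
    from cobra.util.array import create_stoichiometric_matrix

    S = create_stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    ids = [r.id for r in model.reactions]
    return S, lb, ub, ids
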