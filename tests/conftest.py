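import pytest

from ecgem.gecko import apply_enzyme_constraints
from ecgem.model import MetabolicModel, Metabolite, Reaction
from ecgem.synth import ToySpec, make_toy_model


@pytest.fixture(scope="session")
def toy():
    """Default synthetic central-carbon fixture (model + analytic truth)."""
    return make_toy_model(ToySpec())


@pytest.fixture(scope="session")
def toy_ec(toy):
    """Enzyme-constrained toy with released glucose uptake."""
    return apply_enzyme_constraints(
        toy.model, toy.enzyme_entries, release_uptake="EX_glc_e"
    )


@pytest.fixture()
def chain_model():
    """uptake(<=5) -> a -> b -> biomass: a fully determined linear pathway."""
    return MetabolicModel(
        metabolites=[Metabolite("a"), Metabolite("b")],
        reactions=[
            Reaction("UPT", {"a": 1}, 0, 5),
            Reaction("CONV", {"a": -1, "b": 1}, 0, 1000),
            Reaction("BIO", {"b": -1}, 0, 1000),
        ],
        objective_reaction_id="BIO",
        id="chain",
    )


@pytest.fixture()
def parallel_model():
    """Two parallel routes of capacity 4 each, total demand 4."""
    return MetabolicModel(
        metabolites=[Metabolite("a"), Metabolite("b")],
        reactions=[
            Reaction("UPT", {"a": 1}, 0, 4),
            Reaction("R1", {"a": -1, "b": 1}, 0, 4),
            Reaction("R2", {"a": -1, "b": 1}, 0, 4),
            Reaction("BIO", {"b": -1}, 0, 1000),
        ],
        objective_reaction_id="BIO",
        id="parallel",
    )


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model for use as an independent LP oracle."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(m.id, compartment=m.compartment or "c")
        for m in model.metabolites
    }
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r, cr in zip(model.reactions, rxns):
        cr.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
        if r.gene_rule:
            cr.gene_reaction_rule = r.gene_rule
    cm.objective = model.objective_reaction_id
    return cm
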