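"""In silico strain design: product pathway insertion and MoMA deletion
scanning for γ-PGA (or any target reaction) overproduction.

γ-PGA (poly-γ-glutamic acid) is modeled as a single synthesis reaction
consuming 0.77 D-glutamate + 0.23 L-glutamate per polymer unit, plus a
secretion exchange; its precursors (2-oxoglutarate, D-/L-glutamate) can be
targeted directly by adding secretion exchanges for them.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .model import FluxSolution, MetabolicModel, Reaction, knockout
from .simulation import moma

__all__ = [
    "PGA_STOICHIOMETRY",
    "add_pga_pathway",
    "add_precursor_secretion",
    "DeletionDesign",
    "DesignScan",
    "scan_deletions",
]

#: glutamate consumed per γ-PGA polymer unit (D- and L- enantiomers)
PGA_STOICHIOMETRY = {"glu_d": 0.77, "glu_l": 0.23}


def add_pga_pathway(
    model: MetabolicModel,
    glu_d_id: str = "glu_d",
    glu_l_id: str = "glu_l",
    pga_id: str = "pga",
    reaction_id: str = "PGAS",
    exchange_id: str = "EX_pga_e",
) -> MetabolicModel:
    """Return a copy with the γ-PGA synthesis reaction and secretion exchange.

    Synthesis: 0.77 glu-D + 0.23 glu-L → pga.  Idempotent: calling twice
    leaves a single pathway copy.
    """
    for mid, role in ((glu_d_id, "D-glutamate"), (glu_l_id, "L-glutamate")):
        if not model.has_metabolite(mid):
            raise KeyError(f"missing precursor metabolite {mid!r} ({role})")
    out = model.copy()
    if out.has_reaction(reaction_id):
        return out
    from .model import Metabolite

    if not out.has_metabolite(pga_id):
        out.metabolites.append(Metabolite(pga_id, name="poly-gamma-glutamate unit", compartment="c"))
    out.reactions.append(
        Reaction(
            id=reaction_id,
            stoichiometry={glu_d_id: -0.77, glu_l_id: -0.23, pga_id: 1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            subsystem="gamma-PGA biosynthesis",
            name="poly-gamma-glutamate synthase",
        )
    )
    out.reactions.append(
        Reaction(
            id=exchange_id,
            stoichiometry={pga_id: -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            subsystem="Exchange",
            name="gamma-PGA secretion",
        )
    )
    out.validate()
    return out


def add_precursor_secretion(model: MetabolicModel, metabolite_id: str) -> MetabolicModel:
    """Return a copy with an irreversible secretion exchange for a γ-PGA
    precursor (akg / glu-L / glu-D).  Idempotent."""
    if not model.has_metabolite(metabolite_id):
        raise KeyError(f"unknown metabolite {metabolite_id!r}")
    exch_id = f"EX_{metabolite_id}_e"
    out = model.copy()
    if out.has_reaction(exch_id):
        return out
    out.reactions.append(
        Reaction(
            id=exch_id,
            stoichiometry={metabolite_id: -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            subsystem="Exchange",
            name=f"{metabolite_id} secretion",
        )
    )
    out.validate()
    return out


@dataclass
class DeletionDesign:
    deleted: tuple[str, ...]
    predicted_growth: float
    predicted_target_flux: float
    distance: float
    rank: int | None = None


@dataclass
class DesignScan:
    designs: list[DeletionDesign]
    target_reaction: str
    viability_floor: float  # absolute growth floor used for ranking

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "deleted_ids": "+".join(d.deleted),
                    "growth": d.predicted_growth,
                    "target_flux": d.predicted_target_flux,
                    "rank": d.rank,
                }
                for d in self.designs
            ]
        )

    @property
    def ranked(self) -> list[DeletionDesign]:
        return sorted(
            (d for d in self.designs if d.rank is not None), key=lambda d: d.rank
        )

    @property
    def pareto_front(self) -> list[DeletionDesign]:
        """Designs not dominated in (growth, target flux)."""
        front = []
        for d in self.designs:
            dominated = any(
                (o.predicted_growth >= d.predicted_growth
                 and o.predicted_target_flux >= d.predicted_target_flux
                 and (o.predicted_growth > d.predicted_growth
                      or o.predicted_target_flux > d.predicted_target_flux))
                for o in self.designs
            )
            if not dominated:
                front.append(d)
        return sorted(front, key=lambda d: -d.predicted_target_flux)

    def to_tsv(self, path: str) -> None:
        self.frame().to_csv(path, sep="\t", index=False)


def default_candidates(model: MetabolicModel, reference: FluxSolution) -> list[str]:
    """Reactions carrying flux in the wild-type reference, minus exchanges,
    biomass and the added product reactions.

    Works in the net-flux namespace, so split reversible pairs of an
    irreversible (enzyme-constrained) model count as single candidates.
    """
    from .model import IRREVERSIBLE_MAP

    irrev = model.annotations.get(IRREVERSIBLE_MAP, {})
    objective_net = {model.objective_reaction_id}
    for orig, halves in irrev.items():
        if model.objective_reaction_id in (halves["forward"], halves["reverse"]):
            objective_net.add(orig)
    out = []
    for rid, v in reference.fluxes.items():
        if abs(v) <= 1e-9 or rid in objective_net:
            continue
        if model.has_reaction(rid):
            rxn = model.get_reaction(rid)
        elif rid in irrev:
            half = irrev[rid]["forward"] or irrev[rid]["reverse"]
            rxn = model.get_reaction(half)
        else:
            continue
        if rxn.boundary or rxn.subsystem in (
            "Exchange", "gamma-PGA biosynthesis", "Enzyme usage",
        ):
            continue
        out.append(rid)
    return sorted(out)


def scan_deletions(
    model: MetabolicModel,
    target_reaction: str,
    reference: FluxSolution,
    max_size: int = 1,
    candidates: list[str] | None = None,
    viability_fraction: float = 0.1,
) -> DesignScan:
    """Scan single (or double) reaction deletions that maximize target flux.

    Every candidate deletion set is simulated by MoMA against the wild-type
    reference of the same model.  The "best trade-off" ranking keeps designs
    whose predicted growth stays at or above ``viability_fraction`` of the
    reference growth, sorted by target flux (ties: higher growth, then id);
    all simulated designs, including non-viable ones, are retained so the full
    growth/production Pareto front can be inspected.
    """
    if max_size not in (1, 2):
        raise ValueError("max_size must be 1 or 2")
    netspace = set(reference.fluxes)
    if target_reaction not in netspace and not model.has_reaction(target_reaction):
        raise KeyError(f"target reaction {target_reaction!r} not in model")
    if candidates is None:
        candidates = default_candidates(model, reference)
    if not candidates:
        raise ValueError("empty candidate set")
    sets: list[tuple[str, ...]] = [(c,) for c in candidates]
    if max_size == 2:
        sets += [tuple(sorted(pair)) for pair in combinations(candidates, 2)]

    wt_growth = reference.objective_value
    floor = viability_fraction * wt_growth
    designs = []
    for dset in sets:
        mutant = knockout(model, set(dset))
        sol = moma(mutant, reference)
        if sol.status != "optimal":
            continue  # infeasible mutants are excluded entirely
        growth = max(0.0, sol.objective_value)
        designs.append(
            DeletionDesign(
                deleted=dset,
                predicted_growth=growth,
                predicted_target_flux=sol.fluxes.get(target_reaction, 0.0),
                distance=sol.meta.get("distance", float("nan")),
            )
        )
    viable = [d for d in designs if d.predicted_growth >= floor]
    viable.sort(key=lambda d: (-d.predicted_target_flux, -d.predicted_growth, d.deleted))
    for i, d in enumerate(viable):
        d.rank = i + 1
    return DesignScan(designs, target_reaction, floor)
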