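"""Build enzyme-constrained models.

Two constraint formulations are provided, both acting on the irreversible form
of the input model:

* :func:`apply_enzyme_constraints` — per-reaction capacity caps: each
  constrained reaction consumes a ``prot_<gene>`` pseudo-metabolite with
  coefficient 1/kcat (kcat in h⁻¹), supplied by a ``usage_<gene>`` variable
  bounded by the measured enzyme abundance, enforcing
  v ≤ kcat × 3600 × [E]  (mmol/gDW/h).
* :func:`apply_pool_constraint` — a MOMENT-like variant in which individual
  usage variables are unbounded but their total mass Σ MWᵢ·eᵢ may not exceed
  f × P_total (g/gDW).

Because the carbon-source uptake becomes limited by enzyme capacity rather
than by a measured uptake rate, the glucose uptake bound is released (to −100
mmol/gDW/h by default) when building either variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .enzymes import EnzymeEntry
from .model import (
    IRREVERSIBLE_MAP,
    USAGE_REACTIONS,
    MetabolicModel,
    Metabolite,
    Reaction,
    convert_to_irreversible,
)

__all__ = [
    "ECModel",
    "apply_enzyme_constraints",
    "apply_pool_constraint",
    "enzymatic_cap",
    "DEFAULT_P_TOTAL",
    "DEFAULT_MASS_FRACTION",
    "DEFAULT_UPTAKE_RELEASE",
]

#: total cellular protein content assumed for the pool constraint (g/gDW)
DEFAULT_P_TOTAL = 0.55
#: mass fraction of the constrained enzymes within total protein
DEFAULT_MASS_FRACTION = 0.0191
#: "unlimited" carbon-source uptake bound (mmol/gDW/h, uptake negative)
DEFAULT_UPTAKE_RELEASE = -100.0

SECONDS_PER_HOUR = 3600.0


def enzymatic_cap(entry: EnzymeEntry) -> float:
    """Maximum capacity v_max = kcat × 3600 × [E] in mmol/gDW/h."""
    return entry.kcat * SECONDS_PER_HOUR * entry.abundance


@dataclass
class ECModel:
    """An irreversible model augmented with enzyme pseudo-metabolites.

    ``model`` is a standard :class:`MetabolicModel` (so it serializes through
    the ordinary writers and solves with the ordinary methods); the extra
    fields record which reactions are constrained and through which usage
    variables.
    """

    model: MetabolicModel
    entries: list[EnzymeEntry]
    constrained_reactions: list[str]
    usage_variables: dict[str, str]  # constrained (split) reaction id -> usage id
    pool: dict | None = None  # {"p_total": g/gDW, "f": fraction} for the pool form
    meta: dict = field(default_factory=dict)

    @property
    def usage_reaction_ids(self) -> list[str]:
        return list(self.model.annotations.get(USAGE_REACTIONS, []))

    def caps_report(self) -> pd.DataFrame:
        """Equivalent simple-cap view: v_max per constrained reaction."""
        rows = [
            {
                "reaction_id": e.reaction_id,
                "gene": e.gene,
                "kcat_per_s": e.kcat,
                "abundance_mmol_gdw": e.abundance,
                "vmax_mmol_gdw_h": enzymatic_cap(e),
                "abundance_is_fallback": e.abundance_is_fallback,
            }
            for e in self.entries
        ]
        return pd.DataFrame(rows).set_index("reaction_id")


def _prepare_base(
    model: MetabolicModel,
    entries: list[EnzymeEntry],
    release_uptake: str | None,
    uptake_bound: float,
) -> MetabolicModel:
    seen: set[str] = set()
    for e in entries:
        if e.reaction_id in seen:
            raise ValueError(f"duplicate enzyme entries for reaction {e.reaction_id}")
        seen.add(e.reaction_id)
    base = model.copy()
    if release_uptake is not None:
        exch = base.get_reaction(release_uptake)
        exch.lower_bound = uptake_bound
    return convert_to_irreversible(base)


def _constrained_halves(irr: MetabolicModel, rid: str) -> list[tuple[str, str]]:
    """(split reaction id, usage suffix) pairs for one original reaction."""
    irrev = irr.annotations.get(IRREVERSIBLE_MAP, {})
    if rid not in irrev:
        raise KeyError(
            f"enzyme entry references reaction {rid!r} absent from the model"
        )
    halves = irrev[rid]
    out = []
    if halves["forward"] is not None:
        out.append((halves["forward"], ""))
    if halves["reverse"] is not None:
        out.append((halves["reverse"], "_r"))
    return out


def apply_enzyme_constraints(
    model: MetabolicModel,
    entries: list[EnzymeEntry],
    release_uptake: str | None = None,
    uptake_bound: float = DEFAULT_UPTAKE_RELEASE,
) -> ECModel:
    """GECKO-style per-reaction enzymatic caps.

    Each entry adds a ``prot_<gene>`` pseudo-metabolite consumed by the
    reaction with coefficient 1/(kcat·3600) and produced by a ``usage_<gene>``
    variable with upper bound [E], so flux cannot exceed kcat·3600·[E].  When
    a constrained reaction is reversible, each split direction is capped
    independently (with its own pseudo-metabolite).

    ``release_uptake`` names the carbon-source exchange whose lower bound is
    released to ``uptake_bound`` before augmentation.
    """
    irr = _prepare_base(model, entries, release_uptake, uptake_bound)
    usage_map: dict[str, str] = {}
    usage_ids: list[str] = []
    constrained: list[str] = []
    for e in entries:
        kcat_h = e.kcat * SECONDS_PER_HOUR
        for split_id, suffix in _constrained_halves(irr, e.reaction_id):
            prot_id = f"prot_{e.gene}{suffix}"
            usage_id = f"usage_{e.gene}{suffix}"
            irr.metabolites.append(
                Metabolite(id=prot_id, name=f"enzyme usage pseudo-metabolite ({e.gene})",
                           compartment="c")
            )
            irr.reactions.append(
                Reaction(
                    id=usage_id,
                    stoichiometry={prot_id: 1.0},
                    lower_bound=0.0,
                    upper_bound=e.abundance,
                    subsystem="Enzyme usage",
                    name=f"usage of {e.gene}",
                )
            )
            rxn = irr.get_reaction(split_id)
            rxn.stoichiometry[prot_id] = -1.0 / kcat_h
            usage_map[split_id] = usage_id
            usage_ids.append(usage_id)
            constrained.append(split_id)
    irr.annotations[USAGE_REACTIONS] = usage_ids
    irr.annotations["enzyme_constrained"] = constrained
    irr.id = f"ec_{model.id}"
    irr.validate()
    return ECModel(irr, list(entries), constrained, usage_map, pool=None)


POOL_METABOLITE = "prot_pool"
POOL_SUPPLY = "prot_pool_exchange"


def apply_pool_constraint(
    model: MetabolicModel,
    entries: list[EnzymeEntry],
    p_total: float = DEFAULT_P_TOTAL,
    f: float = DEFAULT_MASS_FRACTION,
    release_uptake: str | None = None,
    uptake_bound: float = DEFAULT_UPTAKE_RELEASE,
) -> ECModel:
    """MOMENT-like total-pool constraint: Σᵢ MWᵢ·eᵢ ≤ f·P_total.

    Per-reaction coupling vᵢ ≤ kcatᵢ·eᵢ is kept through the pseudo-metabolite
    stoichiometry, but the individual usage bounds are released; only the
    total enzyme mass drawn from the shared ``prot_pool`` (g/gDW) is limited.
    """
    if p_total <= 0 or f <= 0:
        raise ValueError("p_total and f must be positive")
    for e in entries:
        if e.mw is None:
            raise ValueError(
                f"pool constraint requires molecular weights; none for gene {e.gene!r}"
            )
    irr = _prepare_base(model, entries, release_uptake, uptake_bound)
    irr.metabolites.append(
        Metabolite(id=POOL_METABOLITE, name="shared enzyme mass pool (g/gDW)", compartment="c")
    )
    pool_bound = f * p_total
    irr.reactions.append(
        Reaction(
            id=POOL_SUPPLY,
            stoichiometry={POOL_METABOLITE: 1.0},
            lower_bound=0.0,
            upper_bound=pool_bound,
            subsystem="Enzyme usage",
            name="total enzyme pool supply",
        )
    )
    usage_map: dict[str, str] = {}
    usage_ids: list[str] = [POOL_SUPPLY]
    constrained: list[str] = []
    for e in entries:
        kcat_h = e.kcat * SECONDS_PER_HOUR
        for split_id, suffix in _constrained_halves(irr, e.reaction_id):
            prot_id = f"prot_{e.gene}{suffix}"
            usage_id = f"usage_{e.gene}{suffix}"
            irr.metabolites.append(
                Metabolite(id=prot_id, name=f"enzyme usage pseudo-metabolite ({e.gene})",
                           compartment="c")
            )
            irr.reactions.append(
                Reaction(
                    id=usage_id,
                    stoichiometry={POOL_METABOLITE: -float(e.mw), prot_id: 1.0},
                    lower_bound=0.0,
                    upper_bound=float("inf"),
                    subsystem="Enzyme usage",
                    name=f"usage of {e.gene} (pool-limited)",
                )
            )
            rxn = irr.get_reaction(split_id)
            rxn.stoichiometry[prot_id] = -1.0 / kcat_h
            usage_map[split_id] = usage_id
            usage_ids.append(usage_id)
            constrained.append(split_id)
    irr.annotations[USAGE_REACTIONS] = usage_ids
    irr.annotations["enzyme_constrained"] = constrained
    irr.id = f"kc_{model.id}"
    irr.validate()
    return ECModel(
        irr,
        list(entries),
        constrained,
        usage_map,
        pool={"p_total": p_total, "f": f, "bound": pool_bound},
    )
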