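"""Core data structures for constraint-based metabolic models.

A :class:`MetabolicModel` is a plain stoichiometric reconstruction: metabolites,
reactions with flux bounds and gene-protein-reaction (GPR) rules, and a single
(biomass) objective reaction.  The structures are deliberately minimal and
value-like; all analysis lives in :mod:`ecgem.simulation` and friends.

Conventions follow the iYO844 reconstruction of *Bacillus subtilis*: reaction
ids upper-case, metabolite ids lower-case, exchange fluxes negative on uptake.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxSolution",
    "convert_to_irreversible",
    "net_fluxes",
    "knockout",
    "evaluate_gpr",
    "gpr_genes",
]

#: annotation key under which the irreversible conversion records, for every
#: original reaction, the ids of its forward/reverse halves.
IRREVERSIBLE_MAP = "irreversible_map"
#: annotation key listing bookkeeping reactions (enzyme usage / pool supply)
#: that are not part of the metabolic flux phenotype.
USAGE_REACTIONS = "enzyme_usage_reactions"


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("metabolite id must be non-empty")


@dataclass
class Reaction:
    """A reaction with signed stoichiometry and flux bounds in mmol/gDW/h."""

    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gene_rule: str = ""
    subsystem: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower_bound {self.lower_bound} exceeds "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def boundary(self) -> bool:
        """True for exchange/demand reactions (single-metabolite stoichiometry)."""
        return len(self.stoichiometry) <= 1

    def genes(self) -> set[str]:
        return gpr_genes(self.gene_rule)


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    objective_reaction_id: str = ""
    annotations: dict = field(default_factory=dict)
    id: str = "model"

    # -- lookups ----------------------------------------------------------
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction with id {rid!r}")

    def get_metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(f"no metabolite with id {mid!r}")

    def has_reaction(self, rid: str) -> bool:
        return any(r.id == rid for r in self.reactions)

    def has_metabolite(self, mid: str) -> bool:
        return any(m.id == mid for m in self.metabolites)

    # -- integrity --------------------------------------------------------
    def validate(self) -> None:
        """Raise ValueError on any violated structural invariant."""
        mids = self.metabolite_ids()
        if len(set(mids)) != len(mids):
            dupes = {m for m in mids if mids.count(m) > 1}
            raise ValueError(f"duplicate metabolite ids: {sorted(dupes)}")
        rids = self.reaction_ids()
        if len(set(rids)) != len(rids):
            dupes = {r for r in rids if rids.count(r) > 1}
            raise ValueError(f"duplicate reaction ids: {sorted(dupes)}")
        known = set(mids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ValueError(
                    f"reaction {r.id} references unknown metabolites {sorted(missing)}"
                )
        if self.objective_reaction_id and self.objective_reaction_id not in set(rids):
            raise ValueError(
                f"objective reaction {self.objective_reaction_id!r} not in model"
            )

    # -- matrix view ------------------------------------------------------
    def stoichiometric_matrix(self) -> tuple[sparse.csr_matrix, list[str], list[str]]:
        """S (metabolites x reactions), with the row/column id orderings."""
        mids = self.metabolite_ids()
        rids = self.reaction_ids()
        mindex = {m: i for i, m in enumerate(mids)}
        rows, cols, vals = [], [], []
        for j, r in enumerate(self.reactions):
            for mid, coef in r.stoichiometry.items():
                rows.append(mindex[mid])
                cols.append(j)
                vals.append(float(coef))
        S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(mids), len(rids))
        )
        return S, mids, rids

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)


@dataclass
class FluxSolution:
    """A flux vector with its objective value and solver status."""

    fluxes: dict[str, float]
    objective_value: float
    status: str  # "optimal" | "infeasible" | "unbounded"
    meta: dict = field(default_factory=dict)

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    def as_vector(self, order: list[str]) -> np.ndarray:
        return np.array([self.fluxes[r] for r in order], dtype=float)


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def _gpr_tokens(rule: str) -> list[str]:
    return _GPR_TOKEN.findall(rule)


def _parse_or(tokens: list[str], pos: int):
    node, pos = _parse_and(tokens, pos)
    terms = [node]
    while pos < len(tokens) and tokens[pos].lower() == "or":
        nxt, pos = _parse_and(tokens, pos + 1)
        terms.append(nxt)
    return (("or", terms) if len(terms) > 1 else terms[0]), pos


def _parse_and(tokens: list[str], pos: int):
    node, pos = _parse_atom(tokens, pos)
    terms = [node]
    while pos < len(tokens) and tokens[pos].lower() == "and":
        nxt, pos = _parse_atom(tokens, pos + 1)
        terms.append(nxt)
    return (("and", terms) if len(terms) > 1 else terms[0]), pos


def _parse_atom(tokens: list[str], pos: int):
    if pos >= len(tokens):
        raise ValueError("truncated gene rule")
    tok = tokens[pos]
    if tok == "(":
        node, pos = _parse_or(tokens, pos + 1)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise ValueError("unbalanced parentheses in gene rule")
        return node, pos + 1
    if tok == ")" or tok.lower() in ("and", "or"):
        raise ValueError(f"unexpected token {tok!r} in gene rule")
    return ("gene", tok), pos + 1


def _parse_gpr(rule: str):
    tokens = _gpr_tokens(rule)
    if not tokens:
        return None
    node, pos = _parse_or(tokens, 0)
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in gene rule {rule!r}")
    return node


def _eval_node(node, absent: set[str]) -> bool:
    kind = node[0]
    if kind == "gene":
        return node[1] not in absent
    if kind == "and":
        return all(_eval_node(n, absent) for n in node[1])
    return any(_eval_node(n, absent) for n in node[1])


def evaluate_gpr(rule: str, absent_genes: set[str]) -> bool:
    """Evaluate a boolean AND/OR gene rule with the given genes knocked out.

    An empty rule evaluates True (spontaneous / orphan reaction).
    """
    node = _parse_gpr(rule)
    if node is None:
        return True
    return _eval_node(node, set(absent_genes))


def gpr_genes(rule: str) -> set[str]:
    node = _parse_gpr(rule)
    out: set[str] = set()

    def walk(n):
        if n[0] == "gene":
            out.add(n[1])
        else:
            for c in n[1]:
                walk(c)

    if node is not None:
        walk(node)
    return out


# ---------------------------------------------------------------------------
# Irreversible conversion
# ---------------------------------------------------------------------------


def convert_to_irreversible(model: MetabolicModel) -> MetabolicModel:
    """Split every reversible reaction R into R_f / R_r with non-negative bounds.

    The net flux of the original reaction is v = v_f - v_r; the mapping is
    recorded under ``annotations[IRREVERSIBLE_MAP]`` so that net fluxes can be
    recombined after simulation.  A model with no reversible reactions is
    returned as an unchanged copy (same reaction count, empty map entries).
    """
    out = model.copy()
    new_reactions: list[Reaction] = []
    irrev_map: dict[str, dict] = {}
    for r in out.reactions:
        if r.lower_bound >= 0:
            new_reactions.append(r)
            irrev_map[r.id] = {"forward": r.id, "reverse": None}
            continue
        rev_stoich = {m: -c for m, c in r.stoichiometry.items()}
        if r.upper_bound <= 0:
            # strictly backward reaction: represent as the reverse direction only
            rev = Reaction(
                id=r.id + "_r",
                stoichiometry=rev_stoich,
                lower_bound=max(0.0, -r.upper_bound),
                upper_bound=-r.lower_bound,
                gene_rule=r.gene_rule,
                subsystem=r.subsystem,
                name=r.name,
            )
            new_reactions.append(rev)
            irrev_map[r.id] = {"forward": None, "reverse": rev.id}
            continue
        fwd = Reaction(
            id=r.id + "_f",
            stoichiometry=dict(r.stoichiometry),
            lower_bound=0.0,
            upper_bound=r.upper_bound,
            gene_rule=r.gene_rule,
            subsystem=r.subsystem,
            name=r.name,
        )
        rev = Reaction(
            id=r.id + "_r",
            stoichiometry=rev_stoich,
            lower_bound=0.0,
            upper_bound=-r.lower_bound,
            gene_rule=r.gene_rule,
            subsystem=r.subsystem,
            name=r.name,
        )
        new_reactions.extend([fwd, rev])
        irrev_map[r.id] = {"forward": fwd.id, "reverse": rev.id}
        if model.objective_reaction_id == r.id:
            out.objective_reaction_id = fwd.id
    out.reactions = new_reactions
    out.annotations[IRREVERSIBLE_MAP] = irrev_map
    return out


def net_fluxes(model: MetabolicModel, fluxes: dict[str, float]) -> dict[str, float]:
    """Recombine split fluxes into the original reaction namespace.

    For models that were never converted the fluxes pass through unchanged.
    Bookkeeping reactions (enzyme usage variables) are dropped.
    """
    usage = set(model.annotations.get(USAGE_REACTIONS, []))
    irrev_map = model.annotations.get(IRREVERSIBLE_MAP)
    if irrev_map is None:
        return {r: v for r, v in fluxes.items() if r not in usage}
    out: dict[str, float] = {}
    for orig, halves in irrev_map.items():
        if orig in usage:
            continue
        v = 0.0
        if halves["forward"] is not None:
            v += fluxes.get(halves["forward"], 0.0)
        if halves["reverse"] is not None:
            v -= fluxes.get(halves["reverse"], 0.0)
        out[orig] = v
    return out


# ---------------------------------------------------------------------------
# Knockouts
# ---------------------------------------------------------------------------


def _zero_reaction(model: MetabolicModel, rid: str) -> None:
    r = model.get_reaction(rid)
    r.lower_bound = 0.0
    r.upper_bound = 0.0


def knockout(model: MetabolicModel, targets) -> MetabolicModel:
    """Return a copy with the targeted reactions (or genes) forced to zero flux.

    Reaction targets have both bounds set to 0; in an irreversible model both
    split halves of the original reaction are zeroed.  Gene targets zero every
    reaction whose GPR evaluates False with those genes absent.
    """
    targets = set(targets)
    out = model.copy()
    rids = set(out.reaction_ids())
    irrev_map = out.annotations.get(IRREVERSIBLE_MAP, {})
    gene_set = set(out.genes) | {
        g for r in out.reactions for g in gpr_genes(r.gene_rule)
    }
    unknown = [
        t
        for t in targets
        if t not in rids and t not in irrev_map and t not in gene_set
    ]
    if unknown:
        raise KeyError(f"unknown knockout targets: {sorted(unknown)}")

    reaction_targets = {t for t in targets if t in rids or t in irrev_map}
    gene_targets = targets - reaction_targets
    for t in reaction_targets:
        if t in irrev_map and t not in rids:
            halves = irrev_map[t]
            for h in (halves["forward"], halves["reverse"]):
                if h is not None:
                    _zero_reaction(out, h)
        else:
            _zero_reaction(out, t)
    if gene_targets:
        for r in out.reactions:
            if r.gene_rule and not evaluate_gpr(r.gene_rule, gene_targets):
                r.lower_bound = 0.0
                r.upper_bound = 0.0
    return out
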