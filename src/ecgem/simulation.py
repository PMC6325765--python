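"""Flux simulation methods: FBA, parsimonious FBA, MoMA and FVA.

All high-level entry points accept either a plain (possibly reversible)
:class:`~ecgem.model.MetabolicModel` or the irreversible augmented model inside
an enzyme-constrained model, and report fluxes in the *net* namespace of the
original reactions (forward minus reverse flux of split pairs; enzyme-usage
bookkeeping variables are dropped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .model import (
    IRREVERSIBLE_MAP,
    USAGE_REACTIONS,
    FluxSolution,
    MetabolicModel,
    convert_to_irreversible,
    net_fluxes,
)
from .solver import solve_lp, solve_qp

__all__ = ["fba", "pfba", "moma", "fva", "FVAResult", "STEADY_STATE_TOL"]

#: tolerance used when asserting S·v = 0 on reported solutions
STEADY_STATE_TOL = 1e-6
_OPT_SLACK = 1e-9  # absolute slack when fixing a previously attained optimum


def _as_irreversible(model: MetabolicModel) -> MetabolicModel:
    """Return a split-form model; models already in split form pass through."""
    lb, _ = model.bounds_arrays()
    if np.all(lb >= 0):
        return model
    return convert_to_irreversible(model)


def _objective_vector(model: MetabolicModel, objective_id: str) -> np.ndarray:
    rids = model.reaction_ids()
    c = np.zeros(len(rids))
    irrev = model.annotations.get(IRREVERSIBLE_MAP, {})
    if objective_id in rids:
        c[rids.index(objective_id)] = 1.0
    elif objective_id in irrev:
        halves = irrev[objective_id]
        if halves["forward"] is not None:
            c[rids.index(halves["forward"])] = 1.0
        if halves["reverse"] is not None:
            c[rids.index(halves["reverse"])] = -1.0
    else:
        raise KeyError(f"objective reaction {objective_id!r} not in model")
    return c


def fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    sense: str = "max",
) -> FluxSolution:
    """Flux balance analysis: optimize cᵀv subject to S·v = 0 and the bounds.

    Fluxes are reported on the model's own reaction namespace (no netting);
    infeasibility/unboundedness is reported through ``status``, not raised.
    """
    objective_id = objective_id or model.objective_reaction_id
    S, _, rids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c = _objective_vector(model, objective_id)
    res = solve_lp(c, S, np.zeros(S.shape[0]), lb, ub, sense=sense)
    if res.status != "optimal":
        return FluxSolution({}, float("nan"), res.status)
    return FluxSolution(dict(zip(rids, res.x)), res.objective, "optimal")


def pfba(model: MetabolicModel, objective_id: str | None = None) -> FluxSolution:
    """Parsimonious FBA: maximize growth, then minimize total flux at that
    growth.

    Stage 2 runs on the irreversible form, so the minimized quantity is the sum
    of all non-negative fluxes; the returned solution is netted back to the
    original reaction namespace.
    """
    objective_id = objective_id or model.objective_reaction_id
    irr = _as_irreversible(model)
    S, _, rids = irr.stoichiometric_matrix()
    lb, ub = irr.bounds_arrays()
    c = _objective_vector(irr, objective_id)
    stage1 = solve_lp(c, S, np.zeros(S.shape[0]), lb, ub, sense="max")
    if stage1.status != "optimal":
        return FluxSolution({}, float("nan"), stage1.status)
    growth = stage1.objective

    lb2, ub2 = lb.copy(), ub.copy()
    # pin the growth optimum (within numerical slack) and minimize total flux
    mask = c != 0
    lb2[mask] = np.maximum(lb2[mask], growth - _OPT_SLACK * max(1.0, abs(growth)))
    total = np.ones(len(rids))
    stage2 = solve_lp(total, S, np.zeros(S.shape[0]), lb2, ub2, sense="min")
    if stage2.status != "optimal":  # pragma: no cover - stage 1 point remains feasible
        return FluxSolution({}, float("nan"), stage2.status)
    raw = dict(zip(rids, stage2.x))
    return FluxSolution(
        net_fluxes(irr, raw),
        growth,
        "optimal",
        meta={"total_flux": stage2.objective, "raw_fluxes": raw},
    )


def _eliminate_usage_variables(irr: MetabolicModel) -> MetabolicModel:
    """Substitute out enzyme-usage bookkeeping variables.

    At steady state a usage variable producing a pseudo-metabolite consumed by
    exactly one reaction with coefficient −c is pinned to u = c·v, so it can
    be folded into that reaction: the usage bound becomes the flux cap
    v ≤ U/c, and any further usage stoichiometry (the shared mass pool) is
    rescaled onto the reaction.  This leaves the QP over metabolic fluxes
    only, which is decisively better scaled for the numerical solver; the
    feasible net-flux polytope is unchanged.
    """
    usage_ids = list(irr.annotations.get(USAGE_REACTIONS, []))
    if not usage_ids:
        return irr
    out = irr.copy()
    consumers: dict[str, list[tuple[str, float]]] = {}
    for r in out.reactions:
        for mid, coef in r.stoichiometry.items():
            consumers.setdefault(mid, []).append((r.id, coef))
    removed_rxns: set[str] = set()
    removed_mets: set[str] = set()
    for uid in usage_ids:
        try:
            u = out.get_reaction(uid)
        except KeyError:
            continue
        produced = [(m, c) for m, c in u.stoichiometry.items() if c > 0]
        if len(produced) != 1 or u.lower_bound != 0:
            continue
        pmet, pc = produced[0]
        users = [(rid, c) for rid, c in consumers.get(pmet, []) if rid != uid]
        if len(users) != 1 or users[0][1] >= 0:
            continue
        rid, c = users[0]
        rxn = out.get_reaction(rid)
        scale = -c / pc  # u = scale * v at steady state
        if np.isfinite(u.upper_bound):
            rxn.upper_bound = min(rxn.upper_bound, u.upper_bound / scale)
        for mid, a in u.stoichiometry.items():
            if mid == pmet:
                continue
            rxn.stoichiometry[mid] = rxn.stoichiometry.get(mid, 0.0) + a * scale
        del rxn.stoichiometry[pmet]
        removed_rxns.add(uid)
        removed_mets.add(pmet)
    out.reactions = [r for r in out.reactions if r.id not in removed_rxns]
    out.metabolites = [m for m in out.metabolites if m.id not in removed_mets]
    out.annotations[USAGE_REACTIONS] = [u for u in usage_ids if u not in removed_rxns]
    return out


def moma(
    model: MetabolicModel,
    reference: FluxSolution | dict[str, float],
    exclude: set[str] | None = None,
) -> FluxSolution:
    """Minimization of metabolic adjustment.

    Finds the feasible flux distribution of ``model`` (typically a knockout)
    closest in Euclidean distance to the wild-type ``reference``, the distance
    being taken over net fluxes of the ordinary metabolic reactions shared by
    model and reference; enzyme-usage bookkeeping variables never enter the
    distance.  An infeasible mutant is reported with status "infeasible"
    (interpreted downstream as zero growth).
    """
    ref = reference.fluxes if isinstance(reference, FluxSolution) else dict(reference)
    irr = _eliminate_usage_variables(_as_irreversible(model))
    S, _, rids = irr.stoichiometric_matrix()
    lb, ub = irr.bounds_arrays()
    n = len(rids)
    rindex = {r: j for j, r in enumerate(rids)}
    usage = set(irr.annotations.get(USAGE_REACTIONS, []))
    skip = usage | (set(exclude) if exclude else set())

    irrev = irr.annotations.get(IRREVERSIBLE_MAP)
    net_ids = list(irrev) if irrev is not None else list(rids)
    matched = [r for r in net_ids if r in ref and r not in skip]
    if not matched:
        raise ValueError("reference shares no reactions with the model")

    rows, cols, vals = [], [], []
    target = np.zeros(len(matched))
    for i, r in enumerate(matched):
        target[i] = ref[r]
        if irrev is not None:
            halves = irrev[r]
            if halves["forward"] is not None:
                rows.append(i); cols.append(rindex[halves["forward"]]); vals.append(1.0)
            if halves["reverse"] is not None:
                rows.append(i); cols.append(rindex[halves["reverse"]]); vals.append(-1.0)
        else:
            rows.append(i); cols.append(rindex[r]); vals.append(1.0)
    M = sparse.csr_matrix((vals, (rows, cols)), shape=(len(matched), n))

    # min ||Mv - ref||^2  =>  P = 2 M'M (+ tiny ridge for strict convexity in
    # the split coordinates), q = -2 M'ref
    ridge = 1e-9
    P = 2.0 * (M.T @ M) + 2.0 * ridge * sparse.eye(n)
    q = -2.0 * (M.T @ target)
    A = sparse.vstack([S, sparse.eye(n)])
    l = np.concatenate([np.zeros(S.shape[0]), lb])
    u = np.concatenate([np.zeros(S.shape[0]), ub])
    res = solve_qp(P, q, A, l, u)
    if res.status != "optimal":
        return FluxSolution({}, 0.0, res.status)
    raw = dict(zip(rids, res.x))
    net = net_fluxes(irr, raw)
    dist = float(np.linalg.norm(M @ res.x - target))
    growth_id = model.objective_reaction_id
    growth = net.get(growth_id, raw.get(growth_id, 0.0))
    return FluxSolution(net, growth, "optimal", meta={"distance": dist, "raw_fluxes": raw})


@dataclass
class FVAResult:
    """Per-reaction flux ranges at a given fraction of the optimal growth."""

    frame: pd.DataFrame  # index: reaction id; columns: minflux, maxflux, fv
    fraction_of_optimum: float
    max_growth: float

    def fv(self) -> pd.Series:
        return self.frame["fv"]

    def to_tsv(self, path: str) -> None:
        self.frame.to_csv(path, sep="\t", index_label="reaction_id")


def fva(
    model: MetabolicModel,
    fraction: float = 0.9,
    reactions: list[str] | None = None,
) -> FVAResult:
    """Flux variability analysis at ``fraction`` of the maximal growth rate.

    For every (net) reaction the minimal and maximal attainable flux is
    computed subject to growth ≥ fraction × max growth; the variability range
    is FV = maxflux − minflux.  Split reversible pairs are recombined to net
    ranges.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    irr = _as_irreversible(model)
    S, _, rids = irr.stoichiometric_matrix()
    lb, ub = irr.bounds_arrays()
    b = np.zeros(S.shape[0])
    cg = _objective_vector(irr, model.objective_reaction_id)
    opt = solve_lp(cg, S, b, lb, ub, sense="max")
    if opt.status != "optimal":
        raise RuntimeError(f"base model has no optimal growth solution ({opt.status})")
    growth = opt.objective

    lb2, ub2 = lb.copy(), ub.copy()
    mask = cg != 0
    floor = fraction * growth - _OPT_SLACK * max(1.0, abs(growth))
    lb2[mask] = np.maximum(lb2[mask], floor)

    rindex = {r: j for j, r in enumerate(rids)}
    irrev = irr.annotations.get(IRREVERSIBLE_MAP)
    usage = set(irr.annotations.get(USAGE_REACTIONS, []))
    net_ids = [r for r in (irrev if irrev is not None else rids) if r not in usage]
    if reactions is not None:
        unknown = [r for r in reactions if r not in set(net_ids)]
        if unknown:
            raise KeyError(f"unknown reactions for FVA: {sorted(unknown)}")
        net_ids = list(reactions)

    records = []
    for r in net_ids:
        c = np.zeros(len(rids))
        if irrev is not None:
            halves = irrev[r]
            if halves["forward"] is not None:
                c[rindex[halves["forward"]]] = 1.0
            if halves["reverse"] is not None:
                c[rindex[halves["reverse"]]] = -1.0
        else:
            c[rindex[r]] = 1.0
        lo = solve_lp(c, S, b, lb2, ub2, sense="min")
        hi = solve_lp(c, S, b, lb2, ub2, sense="max")
        if lo.status != "optimal" or hi.status != "optimal":  # pragma: no cover
            raise RuntimeError(f"FVA subproblem failed for {r}: {lo.status}/{hi.status}")
        records.append((r, lo.objective, hi.objective, max(0.0, hi.objective - lo.objective)))
    frame = pd.DataFrame.from_records(
        records, columns=["reaction_id", "minflux", "maxflux", "fv"]
    ).set_index("reaction_id")
    return FVAResult(frame, fraction, growth)
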