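"""LP/QP simulation methods against hand-solvable oracles."""

import numpy as np
import pytest

from ecgem.model import (
    FluxSolution,
    MetabolicModel,
    Metabolite,
    Reaction,
    convert_to_irreversible,
    knockout,
)
from ecgem.simulation import fba, fva, moma, pfba


class TestFBA:
    def test_linear_chain_capacity(self, chain_model):
        sol = fba(chain_model)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(5.0, abs=1e-9)

    def test_toy_matches_analytic_optimum(self, toy):
        # glucose-limited: growth = uptake / per-growth glucose coefficient
        sol = fba(toy.model)
        assert sol.objective_value == pytest.approx(toy.mu_unconstrained, abs=1e-8)
        assert sol.objective_value == pytest.approx(600.0 / 103.0, abs=1e-8)

    def test_infeasible_reported_as_status(self, chain_model):
        m = chain_model.copy()
        m.get_reaction("BIO").lower_bound = 10.0  # demands more than uptake allows
        sol = fba(m)
        assert sol.status == "infeasible"

    def test_unbounded_reported_as_status(self):
        m = MetabolicModel(
            metabolites=[Metabolite("a")],
            reactions=[
                Reaction("IN", {"a": 1}, 0, float("inf")),
                Reaction("OUT", {"a": -1}, 0, float("inf")),
            ],
            objective_reaction_id="OUT",
        )
        assert fba(m).status == "unbounded"

    def test_steady_state_and_bounds_respected(self, toy):
        sol = fba(toy.model)
        S, _, rids = toy.model.stoichiometric_matrix()
        v = sol.as_vector(rids)
        lb, ub = toy.model.bounds_arrays()
        assert np.max(np.abs(S @ v)) <= 1e-6
        assert np.all(v >= lb - 1e-8) and np.all(v <= ub + 1e-8)


class TestPFBA:
    def test_growth_equals_fba_optimum(self, toy):
        assert pfba(toy.model).objective_value == pytest.approx(
            fba(toy.model).objective_value, abs=1e-6
        )

    def test_unique_optimum_recovered(self, chain_model):
        sol = pfba(chain_model)
        assert sol.fluxes == pytest.approx({"UPT": 5.0, "CONV": 5.0, "BIO": 5.0}, abs=1e-8)

    def test_internal_cycle_suppressed(self, chain_model):
        # add a 3-reaction futile cycle b -> c -> d -> b that FBA may spin
        m = chain_model.copy()
        m.metabolites += [Metabolite("c"), Metabolite("d")]
        m.reactions += [
            Reaction("C1", {"b": -1, "c": 1}, 0, 1000),
            Reaction("C2", {"c": -1, "d": 1}, 0, 1000),
            Reaction("C3", {"d": -1, "b": 1}, 0, 1000),
        ]
        sol = pfba(m)
        assert sol.objective_value == pytest.approx(5.0, abs=1e-8)
        for rid in ("C1", "C2", "C3"):
            assert sol.fluxes[rid] == pytest.approx(0.0, abs=1e-8)

    def test_total_flux_not_above_plain_fba(self, toy):
        psol = pfba(toy.model)
        fsol = fba(convert_to_irreversible(toy.model))
        assert psol.meta["total_flux"] <= sum(fsol.fluxes.values()) + 1e-6

    def test_toy_truth_is_the_parsimonious_point(self, toy, toy_ec):
        sol = pfba(toy_ec.model)
        for rid, v in toy.truth.fluxes.items():
            assert sol.fluxes[rid] == pytest.approx(v, abs=1e-6), rid


class TestMoMA:
    def test_feasible_reference_is_returned_with_zero_distance(self, toy):
        ref = pfba(toy.model)
        sol = moma(toy.model, ref)
        assert sol.status == "optimal"
        assert sol.meta["distance"] == pytest.approx(0.0, abs=1e-5)
        assert sol.objective_value == pytest.approx(ref.objective_value, abs=1e-5)

    def test_closed_form_equality_constrained_least_squares(self):
        """Two parallel suppliers, one deleted: Lagrangian closed form.

        min (v2-2)^2 + (dem-4)^2 s.t. v2 = dem  =>  v2 = dem = 3.
        """
        m = MetabolicModel(
            metabolites=[Metabolite("a")],
            reactions=[
                Reaction("R1", {"a": 1}, 0, 10),
                Reaction("R2", {"a": 1}, 0, 10),
                Reaction("DEM", {"a": -1}, 0, 10),
            ],
            objective_reaction_id="DEM",
        )
        ref = {"R1": 2.0, "R2": 2.0, "DEM": 4.0}
        sol = moma(knockout(m, {"R1"}), ref)
        assert sol.fluxes["R2"] == pytest.approx(3.0, abs=1e-6)
        assert sol.fluxes["DEM"] == pytest.approx(3.0, abs=1e-6)
        # distance^2 = (0-2)^2 + (3-2)^2 + (3-4)^2 = 6
        assert sol.meta["distance"] == pytest.approx(np.sqrt(6.0), abs=1e-6)

    def test_matches_independent_qp_oracle(self, toy):
        """MoMA agrees with a different QP algorithm (scipy SLSQP) solving
        min ||v - ref||^2 s.t. S v = 0 and the mutant bounds directly."""
        from scipy.optimize import minimize

        mut = knockout(toy.model, {"AKGD"})
        ref = pfba(toy.model)
        sol = moma(mut, ref)

        S, _, rids = mut.stoichiometric_matrix()
        S = S.toarray()
        lb, ub = mut.bounds_arrays()
        r = np.array([ref.fluxes[x] for x in rids])
        res = minimize(
            lambda v: np.sum((v - r) ** 2),
            jac=lambda v: 2 * (v - r),
            x0=np.clip(r, lb, ub),
            bounds=list(zip(lb, ub)),
            constraints={"type": "eq", "fun": lambda v: S @ v, "jac": lambda v: S},
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-12},
        )
        assert res.success
        for j, rid in enumerate(rids):
            assert sol.fluxes[rid] == pytest.approx(res.x[j], abs=1e-4), rid
        assert sol.meta["distance"] == pytest.approx(
            np.sqrt(res.fun), abs=1e-4
        )

    def test_growth_not_above_mutant_fba(self, toy):
        mut = knockout(toy.model, {"PGI"})
        ref = pfba(toy.model)
        sol = moma(mut, ref)
        assert sol.objective_value <= fba(mut).objective_value + 1e-6

    def test_infeasible_mutant_status(self, chain_model):
        m = chain_model.copy()
        m.get_reaction("BIO").lower_bound = 1.0
        mut = knockout(m, {"CONV"})
        sol = moma(mut, {"UPT": 5.0, "CONV": 5.0, "BIO": 5.0})
        assert sol.status == "infeasible"

    def test_disjoint_reference_raises(self, chain_model):
        with pytest.raises(ValueError):
            moma(chain_model, {"XXX": 1.0})


class TestFVA:
    def test_fully_determined_network_has_zero_fv(self, chain_model):
        res = fva(chain_model, fraction=1.0)
        assert np.all(res.frame["fv"].to_numpy() <= 1e-7)

    def test_two_parallel_routes_each_swing_full_capacity(self, parallel_model):
        res = fva(parallel_model, fraction=1.0)
        assert res.max_growth == pytest.approx(4.0, abs=1e-9)
        for rid in ("R1", "R2"):
            assert res.frame.loc[rid, "minflux"] == pytest.approx(0.0, abs=1e-7)
            assert res.frame.loc[rid, "maxflux"] == pytest.approx(4.0, abs=1e-7)
            assert res.frame.loc[rid, "fv"] == pytest.approx(4.0, abs=1e-7)

    def test_brackets_the_pfba_point(self, toy):
        res = fva(toy.model, fraction=0.9)
        sol = pfba(toy.model)
        for rid in res.frame.index:
            assert res.frame.loc[rid, "minflux"] - 1e-6 <= sol.fluxes[rid]
            assert sol.fluxes[rid] <= res.frame.loc[rid, "maxflux"] + 1e-6

    def test_min_never_exceeds_max(self, toy, toy_ec):
        for model in (toy.model, toy_ec.model):
            res = fva(model, fraction=0.9)
            assert np.all(
                res.frame["minflux"].to_numpy() <= res.frame["maxflux"].to_numpy() + 1e-9
            )

    def test_net_ranges_for_split_model(self, toy, toy_ec):
        res = fva(toy_ec.model, fraction=0.9)
        # namespace is the original (net) one, without usage bookkeeping
        assert set(res.frame.index) <= set(toy.model.reaction_ids())
        assert not any(r.startswith("usage_") for r in res.frame.index)

    def test_monotone_shrinkage_at_matched_growth_floor(self, toy, toy_ec):
        """Enzyme caps shrink every flux range once growth floors coincide.

        The ec feasible set (same uptake bound, caps added) is a subset of the
        base set, so with an identical absolute growth requirement no FV can
        grow.
        """
        from ecgem.gecko import apply_enzyme_constraints

        ec_same_uptake = apply_enzyme_constraints(toy.model, toy.enzyme_entries)
        res_ec = fva(ec_same_uptake.model, fraction=0.9)
        floor = 0.9 * res_ec.max_growth
        base_fraction = floor / fba(toy.model).objective_value
        res_base = fva(toy.model, fraction=base_fraction)
        for rid in res_ec.frame.index:
            assert (
                res_ec.frame.loc[rid, "fv"]
                <= res_base.frame.loc[rid, "fv"] + 1e-6
            ), rid

    def test_bad_fraction_rejected(self, toy):
        with pytest.raises(ValueError):
            fva(toy.model, fraction=0.0)
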