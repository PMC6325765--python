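"""Prediction scoring, essentiality, kcat randomization, stepwise inclusion,
and the FV-comparison statistics (cross-checked against brute-force
enumeration)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgem.enzymes import EnzymeEntry
from ecgem.evaluation import (
    FluxMeasurementSet,
    compare_fv,
    essentiality_screen,
    prediction_error,
    randomize_kcat,
    stepwise_inclusion,
    subsystem_enrichment,
)
from ecgem.gecko import apply_enzyme_constraints
from ecgem.simulation import FVAResult, pfba
from ecgem.synth import make_flux_measurements


def _meas(values: dict) -> FluxMeasurementSet:
    return FluxMeasurementSet(dict(values))


class TestPredictionError:
    def test_perfect_prediction_scores_zero(self):
        assert prediction_error(_meas({"A": 3.0, "B": 4.0}), {"A": 3.0, "B": 4.0}) == 0.0

    def test_zero_prediction_scores_one(self):
        assert prediction_error(_meas({"A": 3.0, "B": 4.0}), {"A": 0.0, "B": 0.0}) == 1.0

    def test_worked_example(self):
        # ||(3,4)-(3,0)|| / ||(3,4)|| = 4/5
        assert prediction_error(_meas({"A": 3.0, "B": 4.0}), {"A": 3.0, "B": 0.0}) == pytest.approx(0.8)

    @settings(derandomize=True, max_examples=30)
    @given(k=st.floats(0.01, 100, allow_nan=False))
    def test_scale_invariance_under_joint_rescaling(self, k):
        exp = {"A": 3.0, "B": -4.0, "C": 1.0}
        pred = {"A": 2.0, "B": -5.0, "C": 0.5}
        e1 = prediction_error(_meas(exp), pred)
        e2 = prediction_error(
            _meas({r: k * v for r, v in exp.items()}),
            {r: k * v for r, v in pred.items()},
        )
        assert e2 == pytest.approx(e1, rel=1e-9)

    def test_not_symmetric_in_arguments(self):
        a, b = {"A": 1.0, "B": 2.0}, {"A": 2.0, "B": 5.0}
        assert prediction_error(_meas(a), b) != pytest.approx(prediction_error(_meas(b), a))

    def test_missing_prediction_raises(self):
        with pytest.raises(KeyError, match="B"):
            prediction_error(_meas({"A": 1.0, "B": 1.0}), {"A": 1.0})

    def test_zero_experimental_norm_raises(self):
        with pytest.raises(ValueError):
            prediction_error(_meas({"A": 0.0}), {"A": 1.0})

    def test_tsv_round_trip(self, tmp_path):
        m = FluxMeasurementSet({"A": 1.5, "B": -2.0}, cv={"A": 0.1}, condition="wt")
        path = str(tmp_path / "meas.tsv")
        m.to_tsv(path)
        back = FluxMeasurementSet.from_tsv(path)
        assert back.values == pytest.approx(m.values)

    def test_id_remapping_with_sign(self):
        m = FluxMeasurementSet({"glc_upt": 5.0})
        r = m.remapped({"glc_upt": ("EX_glc_e", -1.0)})
        assert r.values == {"EX_glc_e": -5.0}


class TestEssentiality:
    def test_blocking_the_only_biomass_route_is_lethal(self, toy):
        rep = essentiality_screen(toy.model, ["gapA"], method="pfba")
        assert rep.frame.loc["gapA", "growth"] == pytest.approx(0.0, abs=1e-8)
        assert rep.frame.loc["gapA", "predicted_essential"]

    def test_redundant_pathway_pair_not_essential_alone(self, toy):
        # glucose-6-phosphate can leave via PGI or via the PPP (zwf):
        # neither deletion alone is lethal in the unconstrained network
        rep = essentiality_screen(toy.model, ["pgi", "zwf"])
        assert not rep.frame["predicted_essential"].any()

    def test_enzyme_constraints_add_correct_essential_calls(self, toy, toy_ec):
        """The analog of the curated model's essentiality gain: genes whose
        backup route runs through a capacity-limited enzyme become essential
        only once enzyme constraints are integrated."""
        genes = ["gapA", "pgi", "zwf", "pfkA", "pyk", "citZ", "odhA", "sucC", "mdh"]
        observed = {"gapA", "pyk", "pfkA", "pgi", "odhA"}
        base = essentiality_screen(toy.model, genes, observed_essential=observed)
        ec = essentiality_screen(toy_ec.model, genes, observed_essential=observed)
        assert base.correct_calls() == 2  # gapA, pyk
        assert ec.correct_calls() == 5  # + pfkA, pgi, odhA
        # threshold semantics
        for rep in (base, ec):
            assert (
                (rep.frame["growth"] < rep.threshold)
                == rep.frame["predicted_essential"]
            ).all()

    def test_unresolvable_gene_reported_not_fatal(self, toy):
        rep = essentiality_screen(toy.model, ["not_a_gene"])
        assert np.isnan(rep.frame.loc["not_a_gene", "growth"])

    def test_group_summary_counts(self, toy):
        rep = essentiality_screen(
            toy.model,
            ["gapA", "pyk", "mdh"],
            observed_essential={"gapA", "pyk"},
            groups={"gapA": "CC", "pyk": "CC", "mdh": "CC"},
        )
        summary = rep.summary()
        assert summary.loc["CC", "correct"] == 2


class TestRandomizeKcat:
    def test_equal_kcats_give_degenerate_distribution(self, toy):
        entries = [
            EnzymeEntry(e.reaction_id, e.gene, 50.0, e.abundance, mw=e.mw)
            for e in toy.enzyme_entries
        ]
        meas = make_flux_measurements(toy.model, toy.truth, cv=0.0, seed=0)
        res = randomize_kcat(
            toy.model, entries, meas, n_perm=10, seed=1, release_uptake="EX_glc_e"
        )
        assert np.allclose(res.errors, res.true_error)

    def test_seeded_runs_are_bit_identical(self, toy):
        meas = make_flux_measurements(toy.model, toy.truth, cv=0.1, seed=3)
        kw = dict(n_perm=12, seed=42, release_uptake="EX_glc_e")
        a = randomize_kcat(toy.model, toy.enzyme_entries, meas, **kw)
        b = randomize_kcat(toy.model, toy.enzyme_entries, meas, **kw)
        assert np.array_equal(a.errors, b.errors)

    def test_two_free_entries_yield_identity_or_swap(self, toy):
        """Freezing all but two entries leaves exactly two possible models."""
        frozen = {e.reaction_id for e in toy.enzyme_entries} - {"CS", "GAPD_NAD"}
        meas = make_flux_measurements(toy.model, toy.truth, cv=0.0, seed=0)
        res = randomize_kcat(
            toy.model, toy.enzyme_entries, meas, n_perm=30, frozen=frozen,
            seed=7, release_uptake="EX_glc_e",
        )
        # identity permutation reproduces the true-model error exactly
        swapped = []
        by_rid = {e.reaction_id: e for e in toy.enzyme_entries}
        for e in toy.enzyme_entries:
            k = e.kcat
            if e.reaction_id == "CS":
                k = by_rid["GAPD_NAD"].kcat
            elif e.reaction_id == "GAPD_NAD":
                k = by_rid["CS"].kcat
            swapped.append(EnzymeEntry(e.reaction_id, e.gene, k, e.abundance, mw=e.mw))
        ec = apply_enzyme_constraints(toy.model, swapped, release_uptake="EX_glc_e")
        from ecgem.evaluation import prediction_error as perr

        err_swap = perr(meas, pfba(ec.model))
        for err in res.errors:
            assert err == pytest.approx(res.true_error, abs=1e-9) or err == pytest.approx(
                err_swap, abs=1e-9
            )
        assert {round(e, 6) for e in res.errors} == {
            round(res.true_error, 6),
            round(err_swap, 6),
        }

    def test_needs_two_free_entries(self, toy):
        meas = make_flux_measurements(toy.model, toy.truth, cv=0.0, seed=0)
        frozen = {e.reaction_id for e in toy.enzyme_entries[:-1]}
        with pytest.raises(ValueError):
            randomize_kcat(toy.model, toy.enzyme_entries, meas, frozen=frozen, seed=0)


class TestStepwise:
    def _score(self, toy, meas):
        def score(ec):
            sol = pfba(ec.model) if ec is not None else pfba(toy.model)
            return {"wild_type_error": prediction_error(meas, sol)}

        return score

    def test_empty_subset_scores_unconstrained_model(self, toy):
        meas = make_flux_measurements(toy.model, toy.truth, cv=0.0, seed=0)
        df = stepwise_inclusion(
            toy.model, toy.enzyme_entries, self._score(toy, meas),
            mode="exhaustive", release_uptake="EX_glc_e",
        )
        empty = df[df["size"] == 0].iloc[0]
        assert empty["wild_type_error"] == pytest.approx(
            prediction_error(meas, pfba(toy.model))
        )

    @pytest.mark.parametrize("mode", ["exhaustive", "greedy"])
    def test_single_binding_constraint_is_the_minimal_set(self, toy, mode):
        # only the CS capacity binds the wild type, so {CS} alone reproduces
        # the full model's wild-type error
        meas = make_flux_measurements(toy.model, toy.truth, cv=0.0, seed=0)
        df = stepwise_inclusion(
            toy.model, toy.enzyme_entries, self._score(toy, meas),
            mode=mode, release_uptake="EX_glc_e",
        )
        minimal = df[df["minimal"]]
        assert list(minimal["subset"]) == [("CS",)]

    def test_adding_nonbinding_constraint_keeps_error(self, toy):
        meas = make_flux_measurements(toy.model, toy.truth, cv=0.0, seed=0)
        df = stepwise_inclusion(
            toy.model, toy.enzyme_entries, self._score(toy, meas),
            mode="exhaustive", release_uptake="EX_glc_e",
        ).set_index("subset")
        e_cs = df.loc[[("CS",)], "wild_type_error"].iloc[0]
        e_cs_gapd = df.loc[[("CS", "GAPD_NAD")], "wild_type_error"].iloc[0]
        assert e_cs_gapd == pytest.approx(e_cs, abs=1e-9)

    def test_exhaustive_cap_enforced(self, toy):
        with pytest.raises(ValueError, match="cap"):
            stepwise_inclusion(
                toy.model, toy.enzyme_entries, lambda ec: {"x": 0.0},
                mode="exhaustive", exhaustive_cap=2,
            )


# ---------------------------------------------------------------------------
# FV comparison statistics
# ---------------------------------------------------------------------------


def _fva_result(fv: dict) -> FVAResult:
    frame = pd.DataFrame(
        {"minflux": 0.0, "maxflux": list(fv.values()), "fv": list(fv.values())},
        index=list(fv),
    )
    return FVAResult(frame, 0.9, 1.0)


def exact_signed_rank_p(diffs, alternative="greater"):
    """Brute-force Wilcoxon signed-rank tail probability (no ties/zeros)."""
    d = np.asarray(diffs, dtype=float)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append((ranks * np.array(signs)).sum())
    ws = np.array(ws)
    if alternative == "greater":
        return float(np.mean(ws >= w_obs))
    if alternative == "less":
        return float(np.mean(ws <= w_obs))
    return float(min(1.0, 2 * min(np.mean(ws >= w_obs), np.mean(ws <= w_obs))))


class TestCompareFV:
    def test_identical_inputs_all_unchanged(self):
        a = _fva_result({f"R{i}": float(i + 1) for i in range(8)})
        b = _fva_result({f"R{i}": float(i + 1) for i in range(8)})
        cmp = compare_fv(a, b)
        assert cmp.n_unchanged == 8 and cmp.n_reduced == 0 and cmp.n_increased == 0
        assert cmp.median_fold_change == pytest.approx(1.0)
        assert cmp.wilcoxon_pvalue == 1.0

    def test_halved_variability_detected(self):
        base = _fva_result({f"R{i}": float(i + 1) for i in range(8)})
        ec = _fva_result({f"R{i}": (i + 1) / 2.0 for i in range(8)})
        cmp = compare_fv(base, ec)
        assert cmp.n_reduced == 8
        assert cmp.fraction_reduced == 1.0
        assert cmp.median_fold_change == pytest.approx(2.0)
        # all 8 differences positive: one-sided exact p = 2^-8
        assert cmp.wilcoxon_pvalue == pytest.approx(1 / 256)
        assert cmp.wilcoxon_pvalue < 0.05

    def test_wilcoxon_agrees_with_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        for n in (6, 8, 10):
            fv_ec = rng.uniform(0.5, 2.0, n)
            diffs = rng.uniform(-1, 2, n)
            base = _fva_result({f"R{i}": fv_ec[i] + diffs[i] for i in range(n)})
            ec = _fva_result({f"R{i}": fv_ec[i] for i in range(n)})
            cmp = compare_fv(base, ec, atol=-1e-12, rtol=0)  # keep all pairs
            expected = exact_signed_rank_p(diffs, "greater")
            assert cmp.wilcoxon_pvalue == pytest.approx(expected, rel=1e-9)

    def test_major_reduction_cluster_threshold(self):
        base = _fva_result({"A": 100.0, "B": 10.0, "C": 1.0})
        ec = _fva_result({"A": 1.0, "B": 5.0, "C": 1.0})
        cmp = compare_fv(base, ec, reduction_threshold=10.0)
        assert cmp.major_reduction_cluster == ["A"]

    def test_real_toy_models_reduce_variability_at_matched_floor(self, toy):
        # same uptake bound and the same absolute growth requirement: the ec
        # solution space is then a subset of the base space, so no FV grows
        from ecgem.gecko import apply_enzyme_constraints
        from ecgem.simulation import fba, fva

        ec_same = apply_enzyme_constraints(toy.model, toy.enzyme_entries)
        ec = fva(ec_same.model, fraction=0.9)
        base = fva(toy.model, fraction=0.9 * ec.max_growth / fba(toy.model).objective_value)
        cmp = compare_fv(base, ec)
        assert cmp.n_increased == 0
        assert cmp.n_reduced > 0
        assert cmp.median_fv_ec <= cmp.median_fv_base


class TestEnrichment:
    def test_cluster_equal_universe_all_pvalues_one(self):
        universe = {f"R{i}" for i in range(10)}
        subs = {r: ("A" if i < 5 else "B") for i, r in enumerate(sorted(universe))}
        df = subsystem_enrichment(universe, universe, subs)
        assert (df["pvalue"] == 1.0).all()

    def test_two_by_two_table_against_tail_sum(self):
        # universe 20, subsystem 10, cluster 10, overlap 8
        universe = {f"R{i}" for i in range(20)}
        subs = {f"R{i}": ("S" if i < 10 else "other") for i in range(20)}
        cluster = {f"R{i}" for i in range(8)} | {"R15", "R16"}
        df = subsystem_enrichment(cluster, universe, subs)
        expected = sum(
            math.comb(10, k) * math.comb(10, 10 - k) for k in range(8, 11)
        ) / math.comb(20, 10)
        assert df.loc["S", "pvalue"] == pytest.approx(expected, rel=1e-12)

    def test_cluster_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            subsystem_enrichment({"X"}, {"Y"}, {})
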