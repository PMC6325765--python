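"""Model evaluation: prediction-error scoring against measured fluxes, gene
essentiality screening, kcat randomization, stepwise constraint inclusion,
and flux-variability comparison statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enzymes import EnzymeEntry
from .gecko import ECModel, apply_enzyme_constraints
from .model import FluxSolution, MetabolicModel, knockout
from .simulation import FVAResult, moma, pfba

__all__ = [
    "FluxMeasurementSet",
    "prediction_error",
    "EssentialityReport",
    "essentiality_screen",
    "RandomizationResult",
    "randomize_kcat",
    "stepwise_inclusion",
    "FVComparison",
    "compare_fv",
    "subsystem_enrichment",
    "ESSENTIALITY_GROWTH_THRESHOLD",
]

#: predicted growth below this rate (h^-1) calls a knockout lethal
ESSENTIALITY_GROWTH_THRESHOLD = 0.05


@dataclass
class FluxMeasurementSet:
    """Experimental fluxes keyed by model reaction id (mmol/gDW/h)."""

    values: dict[str, float]
    cv: dict[str, float] = field(default_factory=dict)
    condition: str = ""

    def reaction_ids(self) -> list[str]:
        return list(self.values)

    @classmethod
    def from_tsv(cls, path: str, condition: str = "") -> "FluxMeasurementSet":
        df = pd.read_csv(path, sep="\t")
        for col in ("reaction_id", "flux"):
            if col not in df.columns:
                raise ValueError(f"{path}: measurement table lacks column {col!r}")
        values = dict(zip(df["reaction_id"].astype(str), df["flux"].astype(float)))
        cv = (
            dict(zip(df["reaction_id"].astype(str), df["cv"].astype(float)))
            if "cv" in df.columns
            else {}
        )
        return cls(values, cv, condition)

    def to_tsv(self, path: str) -> None:
        df = pd.DataFrame(
            {
                "reaction_id": list(self.values),
                "flux": list(self.values.values()),
                "cv": [self.cv.get(r, np.nan) for r in self.values],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    def remapped(self, mapping: dict[str, tuple[str, float]]) -> "FluxMeasurementSet":
        """Rename measurement ids to model reaction ids with a sign factor.

        ``mapping``: measurement id -> (model reaction id, sign).  Useful when
        the flux study names reactions differently from the model.
        """
        values = {}
        cv = {}
        for mid, v in self.values.items():
            rid, sign = mapping.get(mid, (mid, 1.0))
            values[rid] = sign * v
            if mid in self.cv:
                cv[rid] = self.cv[mid]
        return FluxMeasurementSet(values, cv, self.condition)


def prediction_error(exp: FluxMeasurementSet, pred: FluxSolution | dict[str, float]) -> float:
    """Normalized Euclidean distance ‖exp − pred‖₂ / ‖exp‖₂.

    The distance runs over the measured reactions; every measured reaction
    must be present in the prediction (fluxes are matched by net reaction id).
    A prediction of all zeros — e.g. a no-growth mutant — scores exactly 1.
    """
    fluxes = pred.fluxes if isinstance(pred, FluxSolution) else pred
    ids = exp.reaction_ids()
    if not ids:
        raise ValueError("empty measurement set")
    missing = [r for r in ids if r not in fluxes]
    if missing:
        raise KeyError(f"measured reactions missing from the prediction: {sorted(missing)}")
    e = np.array([exp.values[r] for r in ids], dtype=float)
    p = np.array([fluxes[r] for r in ids], dtype=float)
    norm = np.linalg.norm(e)
    if norm == 0:
        raise ValueError("experimental flux vector has zero norm")
    return float(np.linalg.norm(e - p) / norm)


# ---------------------------------------------------------------------------
# Essentiality
# ---------------------------------------------------------------------------


@dataclass
class EssentialityReport:
    frame: pd.DataFrame  # index: gene; growth, predicted_essential, observed_essential, group
    threshold: float

    @property
    def predicted_essential(self) -> list[str]:
        return list(self.frame.index[self.frame["predicted_essential"]])

    def correct_calls(self, group: str | None = None) -> int:
        df = self.frame
        if group is not None:
            df = df[df["group"] == group]
        return int((df["predicted_essential"] & df["observed_essential"]).sum())

    def summary(self) -> pd.DataFrame:
        return (
            self.frame.groupby("group", dropna=False)
            .agg(
                n=("predicted_essential", "size"),
                predicted=("predicted_essential", "sum"),
                observed=("observed_essential", "sum"),
                correct=("correct", "sum"),
            )
        )


def essentiality_screen(
    model: MetabolicModel,
    genes: list[str],
    threshold: float = ESSENTIALITY_GROWTH_THRESHOLD,
    method: str = "moma",
    reference: FluxSolution | None = None,
    observed_essential: set[str] | None = None,
    groups: dict[str, str] | None = None,
) -> EssentialityReport:
    """Simulate single-gene knockouts and call essentiality.

    Each gene is knocked out through its GPR rules; the mutant is simulated by
    MoMA against the wild-type reference (default) or by pFBA, and called
    essential when predicted growth falls below ``threshold`` (h⁻¹).
    Unresolvable genes are reported with NaN growth rather than raised.
    """
    if method not in ("moma", "pfba"):
        raise ValueError(f"method must be 'moma' or 'pfba', got {method!r}")
    if method == "moma" and reference is None:
        reference = pfba(model)
    model_genes = set(model.genes) | {g for r in model.reactions for g in r.genes()}
    rows = []
    for gene in genes:
        if gene not in model_genes:
            rows.append((gene, np.nan, False))
            continue
        mutant = knockout(model, {gene})
        if method == "moma":
            sol = moma(mutant, reference)
        else:
            sol = pfba(mutant)
        growth = sol.objective_value if sol.status == "optimal" else 0.0
        if not np.isfinite(growth):
            growth = 0.0
        rows.append((gene, growth, growth < threshold))
    frame = pd.DataFrame(rows, columns=["gene", "growth", "predicted_essential"]).set_index("gene")
    obs = observed_essential or set()
    frame["observed_essential"] = [g in obs for g in frame.index]
    frame["correct"] = frame["predicted_essential"] & frame["observed_essential"]
    frame["group"] = [(groups or {}).get(g, "") for g in frame.index]
    return EssentialityReport(frame, threshold)


# ---------------------------------------------------------------------------
# kcat randomization
# ---------------------------------------------------------------------------


@dataclass
class RandomizationResult:
    errors: np.ndarray
    true_error: float
    n_infeasible: int

    @property
    def median(self) -> float:
        return float(np.median(self.errors))

    @property
    def true_percentile(self) -> float:
        """Percentile of the unshuffled model's error within the distribution."""
        return float(100.0 * np.mean(self.errors < self.true_error))


def _wild_type_error(
    model: MetabolicModel,
    entries: list[EnzymeEntry],
    exp: FluxMeasurementSet,
    release_uptake: str | None,
    uptake_bound: float,
) -> float | None:
    ec = apply_enzyme_constraints(model, entries, release_uptake, uptake_bound)
    sol = pfba(ec.model)
    if sol.status != "optimal":
        return None
    return prediction_error(exp, sol)


def randomize_kcat(
    model: MetabolicModel,
    entries: list[EnzymeEntry],
    exp: FluxMeasurementSet,
    n_perm: int = 10000,
    frozen: set[str] | None = None,
    seed: int = 0,
    release_uptake: str | None = None,
    uptake_bound: float = -100.0,
) -> RandomizationResult:
    """Prediction-error distribution under kcat shuffling.

    Each permutation reassigns the kcat values among the non-frozen entries
    (a draw without replacement; abundances stay with their reactions), the
    enzyme-constrained model is rebuilt, the wild type simulated by pFBA, and
    the prediction error scored.  A permuted model that cannot grow is scored
    as error 1 (the all-zero prediction limit) and counted as infeasible.
    """
    frozen = frozen or set()
    free = [e for e in entries if e.reaction_id not in frozen]
    if len(free) < 2:
        raise ValueError("need at least two non-frozen entries to permute")
    rng = np.random.default_rng(seed)
    true_error = _wild_type_error(model, entries, exp, release_uptake, uptake_bound)
    if true_error is None:
        raise RuntimeError("the unshuffled enzyme-constrained model is infeasible")
    kcats = np.array([e.kcat for e in free])
    errors = np.empty(n_perm)
    n_infeasible = 0
    for i in range(n_perm):
        perm = rng.permutation(len(free))
        shuffled = []
        for e in entries:
            if e.reaction_id in frozen:
                shuffled.append(e)
        for j, e in enumerate(free):
            shuffled.append(
                EnzymeEntry(
                    reaction_id=e.reaction_id,
                    gene=e.gene,
                    kcat=float(kcats[perm[j]]),
                    abundance=e.abundance,
                    ec_number=e.ec_number,
                    mw=e.mw,
                    abundance_is_fallback=e.abundance_is_fallback,
                )
            )
        err = _wild_type_error(model, shuffled, exp, release_uptake, uptake_bound)
        if err is None:
            errors[i] = 1.0
            n_infeasible += 1
        else:
            errors[i] = err
    return RandomizationResult(errors, true_error, n_infeasible)


# ---------------------------------------------------------------------------
# Stepwise constraint inclusion
# ---------------------------------------------------------------------------


def stepwise_inclusion(
    model: MetabolicModel,
    entries: list[EnzymeEntry],
    score: "callable[[ECModel | None], dict[str, float]]",
    mode: str = "greedy",
    exhaustive_cap: int = 16,
    release_uptake: str | None = None,
    uptake_bound: float = -100.0,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Score subsets of the enzyme constraints to find minimal sufficient sets.

    ``score`` maps an enzyme-constrained model (or None for the empty subset,
    i.e. the unconstrained model) to a dict of accuracy indices — e.g.
    wild-type prediction error, mutant error, essentiality accuracy.

    * exhaustive mode enumerates all 2^k subsets (k ≤ ``exhaustive_cap``),
    * greedy mode runs forward selection on the first score key.

    Returns one row per subset examined with all scores and a ``minimal``
    flag marking the smallest subsets whose every score matches the full
    model's within ``tol``.
    """
    if mode not in ("greedy", "exhaustive"):
        raise ValueError(f"mode must be 'greedy' or 'exhaustive', got {mode!r}")
    by_rid = {e.reaction_id: e for e in entries}
    rids = list(by_rid)

    def build_and_score(subset: tuple[str, ...]) -> dict[str, float]:
        if not subset:
            return score(None)
        ec = apply_enzyme_constraints(
            model, [by_rid[r] for r in subset], release_uptake, uptake_bound
        )
        return score(ec)

    rows: list[dict] = []

    def record(subset: tuple[str, ...]) -> dict[str, float]:
        s = build_and_score(subset)
        rows.append({"subset": subset, "size": len(subset), **s})
        return s

    full_scores = build_and_score(tuple(rids))
    record(())
    if mode == "exhaustive":
        if len(rids) > exhaustive_cap:
            raise ValueError(
                f"exhaustive mode over {len(rids)} entries exceeds the cap "
                f"({exhaustive_cap}); use greedy mode or raise the cap"
            )
        for k in range(1, len(rids) + 1):
            for subset in itertools.combinations(rids, k):
                record(subset)
    else:
        current: tuple[str, ...] = ()
        key = next(iter(full_scores))
        while len(current) < len(rids):
            best, best_val, best_scores = None, None, None
            for r in rids:
                if r in current:
                    continue
                s = record(tuple(sorted(current + (r,))))
                if best_val is None or s[key] < best_val:
                    best, best_val, best_scores = r, s[key], s
            current = tuple(sorted(current + (best,)))
            if all(abs(best_scores[k2] - full_scores[k2]) <= tol for k2 in full_scores):
                break

    df = pd.DataFrame(rows).drop_duplicates(subset="subset")
    score_keys = [k for k in df.columns if k not in ("subset", "size")]
    achieves = df[score_keys].apply(
        lambda row: all(abs(row[k] - full_scores[k]) <= tol for k in score_keys), axis=1
    )
    df["achieves_full"] = achieves
    min_size = df.loc[achieves, "size"].min() if achieves.any() else np.nan
    df["minimal"] = achieves & (df["size"] == min_size)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Flux variability comparison
# ---------------------------------------------------------------------------


@dataclass
class FVComparison:
    frame: pd.DataFrame  # fv_base, fv_ec, fold_reduction, change
    n_reduced: int
    n_increased: int
    n_unchanged: int
    median_fv_base: float
    median_fv_ec: float
    median_fold_change: float
    wilcoxon_statistic: float
    wilcoxon_pvalue: float
    reduction_threshold: float

    @property
    def major_reduction_cluster(self) -> list[str]:
        return list(self.frame.index[self.frame["major_reduction"]])

    @property
    def fraction_reduced(self) -> float:
        n = self.n_reduced + self.n_increased + self.n_unchanged
        return self.n_reduced / n if n else float("nan")


def compare_fv(
    base: FVAResult,
    ec: FVAResult,
    reduction_threshold: float = 10.0,
    atol: float = 1e-9,
    rtol: float = 1e-6,
    alternative: str = "greater",
) -> FVComparison:
    """Compare per-reaction flux variability between two models.

    Restricted to reactions (shared namespace) with non-zero FV in either
    model: counts reduced/increased/unchanged, the ratio of median FVs, a
    paired Wilcoxon signed-rank test (one-sided by default: base FV exceeds
    enzyme-constrained FV), and the "major reduction" cluster of reactions
    whose FV shrinks by at least ``reduction_threshold``-fold.
    """
    shared = [r for r in base.frame.index if r in set(ec.frame.index)]
    fb = base.frame.loc[shared, "fv"]
    fe = ec.frame.loc[shared, "fv"]
    nonzero = (fb > atol) | (fe > atol)
    fb, fe = fb[nonzero], fe[nonzero]
    tol = atol + rtol * np.maximum(fb, fe)
    reduced = (fb - fe) > tol
    increased = (fe - fb) > tol
    unchanged = ~(reduced | increased)
    with np.errstate(divide="ignore"):
        fold = np.where(fe > atol, fb / np.maximum(fe, atol), np.inf)
    frame = pd.DataFrame(
        {
            "fv_base": fb,
            "fv_ec": fe,
            "fold_reduction": fold,
            "change": np.where(reduced, "reduced", np.where(increased, "increased", "unchanged")),
            "major_reduction": reduced & (fold >= reduction_threshold),
        }
    )
    diffs = (fb - fe).to_numpy()
    if np.allclose(diffs, 0.0):
        stat, p = 0.0, 1.0
    else:
        method = "exact" if len(diffs) <= 25 else "auto"
        res = stats.wilcoxon(diffs, alternative=alternative, method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    med_b, med_e = float(np.median(fb)), float(np.median(fe))
    return FVComparison(
        frame=frame,
        n_reduced=int(reduced.sum()),
        n_increased=int(increased.sum()),
        n_unchanged=int(unchanged.sum()),
        median_fv_base=med_b,
        median_fv_ec=med_e,
        median_fold_change=med_b / med_e if med_e > 0 else float("inf"),
        wilcoxon_statistic=stat,
        wilcoxon_pvalue=p,
        reduction_threshold=reduction_threshold,
    )


def subsystem_enrichment(
    cluster: set[str],
    universe: set[str],
    subsystems: dict[str, str],
) -> pd.DataFrame:
    """One-sided Fisher's exact (hypergeometric) over-representation test.

    For each subsystem: P(X ≥ k) where k is the number of cluster reactions in
    the subsystem, drawing |cluster| reactions from the universe without
    replacement.  Raw p-values are reported; a Benjamini–Hochberg column is
    included for convenience.
    """
    cluster = set(cluster)
    universe = set(universe)
    if not cluster <= universe:
        raise ValueError("cluster must be a subset of the universe")
    N, n = len(universe), len(cluster)
    rows = []
    for sub in sorted({subsystems.get(r, "") for r in universe}):
        members = {r for r in universe if subsystems.get(r, "") == sub}
        K = len(members)
        k = len(members & cluster)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"subsystem": sub, "in_cluster": k, "in_universe": K, "pvalue": p})
    df = pd.DataFrame(rows).set_index("subsystem").sort_values("pvalue")
    m = len(df)
    ranked = df["pvalue"].rank(method="first")
    bh = (df["pvalue"] * m / ranked)[::-1].cummin()[::-1]
    df["pvalue_bh"] = np.minimum(1.0, bh)
    return df
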