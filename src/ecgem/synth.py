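"""Desk-scale synthetic fixtures: a central-carbon toy network with an
analytically known optimum, noisy flux "measurements", and synthetic
proteomics.

The toy mirrors the topology of *B. subtilis* central carbon metabolism as a
carbon-skeleton network (no ATP/NAD bookkeeping): glucose uptake, glycolysis,
the pentose phosphate pathway (oxidative branch plus a reversible
transketolase lump), the TCA cycle with an OXGDC/SSALy 2-oxoglutarate→succinate
bypass, acetate and lactate overflow branches, a glutamate/γ-PGA branch, and a
lumped biomass reaction.  Reaction ids are upper-case, metabolite ids
lower-case, as in iYO844.

Because biomass is the only drain and every precursor has a unique parsimonious
route, the wild-type pFBA solution is a fixed per-growth-unit coefficient
vector scaled by the growth rate, and the growth rate is the minimum over the
binding capacity constraints — so the generator can record an exact analytic
ground truth alongside the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enzymes import DEFAULT_ABUNDANCE_FLOOR, EnzymeEntry, ProteomicsRecord, ProteomicsRecords, gdw_to_cell
from .evaluation import FluxMeasurementSet
from .model import FluxSolution, MetabolicModel, Metabolite, Reaction

__all__ = ["ToySpec", "ToyFixture", "make_toy_model", "make_flux_measurements", "make_proteomics"]

#: default "true" enzymatic capacities (mmol/gDW/h) of the toy's constrained
#: reactions: CS binds wild-type growth, OXGDC is the undetectable-enzyme
#: bypass entry (detection-floor abundance), G6PDH is latent (binds only when
#: glycolysis is cut), GAPD_NAD and PGI are slack.
_DEFAULT_CAPACITIES = {
    "CS": 1.5,
    "GAPD_NAD": 12.0,
    "PGI": 20.0,
    "G6PDH": 0.5,
    "OXGDC": 0.2 * 3600.0 * DEFAULT_ABUNDANCE_FLOOR,
}

_TOY_KCATS = {  # s^-1, loosely following the curated central-carbon values
    "CS": 49.0,
    "GAPD_NAD": 70.0,
    "PGI": 126.0,
    "G6PDH": 174.0,
    "OXGDC": 0.2,
}
_TOY_GENES = {"CS": "citZ", "GAPD_NAD": "gapA", "PGI": "pgi", "G6PDH": "zwf", "OXGDC": "menD"}
_TOY_MW = {"citZ": 41.6, "gapA": 35.8, "pgi": 50.5, "zwf": 55.0, "menD": 63.0}

#: reactions with no alternative route in the toy; capacities on these scale
#: growth analytically (caps elsewhere would trigger rerouting and void the
#: closed-form ground truth)
_OBLIGATE = {
    "GLCt", "HEX1", "GAPD_NAD", "PYK", "PDH", "PYC",
    "CS", "ACONT", "ICDHy", "GLUDy",
}


@dataclass
class ToySpec:
    seed: int = 0
    ppp: bool = True
    overflow: bool = True
    pga_branch: bool = True
    bypass: bool = True
    glucose_uptake: float = 10.0  # mmol/gDW/h cap on the base model's uptake
    capacities: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_CAPACITIES))
    noise_cv: float = 0.10


@dataclass
class ToyFixture:
    model: MetabolicModel
    truth: FluxSolution  # analytic wild-type pFBA optimum under the true caps
    enzyme_entries: list[EnzymeEntry]
    spec: ToySpec
    per_growth_coefficients: dict[str, float]
    mu_true: float
    mu_unconstrained: float


def _toy_reactions(spec: ToySpec) -> list[Reaction]:
    R = Reaction
    big = 1000.0
    rxns = [
        R("EX_glc_e", {"glc_e": -1}, -spec.glucose_uptake, 0.0, "", "Exchange"),
        R("GLCt", {"glc_e": -1, "glc": 1}, 0, big, "ptsG", "Transport"),
        R("HEX1", {"glc": -1, "g6p": 1}, 0, big, "glcK", "Glycolysis"),
        R("PGI", {"g6p": -1, "f6p": 1}, -big, big, "pgi", "Glycolysis"),
        R("PFK", {"f6p": -1, "g3p": 2}, 0, big, "pfkA", "Glycolysis"),
        R("GAPD_NAD", {"g3p": -1, "pep": 1}, 0, big, "gapA", "Glycolysis"),
        R("PYK", {"pep": -1, "pyr": 1}, 0, big, "pyk", "Glycolysis"),
        R("PDH", {"pyr": -1, "accoa": 1, "co2": 1}, 0, big, "pdhA and pdhB and pdhC and pdhD", "Glycolysis"),
        R("PYC", {"pyr": -1, "co2": -1, "oaa": 1}, 0, big, "pycA", "Anaplerosis"),
        R("CS", {"accoa": -1, "oaa": -1, "cit": 1}, 0, big, "citZ or citA", "TCA cycle"),
        R("ACONT", {"cit": -1, "icit": 1}, 0, big, "citB", "TCA cycle"),
        R("ICDHy", {"icit": -1, "akg": 1, "co2": 1}, 0, big, "icd", "TCA cycle"),
        R("AKGD", {"akg": -1, "succoa": 1, "co2": 1}, 0, big, "odhA and odhB and pdhD", "TCA cycle"),
        R("SUCOAS", {"succoa": -1, "succ": 1}, -big, big, "sucC and sucD", "TCA cycle"),
        R("SUCD1", {"succ": -1, "fum": 1}, 0, big, "sdhA and sdhB and sdhC", "TCA cycle"),
        R("FUM", {"fum": -1, "mal": 1}, 0, big, "citG", "TCA cycle"),
        R("MDH", {"mal": -1, "oaa": 1}, 0, big, "mdh", "TCA cycle"),
        R("EX_co2_e", {"co2": -1}, 0, big, "", "Exchange"),
    ]
    if spec.ppp:
        rxns += [
            R("G6PDH", {"g6p": -1, "ru5p": 1, "co2": 1}, 0, big, "zwf", "Pentose phosphate"),
            R("TKT", {"ru5p": -3, "f6p": 2, "g3p": 1}, -big, big, "tkt", "Pentose phosphate"),
        ]
    if spec.overflow:
        rxns += [
            R("PTAr", {"accoa": -1, "actp": 1}, 0, big, "pta", "Overflow"),
            R("ACKr", {"actp": -1, "ac": 1}, 0, big, "ackA", "Overflow"),
            R("EX_ac_e", {"ac": -1}, 0, big, "", "Exchange"),
            R("LDH_L", {"pyr": -1, "lac": 1}, -big, big, "ldh", "Overflow"),
            R("EX_lac_e", {"lac": -1}, 0, big, "", "Exchange"),
        ]
    if spec.bypass:
        rxns += [
            R("OXGDC", {"akg": -1, "sucsal": 1, "co2": 1}, 0, big, "menD", "Bypass"),
            R("SSALy", {"sucsal": -1, "succ": 1}, 0, big, "gabD", "Bypass"),
        ]
    if spec.pga_branch:
        rxns += [
            R("GLUDy", {"akg": -1, "glu_l": 1}, 0, big, "gudB or rocG", "Glutamate"),
            R("GLUR", {"glu_l": -1, "glu_d": 1}, -big, big, "racE", "Glutamate"),
        ]
    biomass = {"g6p": -0.3, "g3p": -0.3, "pyr": -0.5, "accoa": -0.4, "succoa": -0.2, "oaa": -0.3}
    if spec.ppp:
        biomass["ru5p"] = -0.2
    if spec.pga_branch:
        biomass["glu_l"] = -0.3
    rxns.append(R("BIOMASS", biomass, 0, big, "", "Biomass"))
    return rxns


def _per_growth_coefficients(spec: ToySpec) -> dict[str, float]:
    """Parsimonious flux per unit growth, derived by demand cascade."""
    glu = 0.3 if spec.pga_branch else 0.0
    succoa = 0.2
    akg = glu + succoa
    accoa = 0.4 + akg  # biomass + citrate synthesis
    oaa = 0.3 + akg
    pyr = 0.5 + accoa + oaa  # biomass + PDH + PYC
    ru5p = 0.2 if spec.ppp else 0.0
    gapd = pyr  # PEP demand
    g3p = gapd + 0.3 + ru5p / 3.0  # + biomass + transketolase reverse
    pfk = g3p / 2.0
    f6p = pfk + 2.0 * ru5p / 3.0
    g6p = f6p + 0.3
    co2_out = accoa + akg + succoa - oaa  # PDH + ICDHy + AKGD - PYC
    coef = {
        "EX_glc_e": -g6p,
        "GLCt": g6p,
        "HEX1": g6p,
        "PGI": f6p,
        "PFK": pfk,
        "GAPD_NAD": gapd,
        "PYK": pyr,
        "PDH": accoa,
        "PYC": oaa,
        "CS": akg,
        "ACONT": akg,
        "ICDHy": akg,
        "AKGD": succoa,
        "SUCOAS": 0.0,
        "SUCD1": 0.0,
        "FUM": 0.0,
        "MDH": 0.0,
        "EX_co2_e": co2_out,
        "BIOMASS": 1.0,
    }
    if spec.ppp:
        coef["G6PDH"] = 0.0
        coef["TKT"] = -ru5p / 3.0
    if spec.overflow:
        coef.update({"PTAr": 0.0, "ACKr": 0.0, "EX_ac_e": 0.0, "LDH_L": 0.0, "EX_lac_e": 0.0})
    if spec.bypass:
        coef.update({"OXGDC": 0.0, "SSALy": 0.0})
    if spec.pga_branch:
        coef.update({"GLUDy": glu, "GLUR": 0.0})
    return coef


def make_toy_model(spec: ToySpec | None = None) -> ToyFixture:
    """Build the toy network, its true enzyme entries and the analytic optimum.

    The returned ``truth`` is the wild-type parsimonious flux distribution of
    the network under the spec's true enzymatic capacities — the "reality"
    that synthetic measurements are drawn from.  The returned ``model`` is the
    *unconstrained* reconstruction (capacities not applied), i.e. the analog of
    a plain genome-scale model before enzymatic-data integration.
    """
    spec = spec or ToySpec()
    rxns = _toy_reactions(spec)
    met_ids: dict[str, None] = {}
    for r in rxns:
        for mid in r.stoichiometry:
            met_ids.setdefault(mid)
    mets = [Metabolite(m, compartment="e" if m.endswith("_e") else "c") for m in met_ids]
    genes = sorted({g for r in rxns for g in r.genes()})
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        objective_reaction_id="BIOMASS",
        id="toy_cc",
    )
    model.validate()

    coef = _per_growth_coefficients(spec)
    mu_unconstrained = spec.glucose_uptake / coef["GLCt"]
    mu = mu_unconstrained
    for rid, cap in spec.capacities.items():
        c = coef.get(rid, 0.0)
        if c <= 0:
            continue
        if rid not in _OBLIGATE:
            if cap < c * mu:
                raise ValueError(
                    f"capacity on {rid} would force rerouting; analytic ground "
                    f"truth is only defined for caps on {sorted(_OBLIGATE)}"
                )
            continue
        mu = min(mu, cap / c)
    if mu <= 0:
        raise ValueError("contradictory toggles/capacities: no positive growth")
    truth = FluxSolution(
        {rid: c * mu for rid, c in coef.items()}, mu, "optimal",
        meta={"analytic": True},
    )

    entries = []
    for rid, cap in spec.capacities.items():
        if not model.has_reaction(rid):
            continue
        kcat = _TOY_KCATS.get(rid, 100.0)
        gene = _TOY_GENES.get(rid) or sorted(model.get_reaction(rid).genes())[0]
        abundance = cap / (kcat * 3600.0)
        entries.append(
            EnzymeEntry(
                reaction_id=rid,
                gene=gene,
                kcat=kcat,
                abundance=abundance,
                mw=_TOY_MW.get(gene, 50.0),
                abundance_is_fallback=abs(abundance - DEFAULT_ABUNDANCE_FLOOR) < 1e-15,
            )
        )
    return ToyFixture(model, truth, entries, spec, coef, mu, mu_unconstrained)


def make_flux_measurements(
    model: MetabolicModel,
    truth: FluxSolution,
    cv: float = 0.10,
    seed: int = 0,
    reactions: list[str] | None = None,
) -> FluxMeasurementSet:
    """Noisy replicate-style measurements: flux × (1 + ε), ε ~ N(0, cv).

    Multiplicative Gaussian noise matches how replicate variability is
    reported (a coefficient of variation); draws that would flip the sign of
    a flux are clipped to zero.  By default every reaction carrying non-zero
    true flux is "measured".
    """
    if cv < 0:
        raise ValueError(f"cv must be non-negative, got {cv}")
    rng = np.random.default_rng(seed)
    if reactions is None:
        reactions = [r for r, v in truth.fluxes.items() if abs(v) > 1e-9]
    values = {}
    for rid in reactions:
        v = truth.fluxes[rid]
        noisy = v * (1.0 + rng.normal(0.0, cv))
        if v > 0:
            noisy = max(0.0, noisy)
        elif v < 0:
            noisy = min(0.0, noisy)
        values[rid] = noisy
    return FluxMeasurementSet(values, cv={r: cv for r in reactions}, condition=f"synthetic_cv{cv}")


def make_proteomics(
    genes: list[str],
    true_abundance: dict[str, float],
    ci_width: float = 0.2,
    detection_floor: float = DEFAULT_ABUNDANCE_FLOOR,
    seed: int = 0,
) -> ProteomicsRecords:
    """Synthetic absolute proteomics (molecules/cell) with 95% CI upper limits.

    ``true_abundance`` is given in mmol/gDW; records are emitted in
    molecules/cell (the raw instrument scale).  The measured mean deviates
    from truth by at most ci_width/2 (relative), and the CI upper limit sits
    ci_width/2 above the mean, so a cap built from the CI upper limit stays
    within ~ci_width of the true capacity.  Genes whose true abundance falls
    below the detection floor are omitted, exercising the fallback path.
    """
    if detection_floor <= 0:
        raise ValueError("detection_floor must be positive")
    rng = np.random.default_rng(seed)
    records = ProteomicsRecords()
    half = ci_width / 2.0
    for gene in genes:
        true = true_abundance[gene]
        if true < detection_floor:
            continue
        eps = float(np.clip(rng.normal(0.0, half / 2.0), -half, half))
        mean = gdw_to_cell(true) * (1.0 + eps)
        records.add(ProteomicsRecord(gene, mean, mean * (1.0 + half)))
    return records
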