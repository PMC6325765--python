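#!/usr/bin/env python
"""Full-scale analysis on the iYO844 genome-scale model of B. subtilis.

Requires a locally downloaded iYO844 model (e.g. the BiGG SBML distribution);
nothing is fetched from the network.  Builds the enzyme-constrained variant
from the packaged curated table, then reports:

* wild-type pFBA growth and glucose uptake (uptake released to -100),
* flux-variability comparison between the plain and constrained models
  (count of non-zero-FV reactions, fraction reduced, median-FV fold change),
* the single- and double-reaction MoMA deletion scan for gamma-PGA.

Usage:
    python scripts/run_iyo844.py --model iYO844.xml [--out results_iyo844]
"""

from __future__ import annotations

import argparse
import json
import os


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--model", required=True, help="path to iYO844 SBML or JSON")
    ap.add_argument("--out", default="results_iyo844")
    ap.add_argument("--glucose-exchange", default="EX_glc__D_e")
    ap.add_argument("--fva-fraction", type=float, default=0.9)
    ap.add_argument("--max-deletions", type=int, default=1, choices=[1, 2])
    args = ap.parse_args()

    from ecgem.design import add_pga_pathway, scan_deletions
    from ecgem.enzymes import load_enzyme_table
    from ecgem.evaluation import compare_fv
    from ecgem.gecko import apply_enzyme_constraints
    from ecgem.io import read_model
    from ecgem.simulation import fva, pfba

    os.makedirs(args.out, exist_ok=True)
    model = read_model(args.model)
    entries = load_enzyme_table("table1")
    ec = apply_enzyme_constraints(
        model, entries, release_uptake=args.glucose_exchange, uptake_bound=-100.0
    )

    summary: dict = {}
    sol = pfba(ec.model)
    summary["ec_growth_per_h"] = sol.objective_value
    summary["ec_glucose_uptake_mmol_gdw_h"] = -sol.fluxes[args.glucose_exchange]

    released = model.copy()
    released.get_reaction(args.glucose_exchange).lower_bound = -100.0
    base_fva = fva(released, fraction=args.fva_fraction)
    ec_fva = fva(ec.model, fraction=args.fva_fraction)
    cmp = compare_fv(base_fva, ec_fva)
    summary["n_nonzero_fv"] = cmp.n_reduced + cmp.n_increased + cmp.n_unchanged
    summary["fraction_fv_reduced"] = cmp.fraction_reduced
    summary["median_fv_fold_change"] = cmp.median_fold_change
    summary["wilcoxon_pvalue"] = cmp.wilcoxon_pvalue
    base_fva.to_tsv(os.path.join(args.out, "fva_base.tsv"))
    ec_fva.to_tsv(os.path.join(args.out, "fva_ec.tsv"))

    for label, m in (("base", model), ("ec", ec.model)):
        design_model = add_pga_pathway(
            m, glu_d_id="glu__D_c", glu_l_id="glu__L_c", pga_id="pga_c"
        )
        ref = pfba(design_model)
        scan = scan_deletions(
            design_model, "EX_pga_e", ref, max_size=args.max_deletions
        )
        scan.to_tsv(os.path.join(args.out, f"designs_{label}.tsv"))
        top = scan.ranked[:5]
        summary[f"top_designs_{label}"] = [
            {
                "deleted": list(d.deleted),
                "growth": d.predicted_growth,
                "pga_flux": d.predicted_target_flux,
            }
            for d in top
        ]

    with open(os.path.join(args.out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    print(json.dumps(summary, indent=1))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
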