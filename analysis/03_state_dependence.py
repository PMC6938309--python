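"""Unadjusted screening and state-dependence tests.

For each covariate entering the stratum models, fits the unadjusted
single-covariate transition model (onset and remission hazard ratios with
95% CIs) and tests state-dependence — whether the covariate's effect on
future AUD differs by current state — via a 1-df likelihood-ratio test of
beta_onset = -beta_remission. Covariates with p > 0.20 are flagged for the
state-independence constraint in the adjusted models.
"""

import argparse
import json
import warnings
from pathlib import Path

from audtrans import stratify_by_age, build_transition_pairs
from audtrans.cli import _load_cohort
from audtrans.workflow import (
    WorkflowConfig,
    combine_covariates,
    screen_unadjusted,
    select_constraints,
    test_state_dependence,
)
from audtrans.descriptives import contrast_table


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    warnings.simplefilter("ignore")
    cohort = _load_cohort(args.outdir / "cohort.csv", args.outdir / "cohort.schema.yaml")
    config = WorkflowConfig()
    raw_names = list(cohort.schema.names)
    cohort = combine_covariates(cohort, "dep_anx", ("anxiety", "depression"))
    pairs = build_transition_pairs(cohort)

    decisions = {}
    for name, sp in stratify_by_age(pairs).items():
        rows = contrast_table(sp, raw_names)
        by = {r.covariate: r for r in rows}
        screened = [c for c in raw_names if c not in config.always_include
                    and (by[c].significant_onset or by[c].significant_remission)]
        model_covs = list(config.always_include)
        if "anxiety" in screened or "depression" in screened:
            model_covs.append("dep_anx")
        model_covs += [c for c in screened if c not in ("anxiety", "depression")]

        table = screen_unadjusted(sp, model_covs, seed=args.seed)
        results = [test_state_dependence(sp, c, seed=args.seed) for c in model_covs]
        table["state_dependence_p"] = [r.p for r in results]
        table.to_csv(args.outdir / f"table2_{name}.csv", index=False)
        constraints = select_constraints(results, config.state_dependence_threshold)
        decisions[name] = {"model_covariates": model_covs, "constraints": sorted(constraints)}
        print(f"{name}: model covariates {model_covs}")
        for r in results:
            tag = "constrain" if r.covariate in constraints else "free"
            print(f"  {r.covariate:24s} LRT p = {r.p:.3f} -> {tag}")
    with open(args.outdir / "constraints.json", "w") as fh:
        json.dump(decisions, fh, indent=2)


if __name__ == "__main__":
    main()
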