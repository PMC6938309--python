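"""Descriptive analysis of the cohort.

Counts assessments and AUD diagnoses, tabulates the four transition-pair
types per age stratum, summarises any-AUD prevalence by sex and age band
(with a grouped bar chart), and writes the Table-1-style contrasts that
later gate model entry.
"""

import argparse
from pathlib import Path

from audtrans import build_transition_pairs, stratify_by_age
from audtrans.cli import _load_cohort
from audtrans.descriptives import (
    contrast_frame,
    contrast_table,
    plot_prevalence,
    prevalence_any_aud,
    tabulate_transitions,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    cohort = _load_cohort(args.outdir / "cohort.csv", args.outdir / "cohort.schema.yaml")

    df = cohort.data
    print(f"{len(df)} diagnostic assessments, {df['state'].sum()} AUD diagnoses "
          f"({100 * df['state'].mean():.1f}% of person/time points)")
    prev = prevalence_any_aud(cohort)
    overall = prev[prev["sex"] == "all"].iloc[0]
    print(f"{overall['n_any_aud']} subjects ({100 * overall['proportion']:.1f}%) "
          "with an AUD diagnosis at ≥1 assessment")
    prev.to_csv(args.outdir / "prevalence.csv", index=False)
    plot_prevalence(prev, args.outdir / "prevalence.png")

    pairs = build_transition_pairs(cohort)
    for name, sp in stratify_by_age(pairs).items():
        t = tabulate_transitions(sp)
        print(f"{name}: {len(sp)} pairs; onset {t.loc[0, 1]}, remission {t.loc[1, 0]}")
        t.to_csv(args.outdir / f"transitions_{name}.csv")
        rows = contrast_table(sp, cohort.schema.names)
        contrast_frame(rows).to_csv(args.outdir / f"table1_{name}.csv", index=False)
        sig = [r.covariate for r in rows if r.significant_onset or r.significant_remission]
        print(f"  significant pair-type contrasts: {sig}")


if __name__ == "__main__":
    main()
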