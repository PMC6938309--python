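"""Draw the synthetic study cohort.

Generates a cohort emulating the emergency-department panel design (599
drug-using youth, baseline + four biannual follow-ups, 16.3% per-wave
attrition) with transition dynamics governed by the published adjusted
hazard ratios, and writes it in long format for the later stages.
"""

import argparse
from pathlib import Path

from audtrans import generate_cohort, write_panel
from audtrans.presets import study_spec


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = generate_cohort(study_spec(), seed=args.seed)
    args.outdir.mkdir(parents=True, exist_ok=True)
    out = args.outdir / "cohort.csv"
    write_panel(cohort, out)
    cohort.schema.to_yaml(args.outdir / "cohort.schema.yaml")

    n_follow = (cohort.data.groupby("subject_id")["time"].transform("min")
                != cohort.data["time"]).sum()
    print(f"wrote {out}: {cohort.n_subjects} subjects, {cohort.n_observations} assessments")
    print(f"follow-up retention: {100 * n_follow / (cohort.n_subjects * 4):.1f}% "
          f"(design target ≥83.7%)")


if __name__ == "__main__":
    main()
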