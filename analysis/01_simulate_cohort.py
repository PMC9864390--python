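#!/usr/bin/env python
"""Simulate the synthetic outpatient EMR cohort used by the downstream steps.

Writes the three interchange CSVs plus ground_truth.csv to a work directory
(default scratch/cohort, kept out of version control because the raw tables
are large) and a small planted-class summary to results/.
"""

import argparse
from collections import Counter
from pathlib import Path

import pandas as pd

from si_pheno import StudyConfig, write_emr
from si_pheno.synthetic_emr import ScenarioConfig, generate_cohort, truths_to_frame

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n", type=int, default=20_000)
    ap.add_argument("--seed", type=int, default=2017)
    ap.add_argument("--latent-fraction", type=float, default=0.5)
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "cohort")
    args = ap.parse_args()

    scenario = ScenarioConfig(
        n_patients=args.n, seed=args.seed, latent_si_given_low_conf=args.latent_fraction
    )
    records, truths = generate_cohort(scenario, StudyConfig())
    write_emr(records, args.out)
    truths_to_frame(truths).to_csv(args.out / "ground_truth.csv", index=False)

    counts = Counter(t.planted_class for t in truths)
    latent = sum(t.latent_intolerant for t in truths)
    summary = pd.DataFrame(
        sorted(counts.items()), columns=["planted_class", "count"]
    )
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    summary.to_csv(results / "planted_class_counts.csv", index=False)
    print(f"wrote {len(records)} patients to {args.out}")
    print(summary.to_string(index=False))
    print(f"latent intolerant patients: {latent}")


if __name__ == "__main__":
    main()
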