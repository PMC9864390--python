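#!/usr/bin/env python
"""Build the patient-level feature matrix and rank features by mutual
information with the intolerant-vs-tolerant target.

Writes the full MI ranking to results/feature_mi_scores.csv and prints the
top of the ranking, which should be dominated by statin-exposure shape,
visit counts, muscle-symptom code groups and lipid-therapy classes.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from si_pheno import StudyConfig, build_features, read_emr_dir, select_features
from si_pheno.experiments import classify_generated

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "scratch" / "cohort")
    ap.add_argument("--k", type=int, default=400)
    args = ap.parse_args()

    config = StudyConfig()
    records, _ = read_emr_dir(args.data, config)
    entries, _, results, _ = classify_generated(records, config)
    matrix = build_features(records, entries, config)
    labels = np.array([r.label != "tolerant" for r in results], dtype=int)
    selection = select_features(matrix, labels, k=args.k)

    ranking = pd.DataFrame(
        {
            "feature": selection.selected,
            "mi_nats": [selection.scores[f] for f in selection.selected],
            "kind": [matrix.feature_kinds[f] for f in selection.selected],
        }
    )
    results_dir = ROOT / "results"
    results_dir.mkdir(exist_ok=True)
    ranking.to_csv(results_dir / "feature_mi_scores.csv", index=False)
    print(f"feature matrix: {matrix.values.shape[0]} patients x {matrix.values.shape[1]} features")
    print(f"selected {len(selection.selected)} features; top 12 by MI:")
    print(ranking.head(12).to_string(index=False))


if __name__ == "__main__":
    main()
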