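#!/usr/bin/env python
"""Histology scoring analysis and its relation to joint friction.

Aggregates the per-plateau consensus scores of the synthetic study into
per-joint category scores and totals (maximum 11), runs the two-way
genotype x treatment ANOVA per category and total, and computes the
Spearman correlation between each joint's final CoF and its total score.

Writes per-response ANOVA and cell-mean tables plus correlation.csv under
results/study_analysis/.
"""

from pathlib import Path

from jointcof.io import read_study_tables
from jointcof.stats import aggregate_joint_scores, anova_histology, correlate_cof_histology
from jointcof.study import generate_study

ROOT = Path(__file__).resolve().parents[1] / "results"
STUDY = ROOT / "study"
OUT = ROOT / "study_analysis"


def main():
    if (STUDY / "cof.csv").exists():
        dataset = read_study_tables(STUDY / "cof.csv", STUDY / "histology.csv")
    else:
        dataset = generate_study(seed=20260930)
    joint_scores = aggregate_joint_scores(dataset.histology)
    OUT.mkdir(parents=True, exist_ok=True)
    joint_scores.to_csv(OUT / "joint_scores.csv", index=False)
    tables = anova_histology(joint_scores)
    for resp, t in tables.items():
        t["anova"].to_csv(OUT / f"anova_{resp}.csv")
        t["cells"].to_csv(OUT / f"cells_{resp}.csv", index=False)
        p = t["anova"].loc["C(genotype)", "PR(>F)"]
        print(f"{resp:10s}: genotype main effect p = {p:.3g}")
    correlation = correlate_cof_histology(dataset, joint_scores)
    correlation.to_csv(OUT / "correlation.csv", index=False)
    print("\nfinal CoF vs total histology score (Spearman):")
    print(correlation.to_string(index=False))
    print(f"tables written to {OUT}")
    print("finding: genotype dominates the structural scores, and within a "
          "genotype the friction level of a joint does not predict its "
          "histology -- the scores and the friction chain are generated "
          "independently given genotype and loading.")


if __name__ == "__main__":
    main()
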