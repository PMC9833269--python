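#!/usr/bin/env python
"""Coronary-artery-calcium burden versus score quartile, and event comparisons.

In the control cohort: CAC category distribution (0 / 1-99 / 100-400 / >400),
the zero-CAC fraction, and the age/sex-adjusted logistic model of CAC >= 100
on 12-SNP score quartile.  In the FH cohorts: chi-square comparisons of
simulated event frequencies.
"""

import argparse
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from fhprs.association import group_compare, logistic_quartile_or, quantile_labels
from fhprs.panel import Group
from fhprs.phenotype import categorize_cac, read_phenotypes
from fhprs.scoring import read_score_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    scores = read_score_table(args.out / "scores_control.tsv")
    pheno = read_phenotypes(args.out / "cohorts" / "control" / "phenotypes.tsv")
    data = scores.join(pheno, how="inner").dropna(subset=["cac", "prs12"])

    categories = Counter(categorize_cac(c).value for c in data["cac"])
    total = len(data)
    print("control CAC categories: "
          + ", ".join(f"{k} {categories.get(k, 0)} ({100 * categories.get(k, 0) / total:.1f}%)"
                      for k in ("ZERO", "LOW", "MODERATE", "SEVERE")))
    print(f"zero-CAC fraction: {categories.get('ZERO', 0) / total:.3f}")

    high = (data["cac"] >= 100).to_numpy()
    quart = quantile_labels(data["prs12"].to_numpy(), 4)
    res = logistic_quartile_or(high, quart, data["age"], data["sex"])
    rows = []
    print("\nCAC >= 100 vs 12-SNP score quartile (age/sex adjusted):")
    for k, orr in res.quartile_or.items():
        rows.append({"term": f"Q{k}", "or": orr.or_, "ci_low": orr.ci_low,
                     "ci_high": orr.ci_high, "p_value": orr.p_value})
        print(f"  Q{k} vs Q1: OR {orr.or_:.2f} (95% CI {orr.ci_low:.2f}-"
              f"{orr.ci_high:.2f}, p = {orr.p_value:.3g})")
    for name, orr in (("trend", res.trend_or), ("age", res.age_or),
                      ("male", res.sex_or)):
        rows.append({"term": name, "or": orr.or_, "ci_low": orr.ci_low,
                     "ci_high": orr.ci_high, "p_value": orr.p_value})
    print(f"  trend per quartile: OR {res.trend_or.or_:.2f} "
          f"(95% CI {res.trend_or.ci_low:.2f}-{res.trend_or.ci_high:.2f})")
    pd.DataFrame(rows).to_csv(args.out / "cac_quartile_or.tsv", sep="\t",
                              index=False, float_format="%.6g")

    # simulated event comparisons between the FH groups
    print("\nevent comparisons, FH mutation-negative vs mutation-positive:")
    frames = {g: read_phenotypes(args.out / "cohorts" / g.value.lower()
                                 / "phenotypes.tsv")
              for g in (Group.FH_M_NEG, Group.FH_M_POS)}
    for event in ("mi", "stroke", "revasc"):
        table = []
        for g, frame in frames.items():
            yes = int(frame[event].fillna(False).astype(bool).sum())
            table.append([yes, len(frame) - yes])
        res = group_compare(table=table)
        print(f"  {event}: {table[0][0]}/{sum(table[0])} vs "
              f"{table[1][0]}/{sum(table[1])}, chi-square p = {res.p_value:.3g}")


if __name__ == "__main__":
    main()
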