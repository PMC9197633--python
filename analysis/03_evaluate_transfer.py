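#!/usr/bin/env python
"""Fit the winning subset-sum model and validate it on the second cohort.

Takes the rank-1 subset from the search output (or an explicit
``--subset``), fits total ~ subset-sum on the training cohort, and
reports: the conversion equation, EVS/PCC/SRC on both cohorts with
bootstrap percentile intervals and overlap verdicts, the mean-residual
(unbiasedness) intervals, Bland-Altman agreement, and the conditional
distribution of the total per subset-sum value. Tables land in
results/report/.
"""

import argparse
from pathlib import Path

import pandas as pd

from updrs_abbrev import (
    ItemSet,
    bland_altman,
    build_registry,
    conditional_distribution,
    fit_sum_model,
    load_assessments,
    transfer_evaluate,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--train", type=Path, default=ROOT / "results" / "train.csv")
    ap.add_argument("--val", type=Path, default=ROOT / "results" / "val.csv")
    ap.add_argument("--ranked", type=Path,
                    default=ROOT / "results" / "ranked_remote.tsv")
    ap.add_argument("--subset", default=None,
                    help="comma-joined item ids; overrides --ranked")
    ap.add_argument("--bootstrap", type=int, default=2000)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "report")
    args = ap.parse_args()

    registry = build_registry()
    if args.subset:
        subset = ItemSet.parse(args.subset)
    else:
        ranked = pd.read_csv(args.ranked, sep="\t")
        subset = ItemSet.parse(ranked.loc[0, "item_ids"])
    registry.validate_subset(subset)

    train = load_assessments(args.train, registry, provenance="training")
    val = load_assessments(args.val, registry, provenance="validation")
    model = fit_sum_model(train, subset)
    print(f"subset: {subset}")
    print(f"conversion model: y = {model.slope:.2f}x + {model.intercept:.2f} "
          f"(n = {model.n_fit})")

    report = transfer_evaluate(model, subset, train, val,
                               n_boot=args.bootstrap, seed=args.seed)
    args.out.mkdir(parents=True, exist_ok=True)
    rows = []
    for cohort, ivs in (("training", report.train_intervals),
                        ("validation", report.validation_intervals)):
        for metric, iv in ivs.items():
            rows.append({"cohort": cohort, "metric": metric,
                         "point": iv.point, "lower": iv.lower,
                         "upper": iv.upper, "overlap": report.overlap[metric]})
            print(f"{cohort:>10} {metric:>13}: {iv.point:+.3f} "
                  f"[{iv.lower:+.3f}, {iv.upper:+.3f}]"
                  + ("  (intervals overlap)" if report.overlap[metric] else ""))
    pd.DataFrame(rows).to_csv(args.out / "metrics.tsv", sep="\t", index=False)

    for cohort, table, rs in (("training", train, report.train_residuals),
                              ("validation", val, report.validation_residuals)):
        rs.residuals_by_actual.to_csv(
            args.out / f"residual_bands_{cohort}.tsv", sep="\t", index=False)
        y = table.total_scores().to_numpy()
        pred = model.predict(table.subset_sums(subset).to_numpy())
        agr = bland_altman(y, pred)
        print(f"{cohort}: mean residual {rs.mean_residual:+.2f}, "
              f"skewness {rs.skewness:+.2f}, Bland-Altman LoA "
              f"[{agr.loa_lower:+.1f}, {agr.loa_upper:+.1f}]")
        cond = conditional_distribution(table, subset)
        cond.table.to_csv(args.out / f"conditional_{cohort}.tsv",
                          sep="\t", index=False)
    print(f"tables written to {args.out}")


if __name__ == "__main__":
    main()
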