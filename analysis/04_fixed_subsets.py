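#!/usr/bin/env python
"""Score externally specified 8-item subsets against the synthetic cohort.

Evaluates the two published optimal subsets (the remote-constrained and
the unconstrained winners) and any ``--subset`` the user supplies on the
training cohort, reporting EVS/PCC/SRC and the correlation between the
two published subsets' sums. On synthetic data these numbers
characterise the generator, not the real instrument; the same command
against a real export reproduces the published comparisons.
"""

import argparse
from pathlib import Path

from scipy import stats as sps

from updrs_abbrev import (
    ItemSet,
    build_registry,
    evaluate_fixed_subset,
    load_assessments,
    named_subset,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--train", type=Path, default=ROOT / "results" / "train.csv")
    ap.add_argument("--subset", action="append", default=[],
                    help="extra comma-joined item ids (repeatable)")
    args = ap.parse_args()

    registry = build_registry()
    table = load_assessments(args.train, registry, provenance="training")

    candidates = {
        "remote_optimal (published)": named_subset("remote_optimal"),
        "any_item_optimal (published)": named_subset("any_item_optimal"),
    }
    for text in args.subset:
        candidates[text] = ItemSet.parse(text)

    for label, subset in candidates.items():
        m = evaluate_fixed_subset(table, subset)
        print(f"{label}: EVS={m.evs:.3f} PCC={m.pcc:.3f} SRC={m.src:.3f}")

    a = table.subset_sums(named_subset("remote_optimal"))
    b = table.subset_sums(named_subset("any_item_optimal"))
    print("correlation between the two published subsets' sums: "
          f"PCC={sps.pearsonr(a, b).statistic:.3f} "
          f"SRC={sps.spearmanr(a, b).statistic:.3f}")


if __name__ == "__main__":
    main()
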