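#!/usr/bin/env python
"""Exhaustively rank k-item subsets of the training cohort by explained variance.

Searches the remote-practicality pool (42 items, C(42,8) = 118,030,185
subsets) by default; ``--pool any`` searches all 50 items
(C(50,8) = 536,878,650 — roughly a ten-minute desk job; use
``--checkpoint`` to make it resumable). Writes the top-ranked subsets
and the item-occurrence table under results/ and prints the winner.
"""

import argparse
from pathlib import Path

from updrs_abbrev import (
    SearchConfig,
    build_registry,
    candidate_pool,
    compute_suffstats,
    exhaustive_search,
    item_occurrence,
    load_assessments,
    subset_count,
)
from updrs_abbrev.subset_search import write_occurrence, write_ranked

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--train", type=Path, default=ROOT / "results" / "train.csv")
    ap.add_argument("--pool", choices=["remote", "any"], default="remote")
    ap.add_argument("--k", type=int, default=8)
    ap.add_argument("--top-k", type=int, default=100_000)
    ap.add_argument("--write-top", type=int, default=1000,
                    help="ranked rows to write to TSV")
    ap.add_argument("--checkpoint", type=Path, default=None)
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    registry = build_registry()
    table = load_assessments(args.train, registry, provenance="training")
    pool = candidate_pool(registry, "remote" if args.pool == "remote" else "any_item")
    print(f"pool: {args.pool} ({len(pool)} items); "
          f"{subset_count(len(pool), args.k):,} subsets to evaluate")

    stats = compute_suffstats(table, registry)
    results = exhaustive_search(stats, SearchConfig(
        pool=pool, k=args.k, top_k=args.top_k, checkpoint_dir=args.checkpoint,
    ))

    args.out.mkdir(parents=True, exist_ok=True)
    top = results.results[: args.write_top]
    trimmed = type(results)(results=top, pool=results.pool, k=results.k,
                            n_evaluated=results.n_evaluated,
                            predictor_mode=results.predictor_mode)
    write_ranked(trimmed, args.out / f"ranked_{args.pool}.tsv")
    occ = item_occurrence(results, min(args.top_k, len(results)))
    write_occurrence(occ, args.out / f"occurrence_{args.pool}.tsv")

    best = results.best
    print(f"evaluated {results.n_evaluated:,} subsets")
    print(f"rank 1: {best.subset}  EVS = {best.evs:.3f}")
    print("most frequent items in the top "
          f"{min(args.top_k, len(results)):,} subsets:")
    for _, row in occ.head(8).iterrows():
        print(f"  {row['item_id']:>5}  {row['fraction']:.1%}")


if __name__ == "__main__":
    main()
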