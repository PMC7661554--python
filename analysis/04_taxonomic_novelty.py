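#!/usr/bin/env python
"""Taxonomic novelty of the proteolytic guild and SusC substrate classes.

Applies the 16S rank thresholds (86.5% family / 94.5% genus) and the ~60%
AAI family cutoff to the pairwise identity tables, and places each SusC
transporter gene in the substrate cluster of its nearest labeled
reference. Requires the community from 01_simulate_community.py.
"""

import argparse
import json
from pathlib import Path

from aadeg.pipeline import RunConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--community", type=Path,
                    default=Path("results/community"))
    ap.add_argument("--out", type=Path, default=Path("results/novelty"))
    args = ap.parse_args()
    if not (args.community / "qc.tsv").exists():
        raise SystemExit(f"no community at {args.community}; "
                         "run analysis/01_simulate_community.py first")

    bundle = run_pipeline(RunConfig.for_community_dir(
        args.community, out_dir=str(args.out), stages=("novelty",)))

    print("16S rank calls:")
    for row in bundle["novelty_16s"].itertuples():
        print(f"  {row.query_id}: best identity {row.best_identity}% "
              f"-> {row.rank_call}")
    print("AAI family calls:")
    for row in bundle["novelty_aai"].itertuples():
        print(f"  {row.query_id}: best AAI {row.best_identity}% "
              f"-> {row.rank_call}")

    susc = bundle["susc_clusters"]
    truth = json.loads((args.community / "ground_truth.json").read_text())
    frac = (susc.cluster_label == "polypeptide").mean()
    ok = sum(
        (label == "polypeptide") == (truth["susc_clusters"][q] == "polypeptide")
        for q, label in zip(susc.query_id, susc.cluster_label)
        if q in truth["susc_clusters"])
    print(f"SusC genes in the polypeptide cluster: {frac:.0%} "
          f"({ok}/{len(susc)} match the planted class)")
    print(f"tables written to {args.out}")


if __name__ == "__main__":
    main()
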