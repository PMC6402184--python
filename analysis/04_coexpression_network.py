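#!/usr/bin/env python
"""Build the differential lincRNA x differential mRNA coexpression network.

Pearson correlation on per-sample log2(RPKM + 0.1) profiles, screened at
|r| >= 0.85; the p-value is reported but plays no role in screening.
Writes the edge list, degree summary and a SIF export.
"""

import argparse

from cernet.coexpression import edge_sign_counts
from cernet.pipeline import load_config, run_stage


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", default="results/run")
    args = ap.parse_args()

    cfg = load_config(seed=args.seed, outdir=args.out)
    edges = run_stage("coexpr", cfg)

    counts = edge_sign_counts(edges)
    print(f"network: {counts['total']} edges "
          f"({counts['positive']} positive + {counts['negative']} negative) "
          f"over {edges['lincRNA'].nunique()} lincRNAs and "
          f"{edges['mRNA'].nunique()} mRNAs")
    strongest = edges.loc[edges["r"].abs().idxmax()]
    print(f"strongest edge: {strongest.lincRNA} - {strongest.mRNA} "
          f"(r = {strongest.r:.3f})")


if __name__ == "__main__":
    main()
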