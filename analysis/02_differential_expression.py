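#!/usr/bin/env python
"""Call differential expression with the Audic-Claverie count test.

Pools the five libraries per group, tests each feature, converts p to BH
q-values per class, and screens at |log2FC| >= 1 with q < 0.001
(lncRNA/mRNA) or q < 0.05 (miRNA).  Writes de_table.tsv and reports call
counts against the planted truth.
"""

import argparse

from cernet import io as cio
from cernet.pipeline import load_config, run_stage


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", default="results/run")
    args = ap.parse_args()

    cfg = load_config(seed=args.seed, outdir=args.out)
    table = run_stage("de", cfg)

    hit = table[table["direction"] != "ns"]
    print("differential calls per class:")
    print(hit.groupby(["class", "direction"]).size().to_string())
    truth = cio.read_yaml(f"{args.out}/truth.yaml")
    planted, called = set(truth["de"]), set(hit["feature"])
    tp = len(planted & called)
    print(f"\nsensitivity {tp / len(planted):.3f}, "
          f"empirical FDR {len(called - planted) / max(len(called), 1):.3f} "
          f"against {len(planted)} planted features")
    top = table.iloc[0]
    print(f"strongest call: {top.feature} ({top.direction}, "
          f"fold change {top.fold_change:.2f}, q = {top.q:.3g})")


if __name__ == "__main__":
    main()
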