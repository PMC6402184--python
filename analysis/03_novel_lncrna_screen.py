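#!/usr/bin/env python
"""Run the five-gate novel-lncRNA filter cascade on the candidate set.

Gates, in order: known-annotation overlap, length >= 200 nt, longest ORF
< 300 nt, protein-domain motif screen, coding-potential score < -1.
Writes novel_verdicts.tsv with the first failing gate per candidate.
"""

import argparse

from cernet.pipeline import load_config, run_stage


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", default="results/run")
    args = ap.parse_args()

    cfg = load_config(seed=args.seed, outdir=args.out)
    verdicts = run_stage("novel", cfg)

    print(verdicts[["transcript_id", "length_nt", "longest_orf_nt",
                    "cp_score", "verdict"]].to_string(index=False))
    novel = verdicts[verdicts["verdict"] == "novel_lncRNA"]
    print(f"\n{len(novel)} of {len(verdicts)} candidates pass all five gates")


if __name__ == "__main__":
    main()
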