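"""lincRNA target prediction: the cis 10-kb window and trans base pairing.

Cis targets are coding genes whose interval intersects the lincRNA interval
extended by the window (10 kb by default) on either side, strand-agnostic.
Trans targets are scored by the best local complementarity alignment
between the lincRNA and the reverse of the mRNA (so antiparallel pairing
becomes a standard local alignment), with pair scores GC +3, AU +2, GU +1,
mismatch -4 and a linear gap penalty of -6.  The scoring scheme and the
default acceptance threshold of 60 (roughly a 20-30 nt strong duplex) are
explicit, configurable stand-ins: no published scheme exists for this step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ConfigError
from .seq import as_rna

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 10_000
DEFAULT_TRANS_THRESHOLD = 60.0


@dataclass
class TransScoring:
    gc: float = 3.0
    au: float = 2.0
    gu: float = 1.0
    mismatch: float = -4.0
    gap: float = -6.0


def _aligner(scoring: TransScoring) -> Align.PairwiseAligner:
    m = substitution_matrices.Array("ACGU", dims=2)
    pair_scores = {
        ("G", "C"): scoring.gc, ("C", "G"): scoring.gc,
        ("A", "U"): scoring.au, ("U", "A"): scoring.au,
        ("G", "U"): scoring.gu, ("U", "G"): scoring.gu,
    }
    for a in "ACGU":
        for b in "ACGU":
            m[a, b] = pair_scores.get((a, b), scoring.mismatch)
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = m
    al.open_gap_score = scoring.gap
    al.extend_gap_score = scoring.gap
    return al


def cis_neighbors(linc: pd.Series, genes: pd.DataFrame,
                  window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Coding genes intersecting [start - window, end + window] on the same
    chromosome (1-based closed coordinates, strand-agnostic).

    Returns rows (lincRNA, gene, gap_bp); gap is 0 for overlap, otherwise
    the minimum distance between the two intervals.
    """
    if window < 0:
        raise ConfigError("window must be non-negative")
    coding = genes[genes["biotype"] == "protein_coding"]
    same = coding[coding["chrom"] == linc["chrom"]]
    lo, hi = linc["start"] - window, linc["end"] + window
    hit = same[(same["start"] <= hi) & (same["end"] >= lo)]
    # endpoint distance (0 for overlap): gene at linc_end + w is gap w, the
    # outermost interval still inside the window
    gap = np.maximum(
        0, np.maximum(hit["start"] - linc["end"], linc["start"] - hit["end"])
    )
    return pd.DataFrame(
        {"lincRNA": linc["feature_id"], "gene": hit["feature_id"], "gap_bp": gap}
    ).reset_index(drop=True)


def trans_score(linc_seq: str, mrna_seq: str,
                scoring: TransScoring | None = None
                ) -> tuple[float, tuple | None]:
    """Best local complementarity score and the matched regions.

    The region is ((linc_start, linc_end), (mrna_start, mrna_end)) in
    0-based half-open coordinates on the ORIGINAL sequences; None when the
    best score is 0 (no complementary stretch at all).
    """
    if not linc_seq or not mrna_seq:
        return 0.0, None
    scoring = scoring or TransScoring()
    al = _aligner(scoring)
    linc = as_rna(linc_seq)
    mrna_rev = as_rna(mrna_seq)[::-1]
    score = al.score(linc, mrna_rev)
    if score <= 0:
        return 0.0, None
    aln = al.align(linc, mrna_rev)[0]
    (l0, l1) = aln.aligned[0][0][0], aln.aligned[0][-1][1]
    (r0, r1) = aln.aligned[1][0][0], aln.aligned[1][-1][1]
    n = len(mrna_rev)
    return float(score), ((int(l0), int(l1)), (n - int(r1), n - int(r0)))


def predict_targets(
    lincs: pd.DataFrame,
    genes: pd.DataFrame,
    linc_seqs: dict[str, str],
    mrna_seqs: dict[str, str],
    de_mrnas: set[str] | None = None,
    window: int = DEFAULT_WINDOW,
    trans_threshold: float = DEFAULT_TRANS_THRESHOLD,
    scoring: TransScoring | None = None,
) -> pd.DataFrame:
    """Union of cis and trans lincRNA-gene links.

    The candidate gene universe is restricted to ``de_mrnas`` when given
    (the differential-mRNA restriction); pass None to lift it.  Links found
    by both modes collapse to one row with mode 'cis+trans' and both
    evidences kept.
    """
    if de_mrnas is not None:
        genes = genes[genes["feature_id"].isin(de_mrnas)]
        mrna_seqs = {k: v for k, v in mrna_seqs.items() if k in de_mrnas}

    records: dict[tuple[str, str], dict] = {}
    for _, linc in lincs.iterrows():
        for row in cis_neighbors(linc, genes, window).itertuples(index=False):
            records[(row.lincRNA, row.gene)] = {
                "lincRNA": row.lincRNA, "gene": row.gene, "mode": "cis",
                "gap_bp": int(row.gap_bp), "score": np.nan, "region": "",
            }
    for lid in lincs["feature_id"]:
        if lid not in linc_seqs:
            logger.warning("no sequence for lincRNA %s; trans skipped", lid)
            continue
        for gid, gseq in mrna_seqs.items():
            score, region = trans_score(linc_seqs[lid], gseq, scoring)
            if score >= trans_threshold:
                key = (lid, gid)
                if key in records:
                    records[key]["mode"] = "cis+trans"
                    records[key]["score"] = score
                    records[key]["region"] = _fmt_region(region)
                else:
                    records[key] = {
                        "lincRNA": lid, "gene": gid, "mode": "trans",
                        "gap_bp": pd.NA, "score": score,
                        "region": _fmt_region(region),
                    }
    table = pd.DataFrame(
        sorted(records.values(), key=lambda r: (r["lincRNA"], r["gene"])),
        columns=["lincRNA", "gene", "mode", "gap_bp", "score", "region"],
    )
    return table


def _fmt_region(region) -> str:
    if region is None:
        return ""
    (l0, l1), (m0, m1) = region
    return f"linc:{l0}-{l1};mrna:{m0}-{m1}"
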