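"""ceRNA network assembly: miRNA site prediction, consensus voting, triads.

Three in-repo predictors stand in for the external tool ensembles whose
votes the combination logic preserves: a canonical seed-match rule
(TargetScan-style site classes), a simplified nearest-neighbour
hybridisation energy (RNAhybrid-style), and an AU-context accessibility
proxy (PITA-style).  lncRNA-miRNA edges require >= 2 of 3 votes,
miRNA-mRNA edges >= 3 of 3, mirroring ensemble-of-software consensus
prediction.  Triads join the two edge sets on the shared miRNA; strict mode
keeps only direction patterns consistent with competing-endogenous-RNA
logic, sign(lncRNA) = sign(mRNA) = -sign(miRNA).

All predictor thresholds are explicit, configurable stand-ins; none claims
fidelity to any specific external tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError, DomainError
from .seq import as_rna, is_pair, is_wc, revcomp

logger = logging.getLogger(__name__)

SITE_RANK = {"8mer": 4, "7mer-m8": 3, "7mer-A1": 2, "6mer": 1, "none": 0}

#: Watson-Crick nearest-neighbour stack energies (kcal/mol), keyed by the
#: guide-strand dinucleotide (the paired strand is implied).  The 16 keys
#: collapse to 10 unique values under strand symmetry.
STACK_ENERGY = {
    "AA": -0.93, "UU": -0.93,
    "AU": -1.10,
    "UA": -1.33,
    "CA": -2.11, "UG": -2.11,
    "CU": -2.08, "AG": -2.08,
    "GA": -2.35, "UC": -2.35,
    "GU": -2.24, "AC": -2.24,
    "CG": -2.36,
    "GC": -3.42,
    "GG": -3.26, "CC": -3.26,
}
GU_PENALTY = 1.0
INTERNAL_LOOP_PENALTY = 3.0
BULGE_PENALTY = 3.5


def classify_seed_site(mirna: str, window8: str) -> str:
    """Site class of an 8-nt target window opposite miRNA positions 1-8.

    The window runs 5'->3' on the target, so window position 8 sits
    opposite miRNA position 1.  Seed matching is strict Watson-Crick (GU
    wobble does not count); the position-1 adenine is an identity
    requirement, not a pairing one.
    """
    mirna = as_rna(mirna)
    window8 = as_rna(window8)
    if len(mirna) < 8:
        raise DomainError("miRNA must be at least 8 nt")
    if len(window8) != 8:
        raise DomainError("site window must be exactly 8 nt")

    def match(p: int) -> bool:  # p = miRNA position, 1-based
        return is_wc(window8[8 - p], mirna[p - 1])

    m2_7 = all(match(p) for p in range(2, 8))
    m8 = match(8)
    a1 = window8[7] == "A"
    if m2_7 and m8 and a1:
        return "8mer"
    if m2_7 and m8:
        return "7mer-m8"
    if m2_7 and a1:
        return "7mer-A1"
    if m2_7:
        return "6mer"
    return "none"


def scan_seed_sites(mirna: str, transcript: str) -> list[tuple[int, str]]:
    """All seed sites (>= 6mer) in a transcript: (0-based position, type).

    Overlapping sites are allowed; positions index the 8-nt window start.
    """
    mirna = as_rna(mirna)
    transcript = as_rna(transcript)
    sites = []
    for i in range(len(transcript) - 7):
        stype = classify_seed_site(mirna, transcript[i:i + 8])
        if stype != "none":
            sites.append((i, stype))
    return sites


def duplex_energy(mirna: str, site_region: str) -> float:
    """Minimum free energy of the miRNA/site duplex (kcal/mol, <= 0).

    Dynamic programme over antiparallel base pairs (Watson-Crick or GU):
    adjacent pairs add the nearest-neighbour stack energy of the guide
    dinucleotide, each GU pair costs +1.0, an internal loop +3.0 and a
    bulge +3.5 regardless of size.  Any helix of >= 2 stacked Watson-Crick
    pairs therefore scores below zero; structures that cannot reach a
    negative energy report 0.0.
    """
    if not site_region or not mirna:
        return 0.0
    g = as_rna(mirna)
    t = as_rna(site_region)[::-1]  # antiparallel -> parallel indexing
    n, m = len(g), len(t)

    pairs = [(i, j) for i in range(n) for j in range(m) if is_pair(g[i], t[j])]
    best = 0.0
    # M[(i, j)] = best energy of a structure whose 3'-most pair is (i, j)
    M: dict[tuple[int, int], float] = {}
    for i, j in pairs:  # pairs are in lexicographic order, so predecessors done
        pen = GU_PENALTY if not is_wc(g[i], t[j]) else 0.0
        e = pen  # start a fresh helix
        for (i2, j2), prev in M.items():
            if i2 >= i or j2 >= j:
                continue
            if i2 == i - 1 and j2 == j - 1:
                link = STACK_ENERGY[g[i - 1] + g[i]]
            elif i2 == i - 1 or j2 == j - 1:
                link = BULGE_PENALTY
            else:
                link = INTERNAL_LOOP_PENALTY
            e = min(e, prev + link + pen)
        M[(i, j)] = e
        best = min(best, e)
    return best


def au_context(transcript: str, position: int, site_len: int = 8,
               flank: int = 30) -> float:
    """A/U fraction of the sequence flanking a site, truncated at the ends."""
    transcript = as_rna(transcript)
    if not 0 <= position <= len(transcript) - site_len:
        raise DomainError("site lies outside the transcript")
    left = transcript[max(0, position - flank):position]
    right = transcript[position + site_len:position + site_len + flank]
    flanks = left + right
    if not flanks:
        return 0.0
    return sum(b in "AU" for b in flanks) / len(flanks)


def consensus_vote(votes, k: int) -> bool:
    """True iff at least k of the predictor votes are positive."""
    if k < 1:
        raise ConfigError("k must be >= 1")
    if k > len(votes):
        raise ConfigError("k exceeds the number of predictors")
    return sum(bool(v) for v in votes) >= k


@dataclass
class PredictorThresholds:
    """Stand-in predictor gates (all invented, all configurable).

    Defaults are calibrated so that on uniform-random 1.5-kb transcripts the
    2-of-3 consensus fires on < 1% of miRNA-transcript pairs and the 3-of-3
    consensus on ~0%, while planted near-full-complement sites always pass.
    """

    seed_min_rank: int = 2        # >= 7mer-A1 for the seed predictor
    energy_max: float = -25.0     # kcal/mol for the energy predictor
    context_min_rank: int = 1     # >= 6mer for the context predictor
    context_min_au: float = 0.7
    flank: int = 30


def predict_bindings(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    k: int,
    thresholds: PredictorThresholds | None = None,
) -> pd.DataFrame:
    """Score every miRNA x transcript pair with the three predictors.

    Returns one row per pair with individual votes, the k-of-3 consensus,
    and the best site's position, type and energy.  The best site is the
    highest-ranked class, ties broken by lower energy then position.
    """
    th = thresholds or PredictorThresholds()
    rows = []
    for tid, tseq in transcripts.items():
        tseq = as_rna(tseq)
        for mid, mseq in mirnas.items():
            mseq = as_rna(mseq)
            sites = scan_seed_sites(mseq, tseq)
            scored = []
            for pos, stype in sites:
                region = tseq[max(0, pos + 8 - len(mseq)):pos + 8]
                scored.append(
                    (SITE_RANK[stype], -duplex_energy(mseq, region), -pos,
                     pos, stype)
                )
            if scored:
                rank, neg_energy, _, pos, stype = max(scored)
                energy = -neg_energy
                au = au_context(tseq, pos, flank=th.flank)
            else:
                rank, energy, au, pos, stype = 0, 0.0, 0.0, -1, "none"
            votes = (
                rank >= th.seed_min_rank,
                energy <= th.energy_max,
                rank >= th.context_min_rank and au >= th.context_min_au,
            )
            rows.append(
                {
                    "transcript": tid, "mirna": mid,
                    "vote_seed": votes[0], "vote_energy": votes[1],
                    "vote_context": votes[2],
                    "consensus": consensus_vote(votes, k),
                    "site_position": pos, "site_type": stype,
                    "energy": energy,
                }
            )
    return pd.DataFrame(rows)


def assemble_triads(
    de_table: pd.DataFrame,
    lnc_mir_edges: pd.DataFrame,
    mir_mrna_edges: pd.DataFrame,
    mode: str = "strict",
) -> pd.DataFrame:
    """Join consensus edge sets on the shared miRNA into ceRNA triads.

    Only differentially expressed members survive (dangling ids are dropped
    with a log entry).  Strict mode additionally requires
    sign(lncRNA) = sign(mRNA) = -sign(miRNA); permissive keeps every join.
    Output is deduplicated and deterministically sorted.
    """
    if mode not in ("strict", "permissive"):
        raise ConfigError(f"unknown mode {mode!r}")
    direction = dict(zip(de_table["feature"], de_table["direction"]))

    def de_dir(fid):
        d = direction.get(fid)
        return d if d in ("up", "down") else None

    lnc = lnc_mir_edges[lnc_mir_edges["consensus"]]
    mrna = mir_mrna_edges[mir_mrna_edges["consensus"]]
    rows = []
    for le in lnc.itertuples(index=False):
        ld, md = de_dir(le.transcript), de_dir(le.mirna)
        if ld is None or md is None:
            logger.info("dropping edge with non-DE member: %s-%s",
                        le.transcript, le.mirna)
            continue
        for me in mrna[mrna["mirna"] == le.mirna].itertuples(index=False):
            gd = de_dir(me.transcript)
            if gd is None:
                logger.info("dropping edge with non-DE member: %s-%s",
                            me.mirna, me.transcript)
                continue
            if mode == "strict" and not (ld == gd and ld != md):
                continue
            rows.append(
                {
                    "lncRNA": le.transcript, "miRNA": le.mirna,
                    "mRNA": me.transcript,
                    "lnc_dir": ld, "mir_dir": md, "mrna_dir": gd,
                }
            )
    triads = pd.DataFrame(
        rows, columns=["lncRNA", "miRNA", "mRNA",
                       "lnc_dir", "mir_dir", "mrna_dir"]
    ).drop_duplicates()
    return triads.sort_values(
        ["lncRNA", "miRNA", "mRNA"], kind="stable"
    ).reset_index(drop=True)


def planted_site_window(mirna: str) -> str:
    """Reverse complement of miRNA positions 2-8 plus a 3' A: the canonical
    8mer window (used by tests and documentation examples)."""
    return revcomp(as_rna(mirna)[1:8]) + "A"
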