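"""cis window queries and trans complementarity scoring."""

import numpy as np
import pandas as pd
import pytest

from cernet.errors import ConfigError
from cernet.seq import revcomp
from cernet.targets import (TransScoring, cis_neighbors, predict_targets,
                            trans_score)

COLS = ["feature_id", "chrom", "start", "end", "strand", "biotype"]


def _feat(fid, start, end, chrom="chr1", strand="+", biotype="protein_coding"):
    return pd.Series(dict(zip(COLS, [fid, chrom, start, end, strand, biotype])))


def _table(rows):
    return pd.DataFrame(rows, columns=COLS)


def smith_waterman_oracle(a, b, scoring=TransScoring()):
    """Independent textbook local-alignment DP (linear gap)."""
    pair = {("G", "C"): scoring.gc, ("C", "G"): scoring.gc,
            ("A", "U"): scoring.au, ("U", "A"): scoring.au,
            ("G", "U"): scoring.gu, ("U", "G"): scoring.gu}
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = pair.get((a[i - 1], b[j - 1]), scoring.mismatch)
            H[i][j] = max(0.0, H[i - 1][j - 1] + s,
                          H[i - 1][j] + scoring.gap, H[i][j - 1] + scoring.gap)
            best = max(best, H[i][j])
    return best


class TestCisNeighbors:
    def test_gene_just_inside_window(self):
        linc = _feat("L", 5000, 6000, biotype="lincRNA")
        genes = _table([("G", "chr1", 15900, 17000, "+", "protein_coding")])
        hits = cis_neighbors(linc, genes, window=10_000)
        assert list(hits["gene"]) == ["G"]
        assert hits["gap_bp"].iloc[0] == 9900  # 15900 - 6000

    def test_gene_just_outside_window(self):
        linc = _feat("L", 5000, 6000)
        genes = _table([("G", "chr1", 16500, 17000, "+", "protein_coding")])
        assert cis_neighbors(linc, genes, window=10_000).empty

    def test_overlap_gives_zero_gap(self):
        linc = _feat("L", 5000, 6000)
        genes = _table([("G", "chr1", 5500, 7000, "-", "protein_coding")])
        assert cis_neighbors(linc, genes)["gap_bp"].iloc[0] == 0

    def test_other_chromosome_and_noncoding_excluded(self):
        linc = _feat("L", 5000, 6000)
        genes = _table([
            ("G1", "chr2", 5000, 6000, "+", "protein_coding"),
            ("G2", "chr1", 5000, 6000, "+", "lincRNA"),
        ])
        assert cis_neighbors(linc, genes).empty

    def test_negative_window_rejected(self):
        with pytest.raises(ConfigError):
            cis_neighbors(_feat("L", 1, 2), _table([]), window=-1)

    def test_matches_brute_force_on_random_placements(self, rng):
        for _ in range(200):
            ls, gs = rng.integers(1, 50_000, size=2)
            linc = _feat("L", ls, ls + int(rng.integers(100, 2000)))
            gene_rows = []
            for g in range(8):
                s = int(rng.integers(1, 60_000))
                gene_rows.append((f"G{g}", "chr1", s,
                                  s + int(rng.integers(100, 3000)),
                                  "+", "protein_coding"))
            genes = _table(gene_rows)
            window = int(rng.choice([0, 1000, 10_000]))
            got = set(cis_neighbors(linc, genes, window)["gene"])
            expected = set()
            for fid, _, s, e, _, _ in gene_rows:
                # brute force: explicit min distance between closed intervals
                if e < linc["start"]:
                    dist = linc["start"] - e
                elif s > linc["end"]:
                    dist = s - linc["end"]
                else:
                    dist = 0
                if dist <= window:
                    expected.add(fid)
            assert got == expected


class TestTransScore:
    def test_perfect_gc_duplex(self):
        linc = "G" * 30
        mrna = "C" * 30  # reverse complement of the lincRNA
        score, region = trans_score(linc, mrna)
        assert score == 90.0
        assert region == ((0, 30), (0, 30))

    def test_no_complementarity_floors_at_zero(self):
        assert trans_score("A" * 20, "A" * 20) == (0.0, None)

    def test_score_symmetric_under_argument_swap(self, rng):
        from cernet.seq import random_rna
        for _ in range(10):
            a, b = random_rna(rng, 40), random_rna(rng, 55)
            assert trans_score(a, b)[0] == trans_score(b, a)[0]

    def test_matches_exhaustive_dp_on_short_sequences(self, rng):
        from cernet.seq import random_rna
        for _ in range(40):
            a = random_rna(rng, int(rng.integers(4, 13)))
            b = random_rna(rng, int(rng.integers(4, 13)))
            assert trans_score(a, b)[0] == smith_waterman_oracle(a, b[::-1])

    def test_planted_complement_region_located(self, rng):
        from cernet.seq import random_rna
        mrna = random_rna(rng, 200)
        linc = random_rna(rng, 60) + revcomp(mrna[80:110]) + random_rna(rng, 60)
        score, region = trans_score(linc, mrna)
        assert score >= 60
        (l0, l1), (m0, m1) = region
        assert (m0, m1) == (80, 110)
        assert (l0, l1) == (60, 90)


class TestPredictTargets:
    def _fixture(self, rng):
        from cernet.seq import random_rna
        genes = _table([
            ("G_CIS1", "chr1", 12_000, 13_000, "+", "protein_coding"),
            ("G_CIS2", "chr1", 15_900, 17_000, "-", "protein_coding"),
            ("G_FAR", "chr1", 500_000, 501_000, "+", "protein_coding"),
            ("G_TRANS", "chr1", 900_000, 901_000, "+", "protein_coding"),
        ])
        lincs = _table([("L1", "chr1", 5_000, 6_000, "+", "lincRNA"),
                        ("L2", "chr1", 700_000, 701_000, "+", "lincRNA")])
        mrna_seqs = {g: random_rna(rng, 300) for g in genes["feature_id"]}
        linc_seqs = {
            "L1": random_rna(rng, 300),
            "L2": random_rna(rng, 100) + revcomp(mrna_seqs["G_TRANS"][50:90])
                  + random_rna(rng, 100),
        }
        return lincs, genes, linc_seqs, mrna_seqs

    def test_planted_cis_and_trans_links_exact(self, rng):
        lincs, genes, linc_seqs, mrna_seqs = self._fixture(rng)
        table = predict_targets(lincs, genes, linc_seqs, mrna_seqs)
        got = {(r.lincRNA, r.gene, r.mode) for r in table.itertuples(index=False)}
        assert got == {("L1", "G_CIS1", "cis"), ("L1", "G_CIS2", "cis"),
                       ("L2", "G_TRANS", "trans")}

    def test_de_restriction(self, rng):
        lincs, genes, linc_seqs, mrna_seqs = self._fixture(rng)
        table = predict_targets(lincs, genes, linc_seqs, mrna_seqs,
                                de_mrnas=set())
        assert table.empty

    def test_raising_threshold_never_adds_links(self, rng):
        lincs, genes, linc_seqs, mrna_seqs = self._fixture(rng)
        sizes = [len(predict_targets(lincs, genes, linc_seqs, mrna_seqs,
                                     trans_threshold=t))
                 for t in (40.0, 60.0, 90.0, 200.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_dual_mode_link_collapsed(self, rng):
        from cernet.seq import random_rna
        genes = _table([("G", "chr1", 12_000, 13_000, "+", "protein_coding")])
        lincs = _table([("L", "chr1", 5_000, 6_000, "+", "lincRNA")])
        gseq = random_rna(rng, 300)
        lseq = random_rna(rng, 50) + revcomp(gseq[100:140]) + random_rna(rng, 50)
        table = predict_targets(lincs, genes, {"L": lseq}, {"G": gseq})
        assert len(table) == 1
        assert table["mode"].iloc[0] == "cis+trans"
        assert table["gap_bp"].iloc[0] == 6000
        assert table["score"].iloc[0] >= 60
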