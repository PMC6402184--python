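"""Synthetic two-condition RNA-seq inputs with planted ground truth.

Emulates the study design every downstream stage expects: two groups of
count libraries (negative-binomial noise around a flat baseline mean, a
subset of features shifted by a planted log2 fold change in the case group),
a toy genome that places lincRNAs at controlled distances from coding genes,
transcript sequences carrying planted miRNA seed sites, and latent-factor
coexpression modules.  A ``TruthManifest`` records everything planted so
recovery can be scored exactly.

All randomness flows from ``SimConfig.seed`` through named substreams, so a
given configuration is byte-reproducible regardless of which generators are
invoked or in what order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io as cio
from .diffexpr import CountMatrix
from .errors import ConfigError
from .seq import complement, random_rna, revcomp

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

# substream tags hashed with the seed; fixed forever for reproducibility
_STREAM_COUNTS = 0
_STREAM_ANNOT = 1
_STREAM_SEQS = 2
_STREAM_LENGTHS = 10
_STREAM_DE = 11
_STREAM_MODULES = 12


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror a scaled-down version of the emulated design: 5-vs-5
    pooled libraries, 10% of features differentially expressed at
    |log2FC| = 2, negative-binomial dispersion 0.1 around a flat baseline
    mean of 100 counts.
    """

    seed: int = 0
    n_lncrna: int = 200
    n_mirna: int = 40
    n_mrna: int = 400
    n_samples_per_group: int = 5
    de_fraction: float = 0.1
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    baseline_mean: float = 100.0
    #: (size, latent_correlation) per planted coexpression module
    module_specs: list = field(default_factory=list)
    #: log2-scale standard deviation of the shared module factor
    module_log2_sd: float = 3.0
    #: draw module members from planted up-regulated features when possible
    modules_from_de: bool = True
    genome_length: int = 100_000_000
    cis_window: int = 10_000
    #: gap in bp between each planted lincRNA/coding-gene pair
    cis_pair_specs: list = field(default_factory=list)
    #: explicit (lincRNA id, gene id) per cis pair; defaults to the first ids
    cis_pair_ids: list | None = None
    #: (mirna_id, transcript_id, site_type) per planted binding site
    site_specs: list = field(default_factory=list)
    #: (lincrna_id, mrna_id, length_nt) perfect antisense stretches planted
    #: into lincRNAs for the trans-target stage
    trans_pair_specs: list = field(default_factory=list)
    mirna_length: int = 22

    def validate(self) -> None:
        if min(self.n_lncrna, self.n_mirna, self.n_mrna) < 1:
            raise ConfigError("feature counts must be >= 1")
        if self.n_samples_per_group < 1:
            raise ConfigError("need at least one sample per group")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError("de_fraction must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.baseline_mean <= 0:
            raise ConfigError("baseline_mean must be positive")
        if self.mirna_length < 8:
            raise ConfigError("miRNAs must be at least 8 nt")
        for size, rho in self.module_specs:
            if size < 2 or not 0.0 < rho <= 1.0:
                raise ConfigError(f"bad module spec ({size}, {rho})")
        for spec in self.site_specs:
            if spec[2] not in SITE_TYPES:
                raise ConfigError(f"unknown site type {spec[2]!r}")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class TruthManifest:
    """Everything planted: DE effects, modules, cis pairs, binding sites."""

    de: dict = field(default_factory=dict)          # feature id -> signed log2fc
    modules: list = field(default_factory=list)     # {members, latent_correlation}
    cis_pairs: list = field(default_factory=list)   # {lincrna, gene, gap_bp, within_window}
    sites: list = field(default_factory=list)       # {mirna, transcript, position, site_type}
    trans_pairs: list = field(default_factory=list)  # {lincrna, mrna, length_nt}
    triads_strict: list = field(default_factory=list)
    triads_permissive: list = field(default_factory=list)

    def merge(self, other: "TruthManifest") -> "TruthManifest":
        self.de.update(other.de)
        self.modules += other.modules
        self.cis_pairs += other.cis_pairs
        self.sites += other.sites
        self.trans_pairs += other.trans_pairs
        return self

    def to_yaml(self, path) -> None:
        cio.write_yaml(asdict(self), path)

    @classmethod
    def from_yaml(cls, path) -> "TruthManifest":
        return cls(**cio.read_yaml(path))


def feature_ids(config: SimConfig) -> dict[str, list[str]]:
    return {
        "lncRNA": [f"LNC{i:05d}" for i in range(config.n_lncrna)],
        "miRNA": [f"MIR{i:04d}" for i in range(config.n_mirna)],
        "mRNA": [f"MRN{i:05d}" for i in range(config.n_mrna)],
    }


def feature_lengths(config: SimConfig) -> pd.Series:
    """Transcript lengths in nt, shared between the count and sequence sims."""
    rng = config.rng(_STREAM_LENGTHS)
    ids = feature_ids(config)
    lengths = pd.concat(
        [
            pd.Series(rng.integers(300, 3001, config.n_lncrna), index=ids["lncRNA"]),
            pd.Series(config.mirna_length, index=ids["miRNA"]),
            pd.Series(rng.integers(600, 4001, config.n_mrna), index=ids["mRNA"]),
        ]
    )
    return lengths


def planted_de(config: SimConfig) -> dict[str, float]:
    """Deterministic choice of DE features and signed effects per class."""
    if config.planted_log2fc == 0:
        return {}
    rng = config.rng(_STREAM_DE)
    out: dict[str, float] = {}
    for cls, ids in feature_ids(config).items():
        n_de = int(round(config.de_fraction * len(ids)))
        chosen = rng.choice(ids, size=n_de, replace=False)
        # alternating signs: both directions are represented whenever n_de >= 2
        for i, fid in enumerate(chosen):
            out[str(fid)] = (1.0 if i % 2 == 0 else -1.0) * config.planted_log2fc
    return out


def planted_modules(config: SimConfig) -> list[dict]:
    """Module memberships: one lincRNA plus (size-1) mRNAs per module."""
    rng = config.rng(_STREAM_MODULES)
    de = planted_de(config)
    ids = feature_ids(config)
    pool_lnc = [f for f in ids["lncRNA"] if de.get(f, 0) > 0] or ids["lncRNA"]
    pool_mrna = [f for f in ids["mRNA"] if de.get(f, 0) > 0] or ids["mRNA"]
    if not config.modules_from_de:
        pool_lnc, pool_mrna = list(ids["lncRNA"]), list(ids["mRNA"])
    pool_lnc, pool_mrna = list(pool_lnc), list(pool_mrna)
    modules = []
    for size, rho in config.module_specs:
        if not pool_lnc or len(pool_mrna) < size - 1:
            raise ConfigError("not enough features to fill module specs")
        linc = pool_lnc.pop(int(rng.integers(len(pool_lnc))))
        mrnas = [
            pool_mrna.pop(int(rng.integers(len(pool_mrna))))
            for _ in range(size - 1)
        ]
        modules.append({"members": [linc] + mrnas, "latent_correlation": float(rho)})
    return modules


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, TruthManifest]:
    """Draw negative-binomial counts with planted effects and modules.

    Case-group means for DE features are the baseline shifted by the signed
    planted log2 fold change; module members share a latent log2-scale
    Gaussian factor across all samples.
    """
    config.validate()
    rng = config.rng(_STREAM_COUNTS)
    ids = feature_ids(config)
    all_ids = ids["lncRNA"] + ids["miRNA"] + ids["mRNA"]
    classes = pd.Series(
        ["lncRNA"] * config.n_lncrna + ["miRNA"] * config.n_mirna
        + ["mRNA"] * config.n_mrna,
        index=all_ids,
    )
    n = config.n_samples_per_group
    samples = [f"case_{i+1}" for i in range(n)] + [f"ctrl_{i+1}" for i in range(n)]
    groups = pd.Series(["case"] * n + ["control"] * n, index=samples)

    de = planted_de(config)
    modules = planted_modules(config)

    log2_mean = np.full((len(all_ids), 2 * n), np.log2(config.baseline_mean))
    pos = {fid: i for i, fid in enumerate(all_ids)}
    for fid, lfc in de.items():
        log2_mean[pos[fid], :n] += lfc
    c = config.module_log2_sd
    for mod in modules:
        rho = mod["latent_correlation"]
        z = rng.standard_normal(2 * n)
        for fid in mod["members"]:
            u = rng.standard_normal(2 * n)
            log2_mean[pos[fid]] += c * (np.sqrt(rho) * z + np.sqrt(1 - rho) * u)

    mean = np.power(2.0, log2_mean)
    d = config.nb_dispersion
    if d == 0:
        counts = rng.poisson(mean)
    else:
        counts = rng.negative_binomial(1.0 / d, 1.0 / (1.0 + d * mean))

    # nominal design depth, constant across samples: the simulator has no
    # depth variation, and realised column totals would leak composition
    # effects from planted modules into RPKM normalisation
    depth = int(config.baseline_mean * len(all_ids))
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=all_ids, columns=samples),
        groups=groups,
        feature_length=feature_lengths(config),
        feature_class=classes,
        library_size=pd.Series(depth, index=samples),
    )
    return cm, TruthManifest(de=de, modules=modules)


def pool_libraries(cm: CountMatrix, pool_size: int) -> CountMatrix:
    """Sum consecutive same-group samples into pooled libraries.

    Emulates sequencing designs in which several donors are mixed into each
    library; with pool_size equal to the group size this collapses each
    group to a single library.
    """
    if pool_size < 1:
        raise ConfigError("pool_size must be >= 1")
    pooled, labels, names = [], [], []
    for group in ("case", "control"):
        members = cm.samples_in(group)
        if len(members) % pool_size:
            raise ConfigError(
                f"{group} group size {len(members)} not divisible by {pool_size}"
            )
        for k in range(0, len(members), pool_size):
            chunk = members[k:k + pool_size]
            pooled.append(cm.counts[chunk].sum(axis=1))
            labels.append(group)
            names.append(f"{group}_lib{k // pool_size + 1}")
    return CountMatrix(
        counts=pd.concat(pooled, axis=1).set_axis(names, axis=1),
        groups=pd.Series(labels, index=names),
        feature_length=cm.feature_length,
        feature_class=cm.feature_class,
    )


def simulate_annotation(config: SimConfig) -> tuple[pd.DataFrame, TruthManifest]:
    """Place lincRNAs and coding genes on a toy chromosome.

    The first ``len(cis_pair_specs)`` lincRNA/mRNA id pairs are laid out at
    exactly the requested gaps; every other feature sits in its own block
    separated by more than ``cis_window + max(gap)`` so it has no neighbour
    within the window.  Pairs with a gap beyond the window are recorded as
    planted-negative controls.
    """
    config.validate()
    ids = feature_ids(config)
    lengths = feature_lengths(config)
    gaps = [int(g) for g in config.cis_pair_specs]
    if len(gaps) > min(config.n_lncrna, config.n_mrna):
        raise ConfigError("more cis pairs requested than features available")
    if config.cis_pair_ids is not None:
        if len(config.cis_pair_ids) != len(gaps):
            raise ConfigError("cis_pair_ids and cis_pair_specs lengths differ")
        pair_ids = [tuple(p) for p in config.cis_pair_ids]
        flat = [f for p in pair_ids for f in p]
        if len(set(flat)) != len(flat):
            raise ConfigError("cis_pair_ids must be distinct")
    else:
        pair_ids = list(zip(ids["lncRNA"], ids["mRNA"]))[:len(gaps)]
    spacing = config.cis_window + max(gaps, default=0) + 10_000

    rows, cis_pairs = [], []
    pos = 1
    for k, gap in enumerate(gaps):
        linc, gene = pair_ids[k]
        l_len, g_len = int(lengths[linc]), int(lengths[gene])
        rows.append((linc, "chr1", pos, pos + l_len - 1, "+", "lincRNA"))
        g_start = pos + l_len - 1 + gap  # endpoint-distance convention
        rows.append((gene, "chr1", g_start, g_start + g_len - 1,
                     "+" if k % 2 == 0 else "-", "protein_coding"))
        cis_pairs.append(
            {"lincrna": linc, "gene": gene, "gap_bp": gap,
             "within_window": gap <= config.cis_window}
        )
        pos = g_start + g_len + spacing
    paired = {f for p in pair_ids for f in p}
    singles = [f for f in ids["lncRNA"] + ids["mRNA"] if f not in paired]
    for k, fid in enumerate(singles):
        f_len = int(lengths[fid])
        biotype = "lincRNA" if fid.startswith("LNC") else "protein_coding"
        rows.append((fid, "chr1", pos, pos + f_len - 1,
                     "+" if k % 2 == 0 else "-", biotype))
        pos += f_len + spacing
    if pos > config.genome_length:
        raise ConfigError(
            f"genome_length {config.genome_length} too small; need >= {pos}"
        )
    features = pd.DataFrame(rows, columns=cio.FEATURE_COLUMNS)
    return features, TruthManifest(cis_pairs=cis_pairs)


def _site_window(mirna: str, site_type: str) -> str:
    """The planted region: near-full reverse complement of the miRNA whose
    last 8 nt realise the requested seed-site class exactly."""
    region = list(revcomp(mirna))  # region[-1] sits opposite miRNA position 1
    L = len(region)

    def non_matching(excluded: set[str]) -> str:
        return next(b for b in "CGUA" if b not in excluded)

    def break_m8() -> str:
        # neither Watson-Crick nor GU wobble partner of miRNA position 8
        excluded = {complement(mirna[7])}
        if mirna[7] == "G":
            excluded.add("U")
        elif mirna[7] == "U":
            excluded.add("G")
        return non_matching(excluded)

    if site_type == "8mer":
        region[L - 1] = "A"
    elif site_type == "7mer-m8":
        region[L - 1] = non_matching({"A", complement(mirna[0])})
    elif site_type == "7mer-A1":
        region[L - 8] = break_m8()
        region[L - 1] = "A"
    elif site_type == "6mer":
        region[L - 8] = break_m8()
        region[L - 1] = non_matching({"A", complement(mirna[0])})
    else:
        raise ConfigError(f"unknown site type {site_type!r}")
    return "".join(region)


def simulate_sequences(
    config: SimConfig, mirna_seqs: dict[str, str] | None = None
) -> tuple[dict[str, str], dict[str, str], TruthManifest]:
    """Emit transcript and miRNA FASTA sequences with planted binding sites.

    Background is uniform random RNA.  Each planted site is a near-full
    reverse complement of its miRNA whose terminal 8-nt window realises the
    requested seed-site class, flanked by 30 nt of AU-rich sequence (so the
    hybridisation-energy and AU-context stand-in predictors also fire on
    planted sites).  Recorded positions are the 0-based starts of the 8-nt
    seed windows.
    """
    config.validate()
    rng = config.rng(_STREAM_SEQS)
    ids = feature_ids(config)
    lengths = feature_lengths(config)

    if mirna_seqs is None:
        mirna_seqs = {
            mid: random_rna(rng, config.mirna_length) for mid in ids["miRNA"]
        }
    transcripts = {
        tid: random_rna(rng, int(lengths[tid]))
        for tid in ids["lncRNA"] + ids["mRNA"]
    }

    flank = 30
    sites = []
    by_transcript: dict[str, list] = {}
    for mid, tid, stype in config.site_specs:
        if mid not in mirna_seqs:
            raise ConfigError(f"site references unknown miRNA {mid!r}")
        if tid not in transcripts:
            raise ConfigError(f"site references unknown transcript {tid!r}")
        by_transcript.setdefault(tid, []).append((mid, stype))
    for tid, specs in by_transcript.items():
        seq = list(transcripts[tid])
        cursor = flank
        for mid, stype in specs:
            region = _site_window(mirna_seqs[mid], stype)
            L = len(region)
            if cursor + L + flank > len(seq):
                raise ConfigError(
                    f"transcript {tid} too short for requested site(s)"
                )
            seq[cursor:cursor + L] = region
            for j in range(cursor - flank, cursor):
                seq[j] = "A" if rng.random() < 0.5 else "U"
            for j in range(cursor + L, cursor + L + flank):
                seq[j] = "A" if rng.random() < 0.5 else "U"
            sites.append(
                {"mirna": mid, "transcript": tid,
                 "position": cursor + L - 8, "site_type": stype}
            )
            cursor += L + 2 * flank + 10
        transcripts[tid] = "".join(seq)

    trans_pairs = []
    for lid, gid, length in config.trans_pair_specs:
        if lid not in transcripts or gid not in transcripts:
            raise ConfigError(f"trans pair references unknown transcript")
        if lid in by_transcript:
            raise ConfigError(
                f"transcript {lid} carries planted sites; cannot also plant "
                "a trans complement"
            )
        linc = list(transcripts[lid])
        mseq = transcripts[gid]
        if length + 100 > len(linc) or length + 100 > len(mseq):
            raise ConfigError(f"transcripts too short for {length} nt trans pair")
        linc[50:50 + length] = revcomp(mseq[50:50 + length])
        transcripts[lid] = "".join(linc)
        trans_pairs.append({"lincrna": lid, "mrna": gid, "length_nt": int(length)})

    return transcripts, mirna_seqs, TruthManifest(sites=sites,
                                                  trans_pairs=trans_pairs)


def _planted_triads(manifest: TruthManifest) -> None:
    """Derive planted ceRNA triads from planted sites + DE directions."""
    de = manifest.de
    lnc_sites: dict[str, set] = {}
    mrna_sites: dict[str, set] = {}
    for s in manifest.sites:
        target = lnc_sites if s["transcript"].startswith("LNC") else mrna_sites
        target.setdefault(s["mirna"], set()).add(s["transcript"])
    strict, permissive = [], []
    for mid in sorted(set(lnc_sites) & set(mrna_sites)):
        if de.get(mid) is None:
            continue
        for lnc in sorted(lnc_sites[mid]):
            for mrna in sorted(mrna_sites[mid]):
                if de.get(lnc) is None or de.get(mrna) is None:
                    continue
                triad = {"lncrna": lnc, "mirna": mid, "mrna": mrna}
                permissive.append(triad)
                if (np.sign(de[lnc]) == np.sign(de[mrna])
                        == -np.sign(de[mid])):
                    strict.append(triad)
    manifest.triads_strict = strict
    manifest.triads_permissive = permissive


@dataclass
class SimBundle:
    """One complete synthetic dataset plus its merged truth manifest."""

    counts: CountMatrix
    features: pd.DataFrame
    transcripts: dict[str, str]
    mirnas: dict[str, str]
    manifest: TruthManifest


def simulate_all(config: SimConfig,
                 mirna_seqs: dict[str, str] | None = None) -> SimBundle:
    """Run all three generators under one seed and merge the manifests."""
    counts, m1 = simulate_counts(config)
    features, m2 = simulate_annotation(config)
    transcripts, mirnas, m3 = simulate_sequences(config, mirna_seqs)
    manifest = m1.merge(m2).merge(m3)
    _planted_triads(manifest)
    return SimBundle(counts, features, transcripts, mirnas, manifest)


def demo_config(seed: int = 7) -> SimConfig:
    """The bundled end-to-end demonstration dataset.

    A scaled-down two-condition design: 60 lncRNAs, 20 miRNAs and 150 mRNAs
    over 5-vs-5 libraries with 20% of features shifted by |log2FC| = 2; one
    8-member coexpression module; five lincRNA/gene placements at gaps 0,
    2 kb, 5 kb, 9.9 kb and 15 kb (the last a planted-negative beyond the
    10-kb window); one 40-nt planted antisense stretch for the trans stage;
    and planted miRNA sites arranged into four direction-consistent ceRNA
    triads plus one direction-inconsistent decoy.
    """
    cfg = SimConfig(
        seed=seed, n_lncrna=60, n_mirna=20, n_mrna=150,
        n_samples_per_group=5, de_fraction=0.2, planted_log2fc=2.0,
        module_specs=[(8, 0.95)],
        cis_pair_specs=[0, 2000, 5000, 9900, 15000],
    )
    de = planted_de(cfg)
    module_members = {m for mod in planted_modules(cfg) for m in mod["members"]}

    def pick(prefix, sign, n, exclude=()):
        out = [
            f for f, lfc in de.items()
            if f.startswith(prefix) and np.sign(lfc) == sign
            and f not in module_members and f not in exclude
        ]
        if len(out) < n:
            raise ConfigError("demo design needs DE features of both signs")
        return out[:n]

    lnc_up, = pick("LNC", 1, 1)
    lnc_dn, = pick("LNC", -1, 1)
    mir_dn, = pick("MIR", -1, 1)
    mir_up, = pick("MIR", 1, 1)
    mrna_up = pick("MRN", 1, 2)
    mrna_dn = pick("MRN", -1, 3)
    trans_linc, = pick("LNC", 1, 1, exclude=[lnc_up])
    trans_mrna, = pick("MRN", 1, 1, exclude=mrna_up)

    # cis pairs on DE features so the DE-restricted target stage sees them
    cis_lincs = pick("LNC", 1, 3, exclude=[lnc_up, trans_linc]) \
        + pick("LNC", -1, 2, exclude=[lnc_dn])
    cis_genes = pick("MRN", 1, 3, exclude=mrna_up + [trans_mrna]) \
        + pick("MRN", -1, 2, exclude=mrna_dn)
    cfg.cis_pair_ids = list(zip(cis_lincs, cis_genes))

    cfg.site_specs = [
        (mir_dn, lnc_up, "8mer"),
        (mir_dn, mrna_up[0], "8mer"),
        (mir_dn, mrna_up[1], "7mer-m8"),
        (mir_dn, mrna_dn[2], "8mer"),   # direction-inconsistent decoy
        (mir_up, lnc_dn, "8mer"),
        (mir_up, mrna_dn[0], "8mer"),
        (mir_up, mrna_dn[1], "8mer"),
    ]
    cfg.trans_pair_specs = [(trans_linc, trans_mrna, 40)]
    return cfg


def simulate_validation_tables(
    config: SimConfig, n_validated: int = 8, n_case: int = 10,
    n_control: int = 10, n_clinical: int = 33,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """qPCR Ct tables for a panel of planted-DE lncRNAs plus a clinical table.

    Per validated feature: reference-gene Ct ~ 20 with 0.1 cycles of noise,
    control-group delta-Ct 5, case-group delta-Ct shifted by the planted
    log2 fold change, 0.25 cycles of technical noise — so 2^-ddCt recovers
    the planted fold change.  The clinical table draws a biomarker level
    and an activity score from a Gaussian copula with latent correlation
    0.8 (positive biomarker/score association).
    """
    rng = config.rng(3)
    de = planted_de(config)
    validated = [f for f in de if f.startswith("LNC")][:n_validated]

    rows = []
    for fid in validated:
        for i in range(n_case + n_control):
            group = "case" if i < n_case else "control"
            ref = 20.0 + rng.normal(0, 0.1)
            dct = 5.0 - (de[fid] if group == "case" else 0.0)
            rows.append(
                {"feature": fid, "sample": f"{fid}_{group}_{i}", "group": group,
                 "target_ct": ref + dct + rng.normal(0, 0.25),
                 "reference_ct": ref}
            )
    qpcr = pd.DataFrame(rows)

    z1 = rng.standard_normal(n_clinical)
    z2 = 0.8 * z1 + np.sqrt(1 - 0.8**2) * rng.standard_normal(n_clinical)
    clinical = pd.DataFrame(
        {
            "sample": [f"patient_{i+1}" for i in range(n_clinical)],
            "biomarker_pg_ml": np.round(60.0 * np.exp(0.6 * z1), 2),
            "activity_score": np.clip(np.round(10 + 4 * z2), 0, None).astype(int),
        }
    )
    return qpcr, clinical
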