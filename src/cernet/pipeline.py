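"""Stage orchestration behind one YAML configuration.

Each stage reads its inputs from, and writes its outputs to, the run output
directory, so stages can be run individually (via the CLI subcommands) or
end to end with :func:`run_all`.  Outputs are plain TSV/GTF/FASTA/GMT/SIF/
YAML; every table carries header comments recording the thresholds used,
and a run manifest (config hash, seed, stage outputs) accompanies every
run.  Identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import copy
import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from . import __version__
from .cerna import PredictorThresholds, assemble_triads, predict_bindings
from .coexpression import build_network, edge_sign_counts
from .diffexpr import CountMatrix, DEThresholds, rpkm, run_de
from .enrichment import GeneSetCollection, enrich
from .errors import ConfigError, InputError
from .novel import (CascadeParams, DEMO_DOMAIN_PATTERN, demo_candidates,
                    filter_cascade, toy_model)
from .simulate import (SimConfig, demo_config, simulate_all,
                       simulate_validation_tables)
from .targets import predict_targets
from .validation import ddct_fold_change, spearman_rho, two_group_test

logger = logging.getLogger(__name__)

STAGES = ("simulate", "de", "novel", "coexpr", "targets", "cerna",
          "enrich", "validate")

DEFAULT_CONFIG: dict = {
    "seed": 7,
    "outdir": "results/run",
    "simulate": {"demo": True},  # demo=False: SimConfig fields given here
    "de": {"min_abs_log2fc": 1.0, "q_lncRNA": 1e-3, "q_mRNA": 1e-3,
           "q_miRNA": 0.05},
    "novel": {"min_length": 200, "max_orf": 300, "cp_threshold": -1.0,
              "domain_patterns": [DEMO_DOMAIN_PATTERN]},
    "coexpression": {"threshold": 0.85},
    "targets": {"window": 10_000, "trans_threshold": 60.0},
    "cerna": {"k_lnc_mir": 2, "k_mir_mrna": 3, "mode": "strict",
              "energy_max": -25.0, "context_min_au": 0.7},
    "enrichment": {"alpha": 0.05},
}


def load_config(path=None, **overrides) -> dict:
    """Defaults, deep-merged with a YAML file, then keyword overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        user = cio.read_yaml(path) or {}
        _deep_update(cfg, user)
    for key, val in overrides.items():
        if val is not None:
            cfg[key] = val
    return cfg


def _deep_update(base: dict, update: dict) -> None:
    for key, val in update.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def _outdir(cfg) -> Path:
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    return out


def _sim_config(cfg) -> SimConfig:
    sim = dict(cfg["simulate"])
    if sim.pop("demo", False):
        return demo_config(cfg["seed"])
    return SimConfig(seed=cfg["seed"], **sim)


# ---------------------------------------------------------------- stages --

def stage_simulate(cfg: dict) -> None:
    out = _outdir(cfg)
    sc = _sim_config(cfg)
    bundle = simulate_all(sc)
    cm = bundle.counts

    cio.write_counts_tsv(cm.counts, out / "counts.tsv")
    cio.write_table(
        pd.DataFrame({"sample": cm.sample_ids, "group": cm.groups[cm.sample_ids],
                      "library_size": cm.library_size[cm.sample_ids]}),
        out / "sample_sheet.tsv",
    )
    cio.write_table(
        pd.DataFrame({"feature_id": cm.feature_ids,
                      "class": cm.feature_class[cm.feature_ids],
                      "length": cm.feature_length[cm.feature_ids]}),
        out / "feature_lengths.tsv",
    )
    cio.write_gtf(bundle.features, out / "annotation.gtf")
    cio.write_fasta(bundle.transcripts, out / "transcripts.fasta")
    cio.write_fasta(bundle.mirnas, out / "mirnas.fasta")
    bundle.manifest.to_yaml(out / "truth.yaml")

    # novel-lncRNA candidates and the coding-potential model
    cands, coords, known, expected = demo_candidates(cfg["seed"])
    cio.write_fasta(cands, out / "candidates.fasta")
    cio.write_table(coords, out / "candidate_coords.tsv")
    cio.write_gtf(known, out / "candidates_known.gtf")
    cio.write_yaml(expected, out / "candidates_expected.yaml")
    toy_model(cfg["seed"]).to_tsv(out / "cp_model.tsv")

    # gene sets: one planted-target set plus random background sets
    rng = np.random.default_rng([cfg["seed"], 30])
    mrna_ids = [f for f in cm.feature_ids if f.startswith("MRN")]
    truth = bundle.manifest
    planted = sorted(
        {p["gene"] for p in truth.cis_pairs if p["within_window"]}
        | {p["mrna"] for p in truth.trans_pairs}
        | {m for mod in truth.modules for m in mod["members"]
           if m.startswith("MRN")}
    )
    sets = {"PLANTED_TARGETS": set(planted)}
    for i in range(20):
        sets[f"RANDOM_SET_{i:02d}"] = set(
            rng.choice(mrna_ids, size=30, replace=False)
        )
    cio.write_gmt(sets, out / "gene_sets.gmt")

    qpcr, clinical = simulate_validation_tables(sc)
    cio.write_table(qpcr, out / "qpcr.tsv")
    cio.write_table(clinical, out / "clinical.tsv")


def _load_counts(out: Path) -> CountMatrix:
    counts = cio.read_counts_tsv(out / "counts.tsv")
    sheet = cio.read_table(out / "sample_sheet.tsv").set_index("sample")
    lengths = cio.read_table(out / "feature_lengths.tsv").set_index("feature_id")
    return CountMatrix(
        counts=counts,
        groups=sheet["group"],
        feature_length=lengths["length"],
        feature_class=lengths["class"],
        library_size=sheet["library_size"],
    )


def _de_thresholds(cfg) -> DEThresholds:
    d = cfg["de"]
    return DEThresholds(
        min_abs_log2fc=d["min_abs_log2fc"],
        max_q={"lncRNA": d["q_lncRNA"], "mRNA": d["q_mRNA"],
               "miRNA": d["q_miRNA"]},
    )


def stage_de(cfg: dict) -> pd.DataFrame:
    out = _outdir(cfg)
    table = run_de(_load_counts(out), _de_thresholds(cfg))
    cio.write_table(table, out / "de_table.tsv", header_comments=cfg["de"])
    return table


def stage_novel(cfg: dict) -> pd.DataFrame:
    out = _outdir(cfg)
    params = CascadeParams(
        min_length=cfg["novel"]["min_length"],
        max_orf=cfg["novel"]["max_orf"],
        cp_threshold=cfg["novel"]["cp_threshold"],
        domain_patterns=list(cfg["novel"]["domain_patterns"]),
    )
    from .novel import CodingModel

    verdicts, _ = filter_cascade(
        cio.read_fasta(out / "candidates.fasta"),
        known=cio.read_gtf(out / "candidates_known.gtf"),
        model=CodingModel.from_tsv(out / "cp_model.tsv"),
        params=params,
        candidate_coords=cio.read_table(out / "candidate_coords.tsv"),
    )
    cio.write_table(verdicts, out / "novel_verdicts.tsv",
                    header_comments=cfg["novel"])
    return verdicts


def _log_rpkm(cm: CountMatrix, ids, pseudocount: float = 0.1) -> pd.DataFrame:
    """Per-sample log2(RPKM + 0.1) expression (same pseudocount as the DE
    fold change, on the RPKM scale)."""
    sub = cm.counts.loc[ids]
    mat = rpkm(
        sub.to_numpy(),
        cm.feature_length[ids].to_numpy()[:, None],
        cm.library_size[sub.columns].to_numpy()[None, :],
    )
    return pd.DataFrame(np.log2(mat + pseudocount), index=ids, columns=sub.columns)


def _de_ids(out: Path, cls: str) -> list[str]:
    de = cio.read_table(out / "de_table.tsv")
    hit = de[(de["class"] == cls) & (de["direction"] != "ns")]
    return list(hit["feature"])


def stage_coexpr(cfg: dict) -> pd.DataFrame:
    out = _outdir(cfg)
    cm = _load_counts(out)
    features = cio.read_gtf(out / "annotation.gtf")
    lincs = set(features.loc[features["biotype"] == "lincRNA", "feature_id"])
    linc_ids = [f for f in _de_ids(out, "lncRNA") if f in lincs]
    mrna_ids = _de_ids(out, "mRNA")
    if not linc_ids or not mrna_ids:
        raise InputError("no differential lincRNAs/mRNAs; run the de stage first")
    edges, degree = build_network(
        _log_rpkm(cm, linc_ids), _log_rpkm(cm, mrna_ids),
        threshold=cfg["coexpression"]["threshold"],
    )
    comments = dict(cfg["coexpression"], **edge_sign_counts(edges))
    cio.write_table(edges, out / "coexpr_edges.tsv", header_comments=comments)
    cio.write_table(degree, out / "coexpr_degree.tsv")
    cio.write_sif(edges, out / "coexpr_edges.sif", "lincRNA", "mRNA",
                  relation="coexpressed")
    return edges


def stage_targets(cfg: dict) -> pd.DataFrame:
    out = _outdir(cfg)
    features = cio.read_gtf(out / "annotation.gtf")
    seqs = cio.read_fasta(out / "transcripts.fasta")
    linc_ids = _de_ids(out, "lncRNA")
    lincs = features[features["feature_id"].isin(linc_ids)]
    table = predict_targets(
        lincs,
        features,
        {k: v for k, v in seqs.items() if k in set(linc_ids)},
        {k: v for k, v in seqs.items() if k.startswith("MRN")},
        de_mrnas=set(_de_ids(out, "mRNA")),
        window=cfg["targets"]["window"],
        trans_threshold=cfg["targets"]["trans_threshold"],
    )
    cio.write_table(table, out / "target_links.tsv",
                    header_comments=cfg["targets"])
    return table


def stage_cerna(cfg: dict) -> pd.DataFrame:
    out = _outdir(cfg)
    seqs = cio.read_fasta(out / "transcripts.fasta")
    mirnas = cio.read_fasta(out / "mirnas.fasta")
    de = cio.read_table(out / "de_table.tsv")
    th = PredictorThresholds(
        energy_max=cfg["cerna"]["energy_max"],
        context_min_au=cfg["cerna"]["context_min_au"],
    )
    de_mir = {m: mirnas[m] for m in _de_ids(out, "miRNA")}
    lnc_edges = predict_bindings(
        de_mir, {t: seqs[t] for t in _de_ids(out, "lncRNA")},
        k=cfg["cerna"]["k_lnc_mir"], thresholds=th,
    )
    mrna_edges = predict_bindings(
        de_mir, {t: seqs[t] for t in _de_ids(out, "mRNA")},
        k=cfg["cerna"]["k_mir_mrna"], thresholds=th,
    )
    triads = assemble_triads(de, lnc_edges, mrna_edges,
                             mode=cfg["cerna"]["mode"])
    cio.write_table(lnc_edges, out / "lnc_mir_edges.tsv",
                    header_comments=cfg["cerna"])
    cio.write_table(mrna_edges, out / "mir_mrna_edges.tsv",
                    header_comments=cfg["cerna"])
    cio.write_table(triads, out / "triads.tsv", header_comments=cfg["cerna"])
    pairs = pd.concat(
        [
            triads.rename(columns={"lncRNA": "a", "miRNA": "b"})[["a", "b"]],
            triads.rename(columns={"miRNA": "a", "mRNA": "b"})[["a", "b"]],
        ]
    ).drop_duplicates()
    cio.write_sif(pairs, out / "triads.sif", "a", "b", relation="binds")
    return triads


def stage_enrich(cfg: dict) -> pd.DataFrame:
    out = _outdir(cfg)
    sets = cio.read_gmt(out / "gene_sets.gmt")
    lengths = cio.read_table(out / "feature_lengths.tsv")
    universe = set(lengths.loc[lengths["class"] == "mRNA", "feature_id"])
    targets = cio.read_table(out / "target_links.tsv")
    query = set(targets["gene"])
    table = enrich(query, GeneSetCollection(sets, universe),
                   alpha=cfg["enrichment"]["alpha"])
    cio.write_table(table, out / "enrichment.tsv",
                    header_comments=cfg["enrichment"])
    return table


def stage_validate(cfg: dict) -> dict:
    out = _outdir(cfg)
    qpcr = cio.read_table(out / "qpcr.tsv")
    clinical = cio.read_table(out / "clinical.tsv")
    folds, tests = [], {}
    for fid, sub in qpcr.groupby("feature"):
        fc = ddct_fold_change(sub)
        folds.append(pd.DataFrame({"feature": fid, "sample": fc.index,
                                   "fold_change": fc.to_numpy()}))
        case = fc[sub.set_index("sample")["group"] == "case"]
        ctrl = fc[sub.set_index("sample")["group"] == "control"]
        t, p = two_group_test(np.log2(case), np.log2(ctrl))
        tests[fid] = {"mean_case_fold": float(case.mean()),
                      "t": round(t, 4), "p": float(p)}
    cio.write_table(pd.concat(folds, ignore_index=True),
                    out / "qpcr_fold_changes.tsv")
    rho, p = spearman_rho(clinical["biomarker_pg_ml"],
                          clinical["activity_score"])
    report = {
        "qpcr": tests,
        "clinical_correlation": {"spearman_rho": round(rho, 4),
                                 "p": float(p),
                                 "n": int(len(clinical))},
    }
    cio.write_yaml(report, out / "validation_report.yaml")
    return report


_STAGE_FUNCS = {
    "simulate": stage_simulate, "de": stage_de, "novel": stage_novel,
    "coexpr": stage_coexpr, "targets": stage_targets, "cerna": stage_cerna,
    "enrich": stage_enrich, "validate": stage_validate,
}


def run_stage(name: str, cfg: dict):
    if name not in _STAGE_FUNCS:
        raise ConfigError(f"unknown stage {name!r}")
    logger.info("running stage %s", name)
    return _STAGE_FUNCS[name](cfg)


def run_all(cfg: dict) -> Path:
    """Run every stage in order and write the run manifest; returns outdir."""
    out = _outdir(cfg)
    completed = []
    try:
        for name in STAGES:
            run_stage(name, cfg)
            completed.append(name)
    finally:
        manifest = {
            "config_hash": config_hash(cfg),
            "seed": cfg["seed"],
            "version": __version__,
            "stages_completed": completed,
            "partial": completed != list(STAGES),
            "outputs": sorted(
                p.name for p in out.iterdir() if p.name != "run_manifest.yaml"
            ),
        }
        cio.write_yaml(manifest, out / "run_manifest.yaml")
    return out
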