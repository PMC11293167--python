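"""End-to-end orchestration from a single YAML config.

Stages run in dependency order — simulate, design, count, lfc, score,
enrich, secretome, select, pack — each reading either the previous stage's
in-memory product or a configured input file. Every stage writes TSV
artifacts into the output directory and the run ends with a JSON manifest
recording the package version, the full config (seeds included), sha256
digests of outputs, and per-stage row counts. Identical configs reproduce
identical artifacts: all randomness is seeded from explicit config values
and the manifest carries no timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import essentiality, library, quant, secretome, selection, simulate
from .errors import ConfigError

log = logging.getLogger(__name__)

STAGE_ORDER = [
    "simulate", "design", "count", "lfc",
    "score", "enrich", "secretome", "select", "pack",
]


def demo_config(seed: int = 17) -> dict:
    """Small fully-simulated configuration exercising every stage."""
    return {
        "stages": {name: {"enabled": True} for name in STAGE_ORDER},
        "sim": {
            "n_genes": 60,
            "guides_per_gene": 4,
            "nb_mean": 100.0,
            "seed": seed,
        },
        "design": {"guides_per_gene": 4},
        "count": {"anchor": simulate.DEFAULT_ANCHOR, "max_mismatches": 0},
        "score": {"min_guides": 2, "threshold": 0.5},
        "enrich": {"n_perm": 200, "seed": seed + 100, "min_set_size": 5},
        "secretome": {"threshold": 0.5},
        "select": {"threshold": 0.5},
        "pack": {"capacity": 4},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def validate_config(config: dict) -> dict:
    """Check structure and demand explicit seeds for every stochastic stage."""
    cfg = dict(config)
    stages = cfg.get("stages")
    if not isinstance(stages, dict) or not stages:
        raise ConfigError("config needs a non-empty 'stages' mapping")
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    enabled = {s for s in STAGE_ORDER if stages.get(s, {}).get("enabled", False)}
    if "simulate" in enabled:
        sim = cfg.get("sim", {})
        if "seed" not in sim:
            raise ConfigError("stage 'simulate' enabled but sim.seed not set")
    if "enrich" in enabled and "seed" not in cfg.get("enrich", {}):
        raise ConfigError("stage 'enrich' enabled but enrich.seed not set")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the enabled stages; returns the run manifest (also written).

    Raises :class:`ConfigError` before any stage runs if the config is
    invalid; a stage failure aborts with partial outputs preserved.
    """
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages_cfg = cfg["stages"]
    enabled = [s for s in STAGE_ORDER if stages_cfg.get(s, {}).get("enabled", False)]
    art: dict[str, object] = {}
    manifest: dict = {
        "package": "secrescreen",
        "version": _package_version(),
        "config": cfg,
        "stages": {},
    }

    def record(stage: str, rows: int, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "rows": rows,
            "outputs": {f.name: _sha256(f) for f in files},
        }

    for stage in enabled:
        log.info("[%s] running", stage)
        try:
            if stage == "simulate":
                _stage_simulate(cfg, outdir, art, record)
            elif stage == "design":
                _stage_design(cfg, outdir, art, record)
            elif stage == "count":
                _stage_count(cfg, outdir, art, record)
            elif stage == "lfc":
                _stage_lfc(cfg, outdir, art, record)
            elif stage == "score":
                _stage_score(cfg, outdir, art, record)
            elif stage == "enrich":
                _stage_enrich(cfg, outdir, art, record)
            elif stage == "secretome":
                _stage_secretome(cfg, outdir, art, record)
            elif stage == "select":
                _stage_select(cfg, outdir, art, record)
            elif stage == "pack":
                _stage_pack(cfg, outdir, art, record)
        except Exception:
            log.error("[%s] stage failed; partial outputs kept in %s", stage, outdir)
            raise

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _package_version() -> str:
    try:
        return _pkg_version("secrescreen")
    except PackageNotFoundError:
        return "unknown"


# --------------------------------------------------------------------------
# stage implementations


def _sim_config(cfg: dict) -> simulate.SimConfig:
    return simulate.config_from_dict(cfg.get("sim", {}))


def _stage_simulate(cfg, outdir, art, record) -> None:
    sc = _sim_config(cfg)
    genome, features = simulate.simulate_genome(sc)
    truth = simulate.make_ground_truth(sc)
    fasta, gff = outdir / "genome.fa", outdir / "annotation.gff3"
    simulate.write_genome(genome, features, fasta, gff)
    art.update(genome=genome, features=features, truth=truth, sim_config=sc)

    # proteome-level inputs: signal-peptide table + replicate AUC abundances
    gene_ids = features["gene_id"].tolist()
    rng = np.random.default_rng(sc.seed + 10)
    sp_rows = []
    for g in gene_ids:
        klass = truth.secretion_class[g]
        predicted = klass in ("predicted_and_detected", "predicted_only")
        prob = 0.6 + 0.39 * rng.random() if predicted else 0.5 * rng.random()
        sp_rows.append({"protein_id": g, "sp_prob": prob})
    sp_df = pd.DataFrame(sp_rows)
    signalp_path = outdir / "signalp.tsv"
    secretome.write_signalp(sp_df, signalp_path)

    detected = [
        g
        for g in gene_ids
        if truth.secretion_class[g] in ("predicted_and_detected", "detected_only")
    ]
    ab_rows = []
    if len(detected) >= 2:
        pairs = simulate.simulate_abundance(
            len(detected), sc.abundance_rho, sc.seed + 11
        )
        for g, row in zip(detected, pairs.itertuples()):
            for phase, logab in (
                ("outgrowth", row.outgrowth),
                ("production", row.production),
            ):
                per_rep = 10.0**logab / sc.n_replicates
                ab_rows.append(
                    {
                        "protein_id": g,
                        "phase": phase,
                        **{f"auc_{r + 1}": per_rep for r in range(sc.n_replicates)},
                    }
                )
    ab_df = pd.DataFrame(ab_rows)
    abundance_path = outdir / "abundance.tsv"
    _write_tsv(ab_df, abundance_path)
    art.update(signalp_path=signalp_path, abundance_path=abundance_path)
    record("simulate", len(features), [fasta, gff, signalp_path, abundance_path])


def _stage_design(cfg, outdir, art, record) -> None:
    params = library.DesignParams(**cfg.get("design", {}))
    if "genome" not in art:
        paths = cfg.get("inputs", {})
        art["genome"] = library.load_genome(paths["genome"])
        art["features"] = library.load_cds_features(paths["gff"])
    result = library.design_guides(art["genome"], art["features"], params=params)
    if result.genes_without_guides:
        log.warning(
            "no passing guides for %d gene(s): %s",
            len(result.genes_without_guides),
            result.genes_without_guides[:10],
        )
    guides_path = outdir / "guides.tsv"
    _write_tsv(result.guides, guides_path)
    oligos = library.emit_oligos(result.guides)
    oligo_path = outdir / "oligos.fa"
    library.write_oligo_fasta(oligos, oligo_path)
    art["guides"] = result.guides
    record("design", len(result.guides), [guides_path, oligo_path])


def _stage_count(cfg, outdir, art, record) -> None:
    ccfg = cfg.get("count", {})
    anchor = ccfg.get("anchor", simulate.DEFAULT_ANCHOR)
    guides = art.get("guides")
    if guides is None:
        guides = pd.read_csv(cfg["inputs"]["guides"], sep="\t")
        art["guides"] = guides
    fastqs = ccfg.get("fastq")
    files = []
    if fastqs is None:
        # fully simulated branch: draw counts for the designed library and
        # emit amplicon FASTQ for each sample
        sc: simulate.SimConfig = art["sim_config"]
        counts_true = simulate.simulate_screen_counts(guides, art["truth"], sc)
        art["counts_true"] = counts_true
        fastqs = {}
        for j, sample in enumerate(("pre", "post")):
            path = outdir / f"{sample}.fastq.gz"
            simulate.write_screen_fastq(
                counts_true, guides, sample, path, seed=sc.seed + 20 + j,
                anchor=anchor,
            )
            fastqs[sample] = str(path)
            files.append(path)
    counts, stats = quant.count_guides(
        fastqs, guides, anchor=anchor,
        max_mismatches=ccfg.get("max_mismatches", 0),
    )
    counts_path = outdir / "counts.tsv"
    _write_tsv(counts, counts_path)
    files.append(counts_path)
    art["counts"] = counts
    art["count_stats"] = stats
    record("count", len(counts), files)


def _stage_lfc(cfg, outdir, art, record) -> None:
    counts = art.get("counts")
    if counts is None:
        counts = pd.read_csv(cfg["inputs"]["counts"], sep="\t")
    lcfg = cfg.get("lfc", {})
    norm = quant.normalize(counts, pseudocount=lcfg.get("pseudocount", 0.5))
    lfc = quant.compute_lfc(
        norm, pre=lcfg.get("pre", "pre"), post=lcfg.get("post", "post")
    )
    lfc_path = outdir / "lfc.tsv"
    _write_tsv(lfc, lfc_path)
    art["lfc"] = lfc
    record("lfc", len(lfc), [lfc_path])


def _stage_score(cfg, outdir, art, record) -> None:
    lfc = art.get("lfc")
    if lfc is None:
        lfc = pd.read_csv(cfg["inputs"]["lfc"], sep="\t")
    scfg = cfg.get("score", {})
    scores = essentiality.essentiality_scores(
        lfc,
        min_guides=scfg.get("min_guides", 2),
        threshold=scfg.get("threshold", 0.5),
    )
    scores_path = outdir / "scores.tsv"
    _write_tsv(scores, scores_path)
    art["scores"] = scores
    record("score", len(scores), [scores_path])


def _stage_enrich(cfg, outdir, art, record) -> None:
    ecfg = cfg.get("enrich", {})
    scores = art.get("scores")
    if scores is None:
        scores = pd.read_csv(cfg["inputs"]["scores"], sep="\t")
    score_map = pd.Series(
        scores["score"].to_numpy(), index=scores["gene_id"]
    ).dropna()
    gmt_path = ecfg.get("gmt")
    if gmt_path is None and "truth" in art:
        gene_sets = _synthetic_gene_sets(art, ecfg.get("seed", 0))
        gmt_path = outdir / "gene_sets.gmt"
        with open(gmt_path, "w") as fh:
            for name, members in gene_sets.items():
                fh.write("\t".join([name, "synthetic"] + sorted(members)) + "\n")
    else:
        gene_sets = essentiality.read_gmt(gmt_path)
    enrich = essentiality.weighted_gsea(
        score_map,
        gene_sets,
        weight_exponent=ecfg.get("weight_exponent", 1.0),
        n_perm=ecfg.get("n_perm", 1000),
        seed=ecfg["seed"],
        min_set_size=ecfg.get("min_set_size", 5),
    )
    enrich_path = outdir / "enrichment.tsv"
    _write_tsv(enrich, enrich_path)
    art["enrichment"] = enrich
    record("enrich", len(enrich), [enrich_path])


def _synthetic_gene_sets(art, seed: int) -> dict[str, set[str]]:
    """A planted essential set plus random decoys over the simulated genes."""
    truth: simulate.GroundTruth = art["truth"]
    genes = sorted(truth.fitness)
    rng = np.random.default_rng(seed)
    ess = sorted(truth.essential_gene_ids)
    k = min(20, len(ess)) or min(5, len(genes))
    sets: dict[str, set[str]] = {"essential_core": set(ess[:k])}
    for i in range(5):
        size = int(rng.integers(8, 25))
        sets[f"random_set_{i + 1}"] = set(
            rng.choice(genes, size=min(size, len(genes)), replace=False)
        )
    return sets


def _stage_secretome(cfg, outdir, art, record) -> None:
    scfg = cfg.get("secretome", {})
    inputs = cfg.get("inputs", {})
    signalp_path = art.get("signalp_path") or inputs.get("signalp")
    abundance_path = art.get("abundance_path") or inputs.get("abundance")
    preds = secretome.parse_signalp(signalp_path)
    predicted = secretome.predict_secreted(preds, scfg.get("threshold", 0.5))
    abundance = secretome.load_abundance(abundance_path)
    detected = {
        ph: set(abundance.loc[abundance["phase"] == ph, "protein_id"])
        for ph in abundance["phase"].unique()
    }
    table = secretome.define_secretome(
        predicted, detected, sp_probs=preds, abundance=abundance
    )
    sec_path = outdir / "secretome.tsv"
    _write_tsv(table, sec_path)
    art["secretome"] = table
    record("secretome", len(table), [sec_path])


def _stage_select(cfg, outdir, art, record) -> None:
    scfg = cfg.get("select", {})
    sec = art.get("secretome")
    if sec is None:
        sec = pd.read_csv(cfg["inputs"]["secretome"], sep="\t")
    scores = art.get("scores")
    if scores is None:
        scores = pd.read_csv(cfg["inputs"]["scores"], sep="\t")
    excl_path = scfg.get("exclusions")
    exclusion = selection.load_exclusions(excl_path) if excl_path else {}
    result = selection.select_targets(
        sec, scores, exclusion, score_threshold=scfg.get("threshold", 0.5)
    )
    sel_path = outdir / "selection.tsv"
    _write_tsv(result.to_frame(), sel_path)
    art["selection"] = result
    record("select", len(result.candidates), [sel_path])


def _stage_pack(cfg, outdir, art, record) -> None:
    pcfg = cfg.get("pack", {})
    result: selection.SelectionResult = art.get("selection")
    if result is None:
        sel = pd.read_csv(cfg["inputs"]["selection"], sep="\t")
        targets = sel.loc[sel["stage"] == "target", "gene_id"].tolist()
    else:
        targets = result.final
    guides = art.get("guides")
    if guides is None:
        guides = pd.read_csv(cfg["inputs"]["guides"], sep="\t")
    if not targets:
        vectors = pd.DataFrame(columns=["vector_id", "gene_id", "guide_id"])
    else:
        vectors = library.assign_multiplex_vectors(
            targets, guides, capacity=pcfg.get("capacity", 4)
        )
    vec_path = outdir / "vectors.tsv"
    _write_tsv(vectors, vec_path)
    art["vectors"] = vectors
    record("pack", len(vectors), [vec_path])
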