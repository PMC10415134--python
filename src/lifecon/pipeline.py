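"""Pipeline orchestration: simulate -> associate -> concord -> enrich ->
scan -> coevolve, driven by one TOML config, with a manifest of every output.

Each stage draws its seed from the master seed by a documented splitting
rule (``SeedSequence([master_seed, stage_index])``), so stages can be re-run
in isolation and a full re-run with the same config reproduces byte-identical
TSV outputs (the manifest differs only in timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    associate_expression,
    call_signed_set,
    filter_min_species,
    merge_method_calls,
)
from .concordance import concordance_test
from .core_io import (
    SignedGeneSet,
    read_expression_tsv,
    read_fasta_promoters,
    read_jaspar_pfm,
    read_newick_ensemble,
    read_signed_gene_set,
    read_species_tsv,
    write_expression_tsv,
    write_fasta_promoters,
    write_newick_ensemble,
    write_signed_gene_set,
    write_species_tsv,
)
from .enrichment import fisher_enrichment, read_gmt
from .motifs import MotifHit, coevolution_trend, motif_gene_stats, scan_promoters
from .synthetic import (
    SimulationConfig,
    simulate_expression,
    simulate_promoters,
    simulate_signed_partner_set,
    simulate_trait_bm,
    simulate_tree_ensemble,
    species_records_from_trait,
    synthetic_motif,
    write_jaspar_pfm,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "associate", "concord", "enrich", "scan", "coevolve")


class ConfigError(ValueError):
    """Raised before any computation when the config violates its schema."""


class StageError(RuntimeError):
    """Raised when a stage fails on its data (names the stage)."""


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    seeds: dict[str, int] = field(default_factory=dict)
    stages: dict[str, dict] = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def record(self, stage: str, outputs: dict[str, Path]) -> None:
        entry = {}
        for label, path in outputs.items():
            path = Path(path)
            entry[label] = {"path": str(path), "rows": _count_rows(path)}
        self.stages[stage] = {"outputs": entry, "timestamp": time.time()}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _count_rows(path: Path) -> int:
    with open(path) as fh:
        return sum(1 for line in fh if line.strip() and not line.startswith("#"))


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([master_seed, idx]).generate_state(1)[0] % (2**31))


def _comment_header(params: dict) -> str:
    rendered = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# lifecon {__version__} {rendered}\n"


def _write_tsv(df: pd.DataFrame, path: Path, params: dict) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header(params))
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(cfg: dict, out_dir: Path, seed: int) -> dict[str, Path]:
    sim_keys = {f.name for f in dataclasses.fields(SimulationConfig)} - {"seed"}
    sim_cfg = SimulationConfig(
        **{k: v for k, v in cfg.items() if k in sim_keys}, seed=seed
    )
    n_trees = int(cfg.get("n_trees", 10))
    partner_size = int(cfg.get("partner_size", 300))
    promoter_background_genes = int(cfg.get("promoter_background_genes", 200))
    motif_width = int(cfg.get("motif_width", 8))

    ensemble = simulate_tree_ensemble(sim_cfg.n_species, n_trees, seed)
    base_tree = ensemble.trees[0]
    trait = simulate_trait_bm(base_tree, sim_cfg.trait_sigma, sim_cfg.trait_root, seed + 1)
    expr, planted = simulate_expression(sim_cfg, base_tree, trait)
    species = species_records_from_trait(trait)
    partner = simulate_signed_partner_set(
        expr.gene_ids, planted, sim_cfg.concordance_target, partner_size, seed + 2
    )

    with_promoters = bool(cfg.get("with_promoters", True))
    rng = np.random.default_rng(seed + 3)
    mls_genes = sorted(planted.genes())
    if with_promoters:
        planted_consensus = "".join("ACGT"[b] for b in rng.integers(0, 4, motif_width))
        decoy_consensus = "".join("ACGT"[b] for b in rng.integers(0, 4, motif_width))
        planted_motif = synthetic_motif("PLANTED_GAIN", planted_consensus)
        decoy_motif = synthetic_motif("DECOY", decoy_consensus)
        null_pool = [g for g in expr.gene_ids if g not in planted]
        bg_genes = sorted(
            rng.choice(null_pool, size=min(promoter_background_genes, len(null_pool)),
                       replace=False)
        )
        promoters = simulate_promoters(
            species, mls_genes, planted_motif, trend="gain", seed=seed + 4
        )
        promoters.update(
            simulate_promoters(species, bg_genes, planted_motif, trend="none",
                               seed=seed + 5)
        )

    # synthetic annotation library: the planted genes plus random terms
    terms = {"PLANTED_SET": mls_genes}
    random_term_size = min(100, max(5, len(expr.gene_ids) // 4))
    for t in range(10):
        terms[f"RANDOM_{t:02d}"] = sorted(
            rng.choice(expr.gene_ids, size=random_term_size, replace=False)
        )

    out: dict[str, Path] = {}
    out["expression"] = out_dir / "expression.tsv"
    write_expression_tsv(expr, out["expression"])
    out["species"] = out_dir / "species.tsv"
    write_species_tsv(species, out["species"])
    out["trees"] = out_dir / "trees.nwk"
    write_newick_ensemble(ensemble, out["trees"])
    out["truth_genes"] = out_dir / "truth_genes.tsv"
    write_signed_gene_set(planted, out["truth_genes"])
    out["partner_set"] = out_dir / "partner_set.tsv"
    write_signed_gene_set(partner, out["partner_set"])
    if with_promoters:
        out["promoters"] = out_dir / "promoters.fa"
        write_fasta_promoters(promoters, out["promoters"])
        out["motifs"] = out_dir / "motifs.jaspar"
        write_jaspar_pfm([planted_motif, decoy_motif], out["motifs"])
    out["annotation"] = out_dir / "annotation.gmt"
    with open(out["annotation"], "w") as fh:
        for term, genes in terms.items():
            fh.write("\t".join([term, "synthetic"] + list(genes)) + "\n")
    return out


def run_associate(cfg: dict, out_dir: Path, seed: int) -> dict[str, Path]:
    expr = read_expression_tsv(cfg.get("expr", out_dir / "expression.tsv"))
    species = read_species_tsv(cfg.get("species", out_dir / "species.tsv"))
    ensemble = read_newick_ensemble(cfg.get("trees", out_dir / "trees.nwk"))
    methods = tuple(cfg.get("methods", ["spearman", "pgls"]))
    fdr = float(cfg.get("fdr", 0.10))
    min_species = int(cfg.get("min_species", 10))
    trait = {r.species_id: float(np.log2(r.mls_years)) for r in species}

    tables = associate_expression(
        expr, trait, ensemble=ensemble, methods=methods,
        fdr_level=fdr, min_species=min_species,
    )
    assoc = pd.concat([t.to_dataframe() for t in tables.values()], ignore_index=True)
    out: dict[str, Path] = {"assoc": out_dir / "assoc.tsv"}
    _write_tsv(assoc, out["assoc"], {"stage": "associate", "fdr": fdr,
                                     "min_species": min_species})

    calls = [call_signed_set(t, fdr) for t in tables.values()]
    merged = calls[0]
    for other in calls[1:]:
        merged = merge_method_calls(merged, other)
    logger.info("associate: %d gene(s) called at FDR < %s", len(merged), fdr)
    out["mls_genes"] = out_dir / "mls_genes.tsv"
    write_signed_gene_set(merged, out["mls_genes"])

    background = filter_min_species(expr, min_species).gene_ids
    out["background"] = out_dir / "background.txt"
    Path(out["background"]).write_text("\n".join(background) + "\n")
    return out


def _read_background(path) -> set[str]:
    return {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }


def run_concord(cfg: dict, out_dir: Path, seed: int) -> dict[str, Path]:
    set_a = read_signed_gene_set(cfg.get("set_a", out_dir / "mls_genes.tsv"))
    set_b = read_signed_gene_set(cfg.get("set_b", out_dir / "partner_set.tsv"))
    universe = _read_background(cfg.get("universe", out_dir / "background.txt"))
    res = concordance_test(set_a, set_b, universe)
    df = pd.DataFrame(
        [
            {
                "n_universe": res.counts.n_universe,
                "n_a": res.counts.n_a,
                "concordant": res.counts.concordant,
                "discordant": res.counts.discordant,
                "expected_concordant": res.counts.expected_concordant,
                "expected_discordant": res.counts.expected_discordant,
                "or_concordant": res.or_concordant,
                "or_discordant": res.or_discordant,
                "p_concordant": res.p_concordant,
                "p_discordant": res.p_discordant,
            }
        ]
    )
    out = {"concord": out_dir / "concord.tsv"}
    _write_tsv(df, out["concord"], {"stage": "concord"})
    return out


def run_enrich(cfg: dict, out_dir: Path, seed: int) -> dict[str, Path]:
    query_set = read_signed_gene_set(cfg.get("query", out_dir / "mls_genes.tsv"))
    library = read_gmt(cfg.get("gmt", out_dir / "annotation.gmt"))
    background = _read_background(cfg.get("background", out_dir / "background.txt"))
    fdr = float(cfg.get("fdr", 0.05))
    df = fisher_enrichment(
        query_set.genes() & background, library, background, fdr_level=fdr
    )
    out = {"enrich": out_dir / "enrich.tsv"}
    _write_tsv(df, out["enrich"], {"stage": "enrich", "fdr": fdr})
    return out


def run_scan(cfg: dict, out_dir: Path, seed: int) -> dict[str, Path]:
    promoters = read_fasta_promoters(cfg.get("fasta", out_dir / "promoters.fa"))
    motifs = read_jaspar_pfm(cfg.get("motifs", out_dir / "motifs.jaspar"))
    p_threshold = float(cfg.get("pthresh", 1e-4))
    hits = scan_promoters(promoters, motifs, p_threshold=p_threshold)
    df = pd.DataFrame(
        {
            "gene": [h.gene_id for h in hits],
            "species": [h.species_id for h in hits],
            "motif": [h.motif_id for h in hits],
            "offset": [h.offset for h in hits],
            "strand": [h.strand for h in hits],
            "score_bits": [h.score for h in hits],
            "p": [h.p for h in hits],
        }
    )
    out = {"hits": out_dir / "hits.tsv"}
    _write_tsv(df, out["hits"], {"stage": "scan", "pthresh": p_threshold})
    return out


def run_coevolve(cfg: dict, out_dir: Path, seed: int) -> dict[str, Path]:
    hits_df = pd.read_csv(cfg.get("hits", out_dir / "hits.tsv"), sep="\t", comment="#")
    mls_set = read_signed_gene_set(cfg.get("mls_genes", out_dir / "mls_genes.tsv"))
    species = read_species_tsv(cfg.get("species", out_dir / "species.tsv"))
    promoters = read_fasta_promoters(cfg.get("fasta", out_dir / "promoters.fa"))
    fdr = float(cfg.get("fdr", 0.05))

    promoter_genes = {g for g, _ in promoters}
    mls_genes = sorted(mls_set.genes() & promoter_genes)
    bg_genes = sorted(promoter_genes - mls_set.genes())
    if not mls_genes or not bg_genes:
        raise StageError("coevolve: no promoter-covered genes in a group")

    hits_by_key: dict[tuple[str, str], list[MotifHit]] = {}
    for row in hits_df.itertuples(index=False):
        hits_by_key.setdefault((row.motif, row.species), []).append(
            MotifHit(row.gene, row.species, row.motif, int(row.offset),
                     row.strand, float(row.score_bits), float(row.p))
        )
    motif_ids = sorted(hits_df["motif"].unique()) if len(hits_df) else []
    mls_stats: dict[str, dict[str, tuple[float, float]]] = {}
    bg_stats: dict[str, dict[str, tuple[float, float]]] = {}
    for motif_id in motif_ids:
        mls_stats[motif_id] = {}
        bg_stats[motif_id] = {}
        for rec in species:
            sp_hits = hits_by_key.get((motif_id, rec.species_id), [])
            mls_stats[motif_id][rec.species_id] = motif_gene_stats(sp_hits, mls_genes)
            bg_stats[motif_id][rec.species_id] = motif_gene_stats(sp_hits, bg_genes)

    records = coevolution_trend(mls_stats, bg_stats, species, fdr=fdr)
    df = pd.DataFrame(
        {
            "motif": [r.motif_id for r in records],
            "metric": [r.metric for r in records],
            "n_species": [len(r.species_ids) for r in records],
            "rho": [r.rho for r in records],
            "p": [r.p for r in records],
            "q": [r.q for r in records],
            "called": [r.called for r in records],
        }
    )
    out = {"coevo": out_dir / "coevo.tsv"}
    _write_tsv(df, out["coevo"], {"stage": "coevolve", "fdr": fdr})
    return out


_STAGE_RUNNERS = {
    "simulate": run_simulate,
    "associate": run_associate,
    "concord": run_concord,
    "enrich": run_enrich,
    "scan": run_scan,
    "coevolve": run_coevolve,
}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    try:
        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
    except (OSError, tomllib.TOMLDecodeError) as exc:
        raise ConfigError(f"cannot load config: {exc}") from exc
    if "seed" in cfg and not isinstance(cfg["seed"], int):
        raise ConfigError("seed must be an integer")
    enabled = cfg.get("stages", {})
    unknown = set(enabled) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s) in config: {sorted(unknown)}")
    for stage in STAGES:
        section = cfg.get(stage, {})
        if not isinstance(section, dict):
            raise ConfigError(f"[{stage}] must be a table")
    if enabled.get("concord") and not enabled.get("simulate"):
        if "set_b" not in cfg.get("concord", {}):
            raise ConfigError("concord enabled without a simulate stage: set_b required")
    return cfg


def run_pipeline(config_path, out_dir=None) -> RunManifest:
    """Execute enabled stages in dependency order; a stage failure aborts
    with a partial manifest attached to the raised StageError."""
    cfg = load_config(config_path)
    master_seed = int(cfg.get("seed", 0))
    out_dir = Path(out_dir or cfg.get("out_dir", "lifecon_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    enabled = cfg.get("stages", {s: True for s in STAGES})

    manifest = RunManifest(config=cfg, started=time.time())
    for stage in STAGES:
        if not enabled.get(stage, False):
            continue
        seed = stage_seed(master_seed, stage)
        manifest.seeds[stage] = seed
        logger.info("stage %s (seed %d)", stage, seed)
        try:
            outputs = _STAGE_RUNNERS[stage](cfg.get(stage, {}), out_dir, seed)
        except ConfigError:
            raise
        except Exception as exc:
            err = StageError(f"stage {stage!r} failed: {exc}")
            err.manifest = manifest
            raise err from exc
        manifest.record(stage, outputs)
    manifest.finished = time.time()
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
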