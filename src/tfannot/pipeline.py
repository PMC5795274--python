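"""End-to-end orchestration of the synthetic annotation workflow.

Stages: simulate -> call-targets -> merge -> annotate -> nullfdr ->
similarity -> diversity. Every stage writes its artifact under the output
directory and the run closes with a manifest (seed, thresholds, stage
outputs with SHA-256 digests), so a rerun with the same config is
byte-reproducible and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .compendium import Compendium, degree_statistics, master_regulators
from .diversity import diversity_profiles, pagerank, pleiotropy_association
from .enrichment import DEFAULT_UNIVERSE_POLICY, annotate_tfs, build_universe
from .io import write_gene_table, write_gmt
from .null_model import null_model_report
from .similarity import discordance_analysis, function_regulator_sharing, tf_pair_table
from .simulate import (
    SimulationConfig,
    default_config,
    generate_binding_signals,
    generate_compendium,
    generate_gene_space,
    sample_planted_links,
)
from .target_calling import call_targets_from_matrix

logger = logging.getLogger("tfannot")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Thresholds and sizes for one pipeline run; all randomness flows from
    ``seed`` (no stage reads the clock)."""

    seed: int = 0
    tg_fdr: float = 0.01
    association_fdr: float = 0.05
    neighbor_fdr: float = 0.01
    null_cutoffs: tuple[float, ...] = (0.001, 0.0001)
    null_p_flavor: str = "g"
    simulation: SimulationConfig | None = None

    def __post_init__(self) -> None:
        for name in ("tg_fdr", "association_fdr", "neighbor_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.simulation is None:
            self.simulation = default_config(seed=self.seed)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run all stages on synthetic data and write artifacts plus manifest.

    Returns the manifest dict. Any stage failure aborts with the stage name
    attached to the exception message.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    manifest: dict = {
        "tfannot_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "tg_fdr": config.tg_fdr,
            "association_fdr": config.association_fdr,
            "neighbor_fdr": config.neighbor_fdr,
        },
        "simulation": asdict(sim),
        "stages": {},
    }

    stage = "simulate"
    try:
        logger.info("[%s] seed=%d thresholds=%s", stage, config.seed,
                    manifest["thresholds"])
        genes, collections = generate_gene_space(sim)
        links = sample_planted_links(sim, collections)
        truth_comp, truth = generate_compendium(sim, genes, collections, links)
        write_gene_table(genes, outdir / "gene_table.tsv")
        for coll in collections:
            write_gmt(coll, outdir / f"annotations_{coll.name}.gmt")
        truth.to_csv(outdir / "planted_links.tsv", sep="\t", index=False)
        truth_comp.to_gmt(outdir / "compendium_truth.gmt")
        manifest["stages"][stage] = [
            "gene_table.tsv",
            *[f"annotations_{c.name}.gmt" for c in collections],
            "planted_links.tsv",
            "compendium_truth.gmt",
        ]

        stage = "call_targets"
        called = Compendium()
        gene_ids = genes["gene_id"].tolist()
        truth_targets = truth_comp.target_map()
        score_frames = []
        for tf in sorted(truth_targets):
            matrix = generate_binding_signals(sim, tf, truth_targets[tf], gene_ids)
            table = call_targets_from_matrix(matrix, fdr_threshold=config.tg_fdr)
            table.insert(0, "tf_id", tf)
            score_frames.append(table)
            for g in table.loc[table["called"], "gene_id"]:
                called.add_edge(tf, g, "other_high_throughput")
        pd.concat(score_frames).to_csv(outdir / "target_scores.tsv", sep="\t",
                                       index=False)
        called.to_gmt(outdir / "compendium_called.gmt")
        manifest["stages"][stage] = ["target_scores.tsv", "compendium_called.gmt"]

        stage = "merge"
        comp = called if called.n_edges else truth_comp
        stats = degree_statistics(comp)
        masters = master_regulators(comp)
        with open(outdir / "compendium_summary.json", "w") as fh:
            json.dump({"degree_statistics": stats,
                       "master_regulators": masters}, fh, indent=2)
        manifest["stages"][stage] = ["compendium_summary.json"]

        stage = "annotate"
        universes = {
            "coding": build_universe(genes, "coding"),
            "literature_rich": build_universe(
                genes, "literature_rich",
                curated_sources=[c.name for c in collections
                                 if c.source_type == "curated"],
            ),
        }
        associations = annotate_tfs(
            comp, collections, universes,
            universe_policy=DEFAULT_UNIVERSE_POLICY,
            fdr=config.association_fdr,
        )
        associations.to_csv(outdir / "associations.tsv", sep="\t", index=False)
        manifest["stages"][stage] = ["associations.tsv"]

        stage = "nullfdr"
        report = null_model_report(
            comp, collections, universes,
            seed=config.seed + 1_000_003,
            cutoffs=config.null_cutoffs,
            p_flavor=config.null_p_flavor,
            fdr=config.association_fdr,
        )
        report["fdr_table"].to_csv(outdir / "null_fdr.tsv", sep="\t", index=False)
        pairing = report["pairing"]
        with open(outdir / "null_triangle.json", "w") as fh:
            json.dump({"n_upper": pairing.n_upper, "n_lower": pairing.n_lower,
                       "n_tied": pairing.n_tied,
                       "estimated_true_associations":
                           report["estimated_true_associations"]}, fh, indent=2)
        manifest["stages"][stage] = ["null_fdr.tsv", "null_triangle.json"]

        stage = "similarity"
        known_sets = {
            tf: frozenset(
                t if t.startswith(coll.name) else f"{coll.name}:{t}"
                for coll in collections
                for t, members in coll.sets.items() if tf in members
            )
            for tf in comp.tfs
        }
        pool = universes["coding"]
        pairs = tf_pair_table(
            comp, pool, associations, known_function_sets=known_sets,
            tg_fdr=config.neighbor_fdr, target_fun_fdr=config.association_fdr,
        )
        pairs.to_csv(outdir / "tf_pairs.tsv", sep="\t", index=False)
        disc = discordance_analysis(pairs)
        disc.to_csv(outdir / "discordance.tsv", sep="\t", index=False)
        fun_pairs = function_regulator_sharing(associations, collections,
                                               universes["literature_rich"])
        fun_pairs.to_csv(outdir / "function_pairs.tsv", sep="\t", index=False)
        manifest["stages"][stage] = ["tf_pairs.tsv", "discordance.tsv",
                                     "function_pairs.tsv"]

        stage = "diversity"
        profiles = diversity_profiles(comp, associations, collections,
                                      universes, DEFAULT_UNIVERSE_POLICY)
        tf_net = nx.DiGraph(
            (tf, tg) for (tf, tg) in comp.edges if tg in comp.tfs
        )
        tf_net.add_nodes_from(comp.tfs)
        profiles["pagerank"] = pagerank(tf_net).reindex(profiles.index)
        profiles.to_csv(outdir / "diversity_profiles.tsv", sep="\t")
        assoc_report = {}
        try:
            assoc_report["pi_target_fun~pi_reg|n_tg"] = pleiotropy_association(
                profiles, "pi_target_fun", "pi_reg", covariates=["n_tg"]
            )
        except ValueError as exc:
            assoc_report["pi_target_fun~pi_reg|n_tg"] = {"error": str(exc)}
        with open(outdir / "pleiotropy_association.json", "w") as fh:
            json.dump(assoc_report, fh, indent=2)
        manifest["stages"][stage] = ["diversity_profiles.tsv",
                                     "pleiotropy_association.json"]
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["digests"] = {
        name: _digest(outdir / name)
        for names in manifest["stages"].values() for name in names
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
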