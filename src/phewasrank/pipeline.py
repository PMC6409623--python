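"""End-to-end orchestration: scores -> network -> rank -> validate -> predict.

A run is described by a single config (YAML-loadable) that supplies the
inputs either as file paths or as a simulation block, and it always
evaluates two arms side by side: the propagated ranking (PheWAS-Rank)
and the raw evidence ordering (pure -log p, equivalent to d = 0), since
every headline claim about propagation is a paired comparison against
the raw list. Outputs are the intermediate TSV/GMT files, a JSON run
report with input fingerprints, and a Markdown summary table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from . import __version__
from . import io as pio
from .containers import GeneSetCollection
from .enrich import overlap_stats
from .model import PheWASRank
from .rank import RankConfig, rank_genes, top_k
from .drugs import clinical_support_rate, compare_support, predict_agents
from .simulate import (
    SimulationConfig,
    simulate_drug_targets,
    simulate_gene_scores,
    simulate_network,
    simulate_reference_db,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one of ``inputs`` / ``simulate``.

    ``inputs`` maps the keys scores / network / reference / drug_targets
    to file paths (reference and drug_targets optional). ``simulate``
    holds :class:`SimulationConfig` fields.
    """

    outdir: Path
    rank: RankConfig = field(default_factory=RankConfig)
    top_k: int = 100
    inputs: Optional[Dict[str, str]] = None
    simulate: Optional[SimulationConfig] = None
    transpose: Optional[bool] = None
    universe: str = "intersection"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("exactly one of 'inputs' and 'simulate' must be given")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.transpose is None:
            # the attachment generator stores pairs dependent -> anchor,
            # the reverse of the engine's source-is-depended-upon
            # convention, so simulated networks propagate transposed
            self.transpose = self.simulate is not None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Dict[str, Any]) -> "PipelineConfig":
        rank_cfg = RankConfig(**raw.get("rank", {}))
        sim = raw.get("simulate")
        sim_cfg = SimulationConfig(**sim) if sim is not None else None
        return cls(
            outdir=Path(raw.get("outdir", "phewasrank_out")),
            rank=rank_cfg,
            top_k=int(raw.get("top_k", 100)),
            inputs=raw.get("inputs"),
            simulate=sim_cfg,
            transpose=raw.get("transpose"),
            universe=raw.get("universe", "intersection"),
        )


@dataclass
class RunReport:
    """Machine-readable record of one run."""

    version: str
    seed: Optional[int]
    parameters: Dict[str, Any]
    fingerprints: Dict[str, str]
    statistics: Dict[str, Any]

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_markdown(self) -> str:
        lines = [
            "# PheWAS-Rank run report",
            "",
            f"- version: {self.version}",
            f"- seed: {self.seed}",
            "",
            "| statistic | value |",
            "| --- | --- |",
        ]
        for key in sorted(self.statistics):
            lines.append(f"| {key} | {self.statistics[key]} |")
        return "\n".join(lines) + "\n"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage in order and write all artifacts under outdir.

    Stages: (a) obtain gene scores, (b) obtain the dependency network,
    (c) propagate and rank (both arms), (d) top-k validation against the
    reference set, (e) agent prediction and support comparison. Identical
    config and seed reproduce an identical report.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    fingerprints: Dict[str, str] = {}
    stats: Dict[str, Any] = {}
    t0 = time.time()

    # (a)+(b) inputs
    stage = "inputs"
    try:
        if config.simulate is not None:
            sim = config.simulate
            scores, truth = simulate_gene_scores(sim)
            network = simulate_network(truth, sim)
            reference = simulate_reference_db(truth, sim)
            drug_targets = simulate_drug_targets(truth, sim)
            pio.write_gene_scores(scores, outdir / "scores.tsv")
            pio.write_edge_list(network, outdir / "edges.tsv")
            pio.write_gmt(reference, outdir / "reference.gmt")
            pio.write_drug_targets(drug_targets, outdir / "drug_targets.tsv")
            with open(outdir / "truth.txt", "w", encoding="utf-8") as fh:
                fh.write("\n".join(sorted(truth.disease_genes)) + "\n")
            for name in ("scores.tsv", "edges.tsv", "reference.gmt", "drug_targets.tsv"):
                fingerprints[name] = _sha256(outdir / name)
            seed: Optional[int] = sim.seed
        else:
            paths = dict(config.inputs or {})
            if "scores" not in paths or "network" not in paths:
                raise ValueError("inputs must provide 'scores' and 'network' paths")
            scores = pio.read_gene_scores(paths["scores"], p_min=config.rank.p_min)
            network = pio.read_edge_list(paths["network"])
            reference = (
                pio.read_gmt(paths["reference"]) if "reference" in paths else None
            )
            drug_targets = (
                pio.read_drug_targets(paths["drug_targets"])
                if "drug_targets" in paths
                else None
            )
            for key, p in paths.items():
                fingerprints[key] = _sha256(Path(p))
            seed = None
        stats["n_genes_scored"] = len(scores)
        stats["n_network_nodes"] = network.n_nodes
        stats["n_network_edges"] = network.n_edges
        logger.info(
            "stage inputs: %d scored genes, network %d nodes / %d edges",
            len(scores),
            network.n_nodes,
            network.n_edges,
        )
    except Exception as exc:  # noqa: BLE001 - relabelled with stage
        raise PipelineError(stage, exc) from exc

    # (c) rank, both arms
    stage = "rank"
    try:
        model = PheWASRank(
            scores,
            network,
            config.rank,
            universe=config.universe,
            transpose=config.transpose,
        )
        results = model.fit()
        raw_ranking = rank_genes(model.initial_f())
        pio.write_ranked(results.ranking, outdir / "ranked.tsv")
        pio.write_ranked(raw_ranking, outdir / "ranked_raw.tsv")
        stats["n_genes_ranked"] = len(results.ranking)
        stats["n_iterations"] = results.n_iterations
        stats["converged"] = results.converged
        logger.info(
            "stage rank: %d genes, %d iterations, converged=%s",
            len(results.ranking),
            results.n_iterations,
            results.converged,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    k = config.top_k
    rank_top = results.top(k)
    raw_top = top_k(raw_ranking, k)

    # (d) validation
    stage = "validate"
    try:
        if reference is not None and len(reference):
            ref_genes = set().union(*(reference[n] for n in reference.names()))
            n_rank, pct_rank = overlap_stats(rank_top, ref_genes)
            n_raw, pct_raw = overlap_stats(raw_top, ref_genes)
            stats["topk_overlap_rank"] = n_rank
            stats["topk_overlap_rank_pct"] = pct_rank
            stats["topk_overlap_raw"] = n_raw
            stats["topk_overlap_raw_pct"] = pct_raw
            try:
                table, chi2 = results.enrichment_vs(raw_top, ref_genes, k=k)
                stats["enrichment_chi2"] = chi2.statistic
                stats["enrichment_chi2_p"] = chi2.p_value
            except ValueError as exc:
                stats["enrichment_chi2_note"] = str(exc)
        if drug_targets is not None:
            supported_targets = set()
            for agent, targets in drug_targets.targets_by_agent().items():
                if drug_targets.support[agent]:
                    supported_targets |= targets
            in_list = supported_targets & set(results.ranking.gene_ids)
            if in_list and len(in_list) < len(results.ranking):
                ks = results.ks_enrichment(supported_targets)
                stats["ks_D"] = ks.D
                stats["ks_p"] = ks.p_value
                stats["ks_n_targets"] = ks.n_targets
        logger.info("stage validate: %s", {k_: stats[k_] for k_ in stats if "overlap" in k_})
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # (e) drug prediction
    stage = "predict"
    try:
        if drug_targets is not None:
            pred_rank = predict_agents(rank_top, drug_targets)
            pred_raw = predict_agents(raw_top, drug_targets)
            with open(outdir / "agents.tsv", "w", encoding="utf-8") as fh:
                fh.write("agent_id\tn_hit_targets\thit_targets\tsupported\n")
                for p in pred_rank:
                    fh.write(
                        f"{p.agent_id}\t{len(p.hit_targets)}\t"
                        f"{';'.join(sorted(p.hit_targets))}\t{int(p.supported)}\n"
                    )
            if pred_rank:
                s, n, pct = clinical_support_rate(pred_rank)
                stats["agents_rank"] = n
                stats["agents_rank_supported"] = s
                stats["agents_rank_support_pct"] = pct
            if pred_raw:
                s, n, pct = clinical_support_rate(pred_raw)
                stats["agents_raw"] = n
                stats["agents_raw_supported"] = s
                stats["agents_raw_support_pct"] = pct
            if pred_rank and pred_raw:
                try:
                    chi2 = compare_support(
                        (stats["agents_rank_supported"], stats["agents_rank"]),
                        (stats["agents_raw_supported"], stats["agents_raw"]),
                    )
                    stats["support_chi2"] = chi2.statistic
                    stats["support_chi2_p"] = chi2.p_value
                except ValueError as exc:
                    stats["support_chi2_note"] = str(exc)
            logger.info(
                "stage predict: %s agents (rank arm), %s agents (raw arm)",
                stats.get("agents_rank"),
                stats.get("agents_raw"),
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    logger.info("pipeline finished in %.2f s", time.time() - t0)
    params = {
        "d": config.rank.d,
        "epsilon": config.rank.epsilon,
        "log_base": config.rank.log_base,
        "top_k": config.top_k,
        "universe": config.universe,
        "transpose": config.transpose,
    }
    if config.simulate is not None:
        params["simulate"] = dataclasses.asdict(config.simulate)
    report = RunReport(
        version=__version__,
        seed=seed,
        parameters=params,
        fingerprints=fingerprints,
        statistics=stats,
    )
    report.to_json(outdir / "report.json")
    with open(outdir / "report.md", "w", encoding="utf-8") as fh:
        fh.write(report.to_markdown())
    return report
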