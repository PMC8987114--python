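"""Pipeline configuration, orchestration and run manifest.

All analysis thresholds live in :class:`PipelineConfig` (YAML-loadable,
CLI-overridable) and every stage reads them from there.  ``run_all`` wires
the stages together — sample QC, soft-threshold selection, network, module
detection, module--trait association, differential correlation on the two
key modules, hub ranking, differential expression and optional enrichment —
and records a :class:`RunManifest` with the config echo, per-file checksums
and warnings so that reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io import (
    ExpressionMatrix, TraitVector, read_expression, read_traits, read_gmt,
    write_expression, write_network,
)
from .simulate import SimulationParams, simulate
from .network import adjacency, correlation_matrix, dist_tom, pick_soft_threshold, tom
from .modules import (
    cluster_samples, detect_modules, gene_significance_mm, module_eigengenes,
    module_trait, select_key_modules,
)
from .diffcorr import diffcorr_scan, split_by_condition, switched_pairs
from .downstream import differential_expression, enrich, rank_hubs

logger = logging.getLogger("coexdiff")

__all__ = ["PipelineConfig", "RunManifest", "run_simulate", "run_all"]


@dataclass
class PipelineConfig:
    """All user-settable pipeline parameters with their documented defaults.

    Defaults mirror the settings of the reference sepsis analysis: power 5,
    minimum module size 30, lfdr cut 0.05, alpha 0.05 for both differential
    expression and enrichment.
    """

    expression: str | None = None
    traits: str | None = None
    gene_sets: str | None = None          # optional GMT for enrichment
    out_dir: str = "results"
    power: int | None = 5                 # None => select from candidates
    candidate_powers: list[int] = field(default_factory=lambda: list(range(1, 21)))
    target_r2: float = 0.80
    min_module_size: int = 30
    cut_fraction: float = 0.99
    sample_cut_quantile: float = 0.99
    lfdr_cut: float = 0.05
    dge_alpha: float = 0.05
    enrich_alpha: float = 0.05
    welch: bool = False
    seed: int = 0
    # synthetic-data parameters (simulate subcommand)
    sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("target_r2", "lfdr_cut", "dge_alpha", "enrich_alpha",
                     "cut_fraction", "sample_cut_quantile"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.power is not None and self.power < 1:
            raise ValueError("power must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    version: str
    config: dict
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    warnings: list[str] = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def _provenance_header(config: PipelineConfig, stage: str) -> str:
    return (f"# coexdiff {__version__} | stage={stage} | seed={config.seed} | "
            f"power={config.power} | min_module_size={config.min_module_size} | "
            f"lfdr_cut={config.lfdr_cut}\n")


def _write_tsv(df, path: Path, config: PipelineConfig, stage: str,
               index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(config, stage))
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def run_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Generate a synthetic dataset and write expression/trait/truth files."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_kwargs = dict(config.sim)
    sim_kwargs.setdefault("seed", config.seed)
    if "module_sizes" in sim_kwargs:
        sim_kwargs["module_sizes"] = tuple(sim_kwargs["module_sizes"])
    if "n_samples" in sim_kwargs:
        sim_kwargs["n_samples"] = tuple(sim_kwargs["n_samples"])
    if "trait_linked_modules" in sim_kwargs:
        sim_kwargs["trait_linked_modules"] = tuple(sim_kwargs["trait_linked_modules"])
    params = SimulationParams(**sim_kwargs)
    expr, traits, truth = simulate(params)

    paths = {
        "expression": out / "expression.tsv",
        "traits": out / "traits.tsv",
        "truth": out / "truth.json",
    }
    write_expression(expr, paths["expression"])
    with open(paths["traits"], "w") as fh:
        fh.write("sample_id\tlabel\n")
        for s, l in zip(traits.sample_ids, traits.labels):
            fh.write(f"{s}\t{l}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "module_of_gene": truth.module_of_gene,
                "trait_linked_modules": sorted(truth.trait_linked_modules),
                "switch_pairs": [list(p) for p in truth.switch_pairs],
                "params": dataclasses.asdict(params),
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    logger.info("simulated %d genes x %d samples (seed %d)",
                expr.n_genes, expr.n_samples, params.seed)
    return paths


def run_all(config: PipelineConfig,
            expr: ExpressionMatrix | None = None,
            traits: TraitVector | None = None) -> RunManifest:
    """Execute the full two-stage analysis and write all result tables.

    Either pass in-memory inputs or set ``config.expression`` /
    ``config.traits``.  Outputs land under ``config.out_dir``; the manifest
    (run_manifest.json) lists each file's sha256 so determinism can be
    checked by rerunning with the same config.
    """
    collector = _WarningCollector()
    logger.addHandler(collector)
    manifest = RunManifest(version=__version__, config=config.to_dict(),
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        if expr is None:
            if not config.expression:
                raise FileNotFoundError("no expression matrix configured")
            expr = read_expression(config.expression)
        if traits is None:
            if not config.traits:
                raise FileNotFoundError("no trait table configured")
            traits = read_traits(config.traits, expr)
        traits = traits.aligned_to(expr)

        # stage 1: sample QC
        _, kept = cluster_samples(expr, config.sample_cut_quantile)
        if len(kept) < expr.n_samples:
            expr = expr.subset_samples(kept)
            traits = TraitVector(
                tuple(kept),
                np.array([traits.labels[traits.sample_ids.index(s)] for s in kept]),
            )

        # stage 2: network construction
        if config.power is None:
            fit = pick_soft_threshold(expr, config.candidate_powers,
                                      config.target_r2)
            power = fit.power
            logger.info("selected power %d (scale-free R^2 = %.3f)",
                        power, fit.r_squared)
        else:
            power = config.power
        S = correlation_matrix(expr, unsigned=True)
        adj = adjacency(S, power)
        tom_matrix = tom(adj)
        dist = dist_tom(tom_matrix)

        # stage 3: modules and trait association
        _, assignment = detect_modules(dist, expr.gene_ids,
                                       min_module_size=config.min_module_size,
                                       cut_fraction=config.cut_fraction)
        _write_tsv(assignment.to_frame(), out / "modules.tsv", config,
                   "modules", index=False)
        me = module_eigengenes(expr, assignment)
        mt = module_trait(me, traits)
        _write_tsv(mt.table, out / "module_trait.tsv", config, "module_trait")
        gene_significance_mm(expr, traits, me, assignment)
        positive, negative = select_key_modules(mt, allow_single=True)

        # stage 4: differential correlation on the key modules
        cond1, cond2 = split_by_condition(expr, traits)
        all_switched = []
        for label in [m for m in (positive, negative) if m]:
            genes = assignment.members(label)
            if len(genes) < 2:
                continue
            table = diffcorr_scan(cond1, cond2, genes)
            _write_tsv(table.to_frame(), out / f"diffcorr_{label}.tsv",
                       config, f"diffcorr:{label}", index=False)
            all_switched.extend(switched_pairs(table, config.lfdr_cut))

        write_network(all_switched, out / "switched_pairs.tsv", "edge_tsv")
        if all_switched:
            write_network(all_switched, out / "switched_pairs.graphml", "graphml")

        # stage 5: hubs, differential expression, optional enrichment
        hubs = rank_hubs(all_switched)
        _write_tsv(hubs.table, out / "hubs.tsv", config, "hubs")
        dge = differential_expression(cond1, cond2, welch=config.welch,
                                      alpha=config.dge_alpha)
        _write_tsv(dge.table, out / "dge.tsv", config, "dge")
        if config.gene_sets:
            sets = read_gmt(config.gene_sets)
            query = dge.significant_genes()
            if query:
                enr = enrich(query, list(expr.gene_ids), sets,
                             alpha=config.enrich_alpha)
                _write_tsv(enr.table, out / "enrichment.tsv", config, "enrich")

        for path in sorted(out.glob("*.tsv")) + sorted(out.glob("*.graphml")):
            manifest.outputs[path.name] = _sha256(path)
        manifest.warnings = list(collector.messages)
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.write(out / "run_manifest.json")
        return manifest
    except Exception:
        (out / "failed").mkdir(exist_ok=True)
        raise
    finally:
        logger.removeHandler(collector)
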