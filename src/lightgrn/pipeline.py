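"""Pipeline orchestration: simulate -> stage1 -> stage2 -> compare.

A validated :class:`PipelineConfig` drives the whole run; every stage logs
its counts (genes in the pool, edges retained and deleted at each filter)
so the candidate -> rough -> refined funnel is auditable, and a manifest
(config echo, input checksums, seed, per-stage counts) is written at the
end.  Identical config and inputs yield identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import io as _io
from .compare import (
    GeneNetwork,
    degree_rank_table,
    differential_networks,
    export_network,
    summarize_network,
)
from .errors import ConfigError
from .refine import refine_network
from .rough import build_rough_network

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

DEFAULT_CONDITIONS = ("PSI-to-PSII", "PSII-to-PSI")


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run.

    ``expression`` maps condition labels to expression-matrix paths; the
    remaining fields expose the knobs of the two stages (Stage I deletion
    fraction, sigmoid rate, interpolation step, AIC search mode).
    """

    expression: dict[str, str]
    candidates: str
    seed_genes: str
    out_dir: str = "lightgrn_out"
    fraction: float = 0.10
    sigmoid_r: float = 1.0
    standardize_sigmoid: bool = True
    step: float = 0.5
    interp_kind: str = "log-cubic"
    collocation: str = "midpoint"
    aic_mode: str = "greedy_backward"
    aic_n_eff: int | str | None = None
    exhaustive_cap: int = 12
    allow_self_edges: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction < 1.0):
            raise ConfigError(f"fraction must be in [0, 1), got {self.fraction}")
        if self.step <= 0:
            raise ConfigError(f"interpolation step must be positive, got {self.step}")
        if self.sigmoid_r <= 0:
            raise ConfigError(f"sigmoid rate must be positive, got {self.sigmoid_r}")
        if self.aic_mode not in ("greedy_backward", "exhaustive"):
            raise ConfigError(f"unknown AIC mode {self.aic_mode!r}")
        if self.collocation not in ("midpoint", "left"):
            raise ConfigError(f"unknown collocation {self.collocation!r}")
        if isinstance(self.aic_n_eff, str) and self.aic_n_eff != "design":
            raise ConfigError(f"aic_n_eff must be an integer, 'design' or null")
        if not self.expression:
            raise ConfigError("at least one condition's expression matrix is required")
        labels = list(self.expression)
        if len(set(labels)) != len(labels):
            raise ConfigError("condition labels must be distinct")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as err:
            raise ConfigError(str(err)) from None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_mapping(data)

    def echo(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute both stages per condition, then the comparison.

    Returns the run manifest (also written to ``<out_dir>/manifest.json``).
    Fatal errors in a stage abort with a stage-named diagnostic.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.echo(),
        "seed": config.seed,
        "inputs": {},
        "stages": {},
        "outputs": {},
        "partial": False,
    }
    for label, path in config.expression.items():
        if not Path(path).exists():
            raise ConfigError(f"expression matrix for {label!r} not found: {path}")
        manifest["inputs"][f"expression_{label}"] = _checksum(path)
    for name in ("candidates", "seed_genes"):
        path = getattr(config, name)
        if not Path(path).exists():
            raise ConfigError(f"{name} file not found: {path}")
        manifest["inputs"][name] = _checksum(path)

    try:
        predictions = _io.read_candidate_table(config.candidates)
        seeds = _io.read_gene_list(config.seed_genes)
    except Exception as err:
        raise ConfigError(f"stage1 input parsing failed: {err}") from err

    networks: dict[str, GeneNetwork] = {}
    for label, path in config.expression.items():
        dataset = _io.read_expression_matrix(path, condition=label)
        logger.info("[stage1:%s] %d genes, %d candidate predictions",
                    label, len(dataset), len(predictions))
        rough = build_rough_network(
            seeds, predictions, dataset,
            fraction=config.fraction, allow_self_edges=config.allow_self_edges,
        )
        rough_path = _io.write_rough_network(rough, out / f"rough_{label}.tsv")
        logger.info("[stage1:%s] rough network: %d genes, %d edges",
                    label, len(rough.genes), rough.n_edges)

        refined = refine_network(
            rough, dataset,
            mode=config.aic_mode, step=config.step, r=config.sigmoid_r,
            standardize=config.standardize_sigmoid,
            exhaustive_cap=config.exhaustive_cap, n_eff=config.aic_n_eff,
            interp_kind=config.interp_kind, collocation=config.collocation,
            logger=logger,
        )
        networks[label] = refined
        refined_path = export_network(refined, out / f"refined_{label}.tsv", "tsv")
        export_network(refined, out / f"refined_{label}.sif", "sif")
        export_network(refined, out / f"refined_{label}.graphml", "graphml")
        report = {
            t: {
                "regulators": list(f.regulators),
                "b": f.b,
                "beta": f.beta,
                "k": f.k,
                "sigma2": f.sigma2,
                "loglik": f.loglik,
                "aic": f.aic,
                "trace": [[r, a] for r, a in f.trace],
                "flags": list(f.flags),
            }
            for t, f in refined.fits.items()
        }
        (out / f"fits_{label}.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        logger.info("[stage2:%s] refined network: %d nodes, %d edges",
                    label, refined.n_nodes, refined.n_edges)
        manifest["stages"][label] = {
            "n_genes": len(dataset),
            "n_candidates": len(predictions),
            "n_rough_edges": rough.n_edges,
            "n_refined_edges": refined.n_edges,
        }
        manifest["outputs"][f"rough_{label}"] = str(rough_path)
        manifest["outputs"][f"refined_{label}"] = str(refined_path)
        (out / f"summary_{label}.json").write_text(
            json.dumps(summarize_network(refined), indent=2, sort_keys=True)
        )

    if len(networks) == 2:
        a, b = (networks[l] for l in config.expression)
        diff = differential_networks(a, b)
        for name, edge_set in (
            ("common", diff.common),
            (f"only_{a.condition}", diff.only_a),
            (f"only_{b.condition}", diff.only_b),
        ):
            path = out / f"differential_{name}.tsv"
            lines = ["tf_id\ttarget_id"] + [f"{u}\t{v}" for u, v in sorted(edge_set)]
            path.write_text("\n".join(lines) + "\n")
            manifest["outputs"][f"differential_{name}"] = str(path)
        table = degree_rank_table((a, b))
        table_path = out / "degree_table.tsv"
        table.to_csv(table_path, sep="\t", index=False)
        manifest["outputs"]["degree_table"] = str(table_path)
        manifest["stages"]["compare"] = {
            "n_common": len(diff.common),
            f"n_only_{a.condition}": len(diff.only_a),
            f"n_only_{b.condition}": len(diff.only_b),
            "n_sign_conflicts": len(diff.sign_conflicts),
        }

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
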