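"""End-to-end pipeline orchestration with reproducible seeds and a manifest.

A run is described by a :class:`RunConfig` (usually loaded from YAML):
which stages to execute, the analysis thresholds, and a master seed.  Each
stochastic stage derives its own seed deterministically from the master
seed plus a stage tag, so stages can be re-run standalone and still
reproduce the orchestrated run.  A JSON manifest records versions, seeds,
input/output checksums and stage timings.
"""

from __future__ import annotations

import hashlib
import json
import platform
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as ccio
from .de import permutation_de_test
from .deconvolution import consensus_purity, deconvolute, prepare_expression
from .genomic import map_segments_to_genes, two_group_locus_test
from .synthetic import SimulationConfig, simulate_cohort, write_cohort

STAGE_DEPS: dict[str, list[str]] = {
    "simulate": [],
    "deconvolute": ["simulate"],
    "de_test": ["deconvolute"],
    "cna_test": ["simulate"],
}
DEFAULT_STAGES = ("simulate", "deconvolute", "de_test")


@dataclass
class RunConfig:
    out_dir: str = "run_out"
    stages: tuple[str, ...] = DEFAULT_STAGES
    seed: int = 0
    min_median: float = 2.0
    q_threshold: float = 0.25
    n_perm: int = 50_000
    groups: tuple[str, str] = ("IN", "MM")
    mixing_scale: str = "log2"
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        cfg.stages = tuple(cfg.stages)
        cfg.groups = tuple(cfg.groups)
        return cfg


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(master_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_stages(stages: tuple[str, ...]) -> None:
    unknown = [s for s in stages if s not in STAGE_DEPS]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    enabled = set(stages)
    for s in stages:
        missing = [d for d in STAGE_DEPS[s] if d not in enabled]
        if missing:
            raise ValueError(
                f"stage {s!r} requires disabled stage(s) {missing}; "
                "enable them or provide their outputs"
            )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and write a manifest."""
    validate_stages(config.stages)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "master_seed": config.seed,
        "stages": [],
    }
    ctx: dict = {}

    order = [s for s in ("simulate", "deconvolute", "de_test", "cna_test")
             if s in config.stages]
    for stage in order:
        t0 = time.perf_counter()
        seed = stage_seed(config.seed, stage)
        outputs = _STAGE_FNS[stage](config, seed, out, ctx)
        manifest["stages"].append({
            "name": stage,
            "seed": seed,
            "duration_s": round(time.perf_counter() - t0, 3),
            "outputs": {str(p): _sha256(p) for p in outputs},
        })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _stage_simulate(config: RunConfig, seed: int, out: Path, ctx: dict) -> list[Path]:
    sim_cfg = SimulationConfig.from_dict({"seed": seed, **config.simulation})
    expr, annot, truth = simulate_cohort(sim_cfg)
    paths = write_cohort(expr, annot, truth, out / "cohort")
    ctx.update(expr=expr, annotation=annot, truth=truth)
    return list(paths.values())


def _stage_deconvolute(config: RunConfig, seed: int, out: Path, ctx: dict) -> list[Path]:
    expr, annot = ctx["expr"], ctx["annotation"]
    purity_table = pd.read_csv(out / "cohort" / "purity.tsv", sep="\t", index_col=0)
    purity = consensus_purity(purity_table)
    prepared = prepare_expression(expr, min_median=config.min_median)
    profile = deconvolute(prepared, purity, annot["group"],
                          mixing_scale=config.mixing_scale)
    path = out / "compartment_profile.tsv"
    profile.table.to_csv(path, sep="\t", index=False)
    ctx.update(prepared=prepared, purity=purity, profile=profile)
    return [path]


def _stage_de_test(config: RunConfig, seed: int, out: Path, ctx: dict) -> list[Path]:
    result = permutation_de_test(
        ctx["prepared"], ctx["purity"], ctx["annotation"]["group"],
        groups=config.groups, n_perm=config.n_perm, seed=seed,
        mixing_scale=config.mixing_scale,
    )
    path = out / "de_results.tsv"
    result.to_csv(path, sep="\t")
    return [path]


def _stage_cna_test(config: RunConfig, seed: int, out: Path, ctx: dict) -> list[Path]:
    truth, annot = ctx["truth"], ctx["annotation"]
    coords = ccio.read_gene_coordinates(out / "cohort" / "gene_coords.bed")
    gene_cna = map_segments_to_genes(truth.segments, coords)
    result = two_group_locus_test(gene_cna, annot["group"], groups=config.groups,
                                  q_threshold=config.q_threshold)
    path = out / "cna_test.tsv"
    result.to_csv(path, sep="\t")
    return [path]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "deconvolute": _stage_deconvolute,
    "de_test": _stage_de_test,
    "cna_test": _stage_cna_test,
}
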