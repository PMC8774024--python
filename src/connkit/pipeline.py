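"""End-to-end orchestration: simulate/load -> backbone -> metrics -> NBS ->
group statistics -> report.

One master seed deterministically derives per-stage seeds via
``numpy.random.SeedSequence([master_seed, stage_index])`` with a fixed stage
numbering (0 simulate, 1 null models, 2 NBS), so any stage can be rerun in
isolation with the same stream.  Outputs: tidy metric CSVs, NBS JSON, a
group-statistics CSV, and a markdown summary; identical config + seed gives
byte-identical files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import backbone as bb
from . import metrics as gm
from . import nbs as nbs_mod
from . import simulate as sim
from . import stats as gs
from .core import StudyCohort, ValidationError, load_cohort

__all__ = ["PipelineConfig", "validate_config", "stage_seed", "run_pipeline"]

log = logging.getLogger("connkit")

_GLOBAL_METRICS = ["global_efficiency", "shortest_path_length",
                   "local_efficiency", "clustering_coefficient"]
_NODAL_METRICS = ["nodal_efficiency", "degree_centrality",
                  "betweenness_centrality", "clustering_coefficient",
                  "nodal_shortest_path_length"]


def stage_seed(master_seed: int, stage_index: int) -> int:
    """Derive a per-stage seed from the master seed (documented scheme)."""
    return int(np.random.SeedSequence(
        [int(master_seed), int(stage_index)]).generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    cohort_dir: str | None = None      # read manifest.json here; None = simulate
    output_dir: str = "connkit_out"
    seed: int = 0
    backbone_threshold: float = 0.75
    backbone_scope: str = "pooled"
    weightings: tuple[str, ...] = ("binary", "FA", "FN", "FL")
    n_per_group: int = 10
    n_perm: int = 5000
    primary_alpha: float = 0.01
    component_stat: str = "extent"
    n_null: int = 100
    swaps_per_edge: int = 10
    fdr_alpha: float = 0.05
    nbs_alpha: float = 0.05
    small_world: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.backbone_threshold < 1.0):
            raise ValidationError("backbone_threshold must lie in (0, 1)")
        if not (0.0 < self.fdr_alpha < 1.0) or not (0.0 < self.nbs_alpha < 1.0):
            raise ValidationError("alpha values must lie in (0, 1)")
        # delegate range checks to the stage configs
        nbs_mod.NBSConfig(n_perm=self.n_perm, primary_alpha=self.primary_alpha,
                          component_stat=self.component_stat)
        gm.NullModelConfig(n_null=self.n_null,
                           swaps_per_edge=self.swaps_per_edge)


def validate_config(path: str | Path) -> PipelineConfig:
    """Load a YAML/JSON config; unknown keys are an error, defaults fill the rest."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError("config must be a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    if "weightings" in data:
        data["weightings"] = tuple(data["weightings"])
    return PipelineConfig(**data)


def _echo_config(cfg: PipelineConfig, outdir: Path) -> None:
    d = asdict(cfg)
    d["weightings"] = list(cfg.weightings)
    with open(outdir / "config_resolved.json", "w") as fh:
        json.dump(d, fh, indent=1)


def _markdown_report(cfg: PipelineConfig, nbs_results: dict,
                     global_stats: pd.DataFrame,
                     nodal_stats: pd.DataFrame) -> str:
    lines = ["# Connectome group analysis report", ""]
    lines.append("## Significant connections (NBS)")
    any_sig = False
    for w, res in nbs_results.items():
        for comp in res.significant(cfg.nbs_alpha):
            any_sig = True
            for a, b in comp.edges:
                lines.append(f"- {a} -- {b} ({w}), component "
                             f"{res.config.component_stat}={comp.stat:g}, "
                             f"p_fwe={comp.p_fwe:.4f}")
    if not any_sig:
        lines.append("- none")
    lines.append("")
    lines.append("## Global properties (ANOVA on z-scores, FDR corrected)")
    lines.append("")
    if not global_stats.empty:
        cols = [c for c in global_stats.columns if c != "degenerate"]
        lines.append(global_stats[cols].round(4).to_markdown(index=False))
    lines.append("")
    lines.append("## Nodal properties with q < {:.2f}".format(cfg.fdr_alpha))
    lines.append("")
    if not nodal_stats.empty:
        sig = nodal_stats[nodal_stats["q_fdr"] < cfg.fdr_alpha]
        if len(sig):
            cols = [c for c in sig.columns if c != "degenerate"]
            lines.append(sig[cols].round(4).to_markdown(index=False))
        else:
            lines.append("none")
    lines.append("")
    return "\n".join(lines)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns a dict of in-memory results and writes the
    report bundle under ``cfg.output_dir``."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _echo_config(cfg, outdir)

    def timed(stage, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        log.info("stage %s done in %.2f s", stage, time.perf_counter() - t0)
        return result

    if cfg.cohort_dir is not None:
        cohort: StudyCohort = timed(
            "load", load_cohort, Path(cfg.cohort_dir) / "manifest.json")
    else:
        sim_cfg = sim.default_config(seed=stage_seed(cfg.seed, 0),
                                     n_per_group=cfg.n_per_group)
        cohort = timed("simulate", sim.generate_cohort, sim_cfg)
        timed("save-cohort", sim.simulate_to_dir, sim_cfg, outdir / "cohort")

    mask = timed("backbone", bb.consistency_mask, cohort,
                 cfg.backbone_threshold, scope=cfg.backbone_scope)

    null_cfg = (gm.NullModelConfig(n_null=cfg.n_null,
                                   swaps_per_edge=cfg.swaps_per_edge,
                                   seed=stage_seed(cfg.seed, 1))
                if cfg.small_world else None)
    global_df, nodal_df = timed("metrics", gm.compute_all, cohort, mask,
                                null_cfg, cfg.weightings)
    global_df.to_csv(outdir / "global_metrics.csv", index=False)
    nodal_df.to_csv(outdir / "nodal_metrics.csv", index=False)

    nbs_results = {}
    weighted = [w for w in cfg.weightings if w != "binary"]
    for i, w in enumerate(weighted):
        nbs_cfg = nbs_mod.NBSConfig(n_perm=cfg.n_perm,
                                    primary_alpha=cfg.primary_alpha,
                                    component_stat=cfg.component_stat,
                                    seed=stage_seed(cfg.seed, 2) + i)
        nbs_results[w] = timed(f"nbs-{w}", nbs_mod.nbs_test, cohort, w,
                               mask, nbs_cfg)
    with open(outdir / "nbs_results.json", "w") as fh:
        json.dump({w: r.to_dict() for w, r in nbs_results.items()}, fh, indent=1)

    gstats = timed("group-stats-global", gs.group_metric_analysis, global_df,
                   _GLOBAL_METRICS, by_node=False, fdr_alpha=cfg.fdr_alpha)
    nstats = timed("group-stats-nodal", gs.group_metric_analysis, nodal_df,
                   _NODAL_METRICS, by_node=True, fdr_alpha=cfg.fdr_alpha)
    gstats.to_csv(outdir / "group_stats_global.csv", index=False)
    nstats.to_csv(outdir / "group_stats_nodal.csv", index=False)

    report = _markdown_report(cfg, nbs_results, gstats, nstats)
    (outdir / "report.md").write_text(report)

    return {"cohort": cohort, "mask": mask, "global_metrics": global_df,
            "nodal_metrics": nodal_df, "nbs": nbs_results,
            "global_stats": gstats, "nodal_stats": nstats,
            "report": report}
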