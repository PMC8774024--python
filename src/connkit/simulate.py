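"""Synthetic three-group cohorts of multi-weighted connectomes.

The generator emulates the statistical structure of a motor-sensory
white-matter study with two patient groups (Ep: stimulation-related epilepsy;
nEp: no epilepsy) and matched controls (con), n = 10 per group:

* one population template per weighting over a single shared binary support
  (deterministic tractography yields one streamline set per subject, from
  which all weightings derive), with bilateral medial-area-6 hubs connected
  to most other nodes and homotopic left/right pairs always connected;
* per-subject multiplicative lognormal edge noise;
* planted *edge effects*: multiplicative reductions of specific edges in
  specific weightings for specific patient groups (the reported connection
  findings are reductions, so multipliers lie in (0, 1]);
* planted *hub dropout*: each hub-incident edge is independently deleted from
  a patient subject's support with a per-group probability, emulating hub
  disconnection; this is what drives the global/nodal efficiency and degree
  reductions in every weighting, binary included.

Stripping all effects (:func:`null_cohort`) gives groups that differ only by
label — the type-I-error harness for the downstream statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import (
    GROUPS,
    WEIGHTINGS,
    AtlasDefinition,
    ConnectomeMatrix,
    StudyCohort,
    Subject,
    ValidationError,
    default_atlas,
    exclude_nodes,
    DEFAULT_EXCLUDED_NODES,
    save_cohort,
)

__all__ = [
    "PlantedEffect",
    "SimulationConfig",
    "default_config",
    "generate_template",
    "generate_cohort",
    "null_cohort",
]


@dataclass(frozen=True)
class PlantedEffect:
    """Multiplicative reduction of one edge in one weighting for some groups."""

    edge: tuple[str, str]
    weighting: str
    groups_affected: tuple[str, ...]
    multiplier: float

    def __post_init__(self) -> None:
        if not (0.0 < self.multiplier <= 1.0):
            raise ValidationError(
                f"multiplier must lie in (0, 1], got {self.multiplier}")
        if self.weighting not in WEIGHTINGS:
            raise ValidationError(f"unknown weighting {self.weighting!r}")


def _default_effects() -> tuple[PlantedEffect, ...]:
    # FA reduction at the interhemispheric SMA edge in the epilepsy group
    # only; FN reduction at the two trunk/limb sensorimotor edges in both
    # patient groups.  Multipliers of 0.6 give power >= 0.8 at n = 10.
    return (
        PlantedEffect(("A6m_L", "A6m_R"), "FA", ("Ep",), 0.6),
        PlantedEffect(("A123tru_L", "A4ul_L"), "FN", ("Ep", "nEp"), 0.6),
        PlantedEffect(("A123tru_R", "A4t_R"), "FN", ("Ep", "nEp"), 0.6),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters.

    Scale parameters must be positive; ``edge_density`` must yield a connected
    template (redrawn up to 1000 times).  ``hub_dropout`` maps group label to
    the per-edge probability that a hub-incident edge is deleted from that
    subject's support.
    """

    n_per_group: int = 10
    seed: int = 0
    hub_nodes: tuple[str, ...] = ("A6m_L", "A6m_R")
    edge_density: float = 0.35
    fn_log_mean: float = 4.0     # lognormal of FN: median ~ e^4 ~ 55 streamlines
    fn_log_sd: float = 0.8
    fa_mean: float = 0.5         # truncated normal on (0.2, 0.8)
    fa_sd: float = 0.1
    fl_mean: float = 60.0        # mm, truncated normal on (0, inf)
    fl_sd: float = 15.0
    subject_noise_sd: float = 0.05
    effects: tuple[PlantedEffect, ...] = field(default_factory=_default_effects)
    hub_dropout: Mapping[str, float] = field(
        default_factory=lambda: {"Ep": 0.30, "nEp": 0.15, "con": 0.0})
    hub_connect_prob: float = 0.9

    def __post_init__(self) -> None:
        for name in ("fn_log_sd", "fa_sd", "fl_sd", "fa_mean", "fl_mean"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not (0.0 < self.edge_density <= 1.0):
            raise ValidationError("edge_density must lie in (0, 1]")
        if self.subject_noise_sd < 0:
            raise ValidationError("subject_noise_sd must be >= 0")


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    return replace(SimulationConfig(seed=seed), **overrides)


def _study_atlas() -> AtlasDefinition:
    return exclude_nodes(default_atlas(), DEFAULT_EXCLUDED_NODES)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _draw_support(rng: np.random.Generator, cfg: SimulationConfig,
                  ids: Sequence[str]) -> np.ndarray:
    """One symmetric boolean support: hubs densely connected, homotopic pairs
    always connected, other pairs with probability ``edge_density``."""
    n = len(ids)
    idx = {v: i for i, v in enumerate(ids)}
    hubs = [idx[h] for h in cfg.hub_nodes if h in idx]
    sup = np.zeros((n, n), dtype=bool)
    iu = np.triu_indices(n, k=1)
    sup[iu] = rng.random(len(iu[0])) < cfg.edge_density
    for h in hubs:
        for j in range(n):
            if j != h:
                if rng.random() < cfg.hub_connect_prob:
                    sup[min(h, j), max(h, j)] = True
    # homotopic left/right pairs share a stem
    for i, a in enumerate(ids):
        stem, hemi = a.rsplit("_", 1)
        if hemi == "L" and f"{stem}_R" in idx:
            j = idx[f"{stem}_R"]
            sup[min(i, j), max(i, j)] = True
    # edges carrying planted effects must exist in the template
    for eff in cfg.effects:
        if all(v in idx for v in eff.edge):
            i, j = idx[eff.edge[0]], idx[eff.edge[1]]
            sup[min(i, j), max(i, j)] = True
    sup = sup | sup.T
    return sup


def _connected(sup: np.ndarray) -> bool:
    from scipy.sparse.csgraph import connected_components
    from scipy.sparse import csr_matrix
    ncomp, _ = connected_components(csr_matrix(sup), directed=False)
    return ncomp == 1


def generate_template(config: SimulationConfig) -> dict[str, ConnectomeMatrix]:
    """Population-level matrix per weighting over a single connected support.

    Hub nodes are guaranteed to connect to at least 80% of the other nodes;
    the template is redrawn (up to 1000 times) until connected.
    """
    atlas = _study_atlas()
    ids = atlas.retained_ids
    n = len(ids)
    rng = np.random.default_rng(config.seed)
    idx = {v: i for i, v in enumerate(ids)}
    hubs = [idx[h] for h in config.hub_nodes if h in idx]

    sup = None
    for _ in range(1000):
        cand = _draw_support(rng, config, ids)
        if all(cand[h].sum() >= 0.8 * (n - 1) for h in hubs) and _connected(cand):
            sup = cand
            break
    if sup is None:
        raise ValidationError(
            "could not draw a connected template in 1000 redraws; "
            "edge_density is too low")

    fn = np.zeros((n, n))
    fa = np.zeros((n, n))
    fl = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    on = sup[iu]
    k = int(on.sum())
    fn_vals = rng.lognormal(config.fn_log_mean, config.fn_log_sd, size=k)
    fa_vals = _truncnorm(rng, config.fa_mean, config.fa_sd, 0.2, 0.8, k)
    fl_vals = _truncnorm(rng, config.fl_mean, config.fl_sd, 1e-6, np.inf, k)
    for mat, vals in ((fn, fn_vals), (fa, fa_vals), (fl, fl_vals)):
        flat = np.zeros(len(on))
        flat[on] = vals
        mat[iu] = flat
        mat += mat.T

    def _mk(vals, w):
        return ConnectomeMatrix("template", w, vals, ids)

    return {
        "binary": _mk(sup.astype(float), "binary"),
        "FA": _mk(fa, "FA"),
        "FN": _mk(fn, "FN"),
        "FL": _mk(fl, "FL"),
    }


def _edge_index(ids: Sequence[str], edge: tuple[str, str]) -> tuple[int, int]:
    idx = {v: i for i, v in enumerate(ids)}
    for v in edge:
        if v not in idx:
            raise ValidationError(f"effect edge endpoint {v!r} not in atlas")
    return idx[edge[0]], idx[edge[1]]


def generate_cohort(config: SimulationConfig) -> StudyCohort:
    """3 x ``n_per_group`` subjects: template x subject noise, planted edge
    multipliers, then hub dropout; binary = FN > 0."""
    if config.n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    template = generate_template(config)
    atlas = _study_atlas()
    ids = atlas.retained_ids
    n = len(ids)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    idx = {v: i for i, v in enumerate(ids)}
    hubs = [idx[h] for h in config.hub_nodes if h in idx]
    sup = template["binary"].values > 0
    iu = np.triu_indices(n, k=1)

    for eff in config.effects:
        i, j = _edge_index(ids, eff.edge)
        if not sup[i, j]:
            raise ValidationError(
                f"effect edge {eff.edge} is not in the template support")

    subjects: list[Subject] = []
    counter = 0
    for group in GROUPS:
        for _ in range(config.n_per_group):
            counter += 1
            sid = f"{group}{counter:02d}"
            mats: dict[str, np.ndarray] = {}
            for w in ("FA", "FN", "FL"):
                base = template[w].values.copy()
                noise = np.ones((n, n))
                noise_u = rng.lognormal(0.0, config.subject_noise_sd,
                                        size=len(iu[0]))
                noise[iu] = noise_u
                noise = np.triu(noise, 1) + np.triu(noise, 1).T
                vals = base * noise
                if w == "FA":
                    # keep FA inside the generator's (0.2, 0.8) band after
                    # noise; planted reductions below may still lower entries
                    np.clip(vals, 0.2, 0.8, out=vals)
                    vals[~sup] = 0.0
                mats[w] = vals
            for eff in config.effects:
                if group in eff.groups_affected:
                    i, j = _edge_index(ids, eff.edge)
                    mats[eff.weighting][i, j] *= eff.multiplier
                    mats[eff.weighting][j, i] *= eff.multiplier
            p_drop = float(dict(config.hub_dropout).get(group, 0.0))
            if p_drop > 0:
                # disconnect hub-incident edges; homotopic pairs are spared
                # (the interhemispheric connection weakens, it does not vanish)
                drop = np.zeros((n, n), dtype=bool)
                seen: set[tuple[int, int]] = set()
                for h in hubs:
                    for j2 in range(n):
                        e = (min(h, j2), max(h, j2))
                        if j2 == h or not sup[h, j2] or e in seen:
                            continue
                        seen.add(e)
                        a_stem = ids[e[0]].rsplit("_", 1)[0]
                        b_stem = ids[e[1]].rsplit("_", 1)[0]
                        if a_stem == b_stem:
                            continue
                        if rng.random() < p_drop:
                            drop[e[0], e[1]] = drop[e[1], e[0]] = True
                for w in ("FA", "FN", "FL"):
                    mats[w][drop] = 0.0
            binary = (mats["FN"] > 0).astype(float)
            sub_mats = {"binary": ConnectomeMatrix(sid, "binary", binary, ids)}
            for w in ("FA", "FN", "FL"):
                sub_mats[w] = ConnectomeMatrix(sid, w, mats[w], ids)
            subjects.append(Subject(sid, group, sub_mats))

    meta = {
        "generator": "connkit.simulate",
        "config": _config_dict(config),
    }
    return StudyCohort(subjects, atlas, meta=meta)


def null_cohort(config: SimulationConfig) -> StudyCohort:
    """Same generator with every effect stripped: groups differ only by label."""
    null_cfg = replace(config, effects=(),
                       hub_dropout={g: 0.0 for g in GROUPS})
    return generate_cohort(null_cfg)


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["effects"] = [
        {"edge": list(e.edge), "weighting": e.weighting,
         "groups_affected": list(e.groups_affected), "multiplier": e.multiplier}
        for e in config.effects
    ]
    d["hub_dropout"] = dict(config.hub_dropout)
    d["hub_nodes"] = list(config.hub_nodes)
    return d


def simulate_to_dir(config: SimulationConfig, outdir: str | Path) -> Path:
    """Write a full cohort directory (matrices + manifest + config echo)."""
    cohort = generate_cohort(config)
    mpath = save_cohort(cohort, outdir)
    with open(Path(outdir) / "config.json", "w") as fh:
        json.dump(_config_dict(config), fh, indent=1)
    return mpath
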