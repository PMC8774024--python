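"""Data model and I/O for atlases, connectome matrices, and study cohorts.

The analysis operates on per-subject symmetric weighted adjacency matrices
over a fixed node parcellation (atlas).  Four edge weightings are carried per
subject:

* ``binary`` — 1 if any streamline connects the two regions, else 0;
* ``FA``    — mean fractional anisotropy along the connecting streamlines,
  dimensionless in [0, 1];
* ``FN``    — streamline (fiber) count, >= 0;
* ``FL``    — mean streamline length in mm, >= 0.

Regions invaded by tumor are flagged *excluded* on the atlas and never appear
in any matrix or metric; matrices are stored over the retained nodes only.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WEIGHTINGS",
    "GROUPS",
    "NodeInfo",
    "AtlasDefinition",
    "ConnectomeMatrix",
    "Subject",
    "StudyCohort",
    "ValidationError",
    "default_atlas",
    "DEFAULT_EXCLUDED_NODES",
    "load_atlas",
    "save_atlas",
    "exclude_nodes",
    "read_matrix",
    "write_matrix",
    "load_cohort",
    "save_cohort",
]

WEIGHTINGS = ("binary", "FA", "FN", "FL")
GROUPS = ("Ep", "nEp", "con")

#: Relative asymmetry above which an input matrix is rejected rather than
#: symmetrized.  Tractography connectomes are symmetric by construction, so
#: larger asymmetry indicates file corruption.
SYMMETRY_RTOL = 1e-6


class ValidationError(ValueError):
    """Raised when an atlas, matrix, or cohort violates a structural invariant."""


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeInfo:
    """One parcellation region.

    ``node_id`` ends in ``_L`` or ``_R`` matching ``hemisphere``; ``excluded``
    marks tumor-invaded regions that are dropped from every analysis.
    """

    node_id: str
    hemisphere: str
    gyrus: str = ""
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.hemisphere not in ("L", "R"):
            raise ValidationError(
                f"hemisphere must be 'L' or 'R', got {self.hemisphere!r}")
        if not self.node_id.endswith(f"_{self.hemisphere}"):
            raise ValidationError(
                f"node_id {self.node_id!r} does not end in '_{self.hemisphere}'")


@dataclass(frozen=True)
class AtlasDefinition:
    """Ordered, named node set shared by every matrix in a cohort."""

    nodes: tuple[NodeInfo, ...]
    name: str = "atlas"

    def __post_init__(self) -> None:
        if not self.nodes:
            raise ValidationError("atlas has no nodes")
        ids = [n.node_id for n in self.nodes]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate node_id(s): {sorted(dupes)}")

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(n.node_id for n in self.nodes)

    @property
    def retained(self) -> tuple[NodeInfo, ...]:
        return tuple(n for n in self.nodes if not n.excluded)

    @property
    def retained_ids(self) -> tuple[str, ...]:
        return tuple(n.node_id for n in self.retained)

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def __len__(self) -> int:
        return len(self.nodes)


# The packaged motor-sensory parcellation: 14 bilateral subregions of the
# precentral gyrus (PrG), postcentral gyrus (PoG), paracentral lobule (PCL)
# and medial/dorsolateral area 6 of the superior frontal gyrus (SFG), using
# Brainnetome-style labels (A4 = primary motor, A1/2/3 = primary sensory,
# A6 = premotor/SMA; suffixes: hf head-face, ul upper limb, ll lower limb,
# t/tru trunk, tl tongue-larynx, m medial, dl dorsolateral, cdl/cvl caudal
# dorso-/ventrolateral, tonIa tongue region, ulhf upper-limb-head-face).
_DEFAULT_ATLAS_SPEC: tuple[tuple[str, str], ...] = (
    ("A4hf", "PrG"),
    ("A6cdl", "PrG"),
    ("A4ul", "PrG"),
    ("A4t", "PrG"),
    ("A4tl", "PrG"),
    ("A6cvl", "PrG"),
    ("A123ulhf", "PoG"),
    ("A123tonIa", "PoG"),
    ("A2", "PoG"),
    ("A123tru", "PoG"),
    ("A123ll", "PCL"),
    ("A4ll", "PCL"),
    ("A6m", "SFG"),
    ("A6dl", "SFG"),
)

#: Default tumor-exclusion list: six left-hemisphere regions under the
#: frontal tumor-overlap map.  A stand-in — the study does not print which
#: six regions were excluded; these are chosen so that every node named in
#: the reported results remains retained.
DEFAULT_EXCLUDED_NODES: tuple[str, ...] = (
    "A6cdl_L", "A6cvl_L", "A4tl_L", "A4t_L", "A2_L", "A6dl_L",
)


def default_atlas() -> AtlasDefinition:
    """The packaged 28-node bilateral motor-sensory atlas (no exclusions)."""
    nodes = []
    for stem, gyrus in _DEFAULT_ATLAS_SPEC:
        for hemi in ("L", "R"):
            nodes.append(NodeInfo(f"{stem}_{hemi}", hemi, gyrus))
    return AtlasDefinition(tuple(nodes), name="motor-sensory-28")


def load_atlas(path: str | Path | None = None) -> AtlasDefinition:
    """Load an atlas from JSON, or return the packaged default if no path.

    JSON layout::

        {"name": str, "nodes": [{"id", "hemisphere", "gyrus", "excluded"}]}
    """
    if path is None:
        return default_atlas()
    with open(path) as fh:
        data = json.load(fh)
    nodes = tuple(
        NodeInfo(
            node_id=n["id"],
            hemisphere=n["hemisphere"],
            gyrus=n.get("gyrus", ""),
            excluded=bool(n.get("excluded", False)),
        )
        for n in data["nodes"]
    )
    return AtlasDefinition(nodes, name=data.get("name", "atlas"))


def save_atlas(atlas: AtlasDefinition, path: str | Path) -> None:
    data = {
        "name": atlas.name,
        "nodes": [
            {"id": n.node_id, "hemisphere": n.hemisphere,
             "gyrus": n.gyrus, "excluded": n.excluded}
            for n in atlas.nodes
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def exclude_nodes(atlas: AtlasDefinition, exclude: Iterable[str]) -> AtlasDefinition:
    """Flag the given node ids as excluded (tumor-invaded).

    Node order is preserved; already-excluded nodes stay excluded, so the
    operation is idempotent.  Unknown ids raise :class:`ValidationError`.
    """
    exclude = set(exclude)
    known = set(atlas.node_ids)
    unknown = exclude - known
    if unknown:
        raise ValidationError(f"unknown node_id(s): {sorted(unknown)}")
    nodes = tuple(
        replace(n, excluded=True) if n.node_id in exclude else n
        for n in atlas.nodes
    )
    return AtlasDefinition(nodes, name=atlas.name)


# ---------------------------------------------------------------------------
# Connectome matrices
# ---------------------------------------------------------------------------

@dataclass
class ConnectomeMatrix:
    """One subject's symmetric nonnegative adjacency in one weighting.

    ``values`` is indexed by the atlas's *retained* node order.
    """

    subject_id: str
    weighting: str
    values: np.ndarray
    node_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        v = self.values
        if self.weighting not in WEIGHTINGS:
            raise ValidationError(f"unknown weighting {self.weighting!r}")
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"matrix is not square: shape {v.shape}")
        if v.shape[0] != len(self.node_order):
            raise ValidationError(
                f"matrix size {v.shape[0]} != node count {len(self.node_order)}")
        if not np.allclose(v, v.T, rtol=0, atol=SYMMETRY_RTOL * max(v.max(initial=0.0), 1.0)):
            raise ValidationError("matrix is not symmetric within tolerance")
        if np.any(np.diag(v) != 0):
            raise ValidationError("diagonal must be zero")
        if np.any(v < 0):
            raise ValidationError("negative entries are not allowed")
        if self.weighting == "FA" and np.any(v > 1 + 1e-9):
            raise ValidationError("FA entries must be <= 1")
        if self.weighting == "binary" and not np.all(np.isin(v, (0.0, 1.0))):
            raise ValidationError("binary entries must be 0 or 1")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def copy_with(self, values: np.ndarray, weighting: str | None = None) -> "ConnectomeMatrix":
        return ConnectomeMatrix(
            subject_id=self.subject_id,
            weighting=weighting or self.weighting,
            values=np.array(values, dtype=float),
            node_order=self.node_order,
        )


def read_matrix(path: str | Path, atlas: AtlasDefinition, weighting: str) -> ConnectomeMatrix:
    """Read a square CSV/TSV adjacency with a node-id header row and column.

    The delimiter is sniffed (comma or tab).  Rows/columns may appear in any
    order; they are reindexed to the atlas's retained order.  Asymmetry up to
    ``SYMMETRY_RTOL`` (relative to the max entry) is averaged away; more is an
    error.  The diagonal is forced to zero.
    """
    path = Path(path)
    with open(path) as fh:
        sample = fh.read(4096)
    delim = csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    df = pd.read_csv(path, sep=delim, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1]:
        raise ValidationError(f"{path}: table is not square: {df.shape}")
    ids = list(atlas.retained_ids)
    missing = set(ids) - set(df.index)
    if missing or set(ids) != set(df.index) or set(ids) != set(df.columns):
        raise ValidationError(
            f"{path}: header node ids do not match the retained atlas nodes")
    m = df.loc[ids, ids].to_numpy(dtype=float)
    tol = SYMMETRY_RTOL * max(np.abs(m).max(), 1.0)
    asym = np.abs(m - m.T).max()
    if asym > tol:
        raise ValidationError(f"{path}: asymmetry {asym:g} exceeds tolerance {tol:g}")
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    sid = path.stem
    return ConnectomeMatrix(subject_id=sid, weighting=weighting,
                            values=m, node_order=tuple(ids))


def write_matrix(m: ConnectomeMatrix, path: str | Path) -> None:
    """Write a matrix as CSV with node-id header; round-trips through
    :func:`read_matrix` to within float text precision (12 significant digits)."""
    df = pd.DataFrame(m.values, index=list(m.node_order), columns=list(m.node_order))
    df.index.name = "node_id"
    df.to_csv(path, float_format="%.12g")


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class Subject:
    subject_id: str
    group: str
    matrices: dict[str, ConnectomeMatrix]


@dataclass
class StudyCohort:
    """All subjects of a study: groups x weightings over one atlas."""

    subjects: list[Subject]
    atlas: AtlasDefinition
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.subjects:
            return
        ref = set(self.subjects[0].matrices)
        n = self.atlas.n_retained
        for s in self.subjects:
            if set(s.matrices) != ref:
                raise ValidationError(
                    f"subject {s.subject_id} carries weightings {sorted(s.matrices)}, "
                    f"expected {sorted(ref)}")
            for w, m in s.matrices.items():
                if m.n_nodes != n:
                    raise ValidationError(
                        f"subject {s.subject_id} {w}: {m.n_nodes} nodes != atlas {n}")
        groups = {s.group for s in self.subjects}
        if len(groups) < 1:
            raise ValidationError("cohort has no groups")

    @property
    def weightings(self) -> tuple[str, ...]:
        return tuple(w for w in WEIGHTINGS if w in self.subjects[0].matrices)

    @property
    def groups(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.subjects:
            if s.group not in seen:
                seen.append(s.group)
        return tuple(seen)

    def group_labels(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    def stack(self, weighting: str) -> np.ndarray:
        """All subjects' matrices for one weighting as (n_subjects, N, N)."""
        return np.stack([s.matrices[weighting].values for s in self.subjects])


def save_cohort(cohort: StudyCohort, outdir: str | Path) -> Path:
    """Write matrices (CSV per subject per weighting), the atlas, and a
    manifest JSON; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_atlas(cohort.atlas, outdir / "atlas.json")
    entries = []
    for s in cohort.subjects:
        paths = {}
        for w, m in s.matrices.items():
            p = outdir / f"{s.subject_id}_{w}.csv"
            write_matrix(m, p)
            paths[w] = p.name
        entries.append({"id": s.subject_id, "group": s.group, "matrices": paths})
    manifest = {"atlas": "atlas.json", "subjects": entries, "meta": cohort.meta}
    mpath = outdir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return mpath


def load_cohort(manifest_path: str | Path) -> StudyCohort:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    atlas = load_atlas(base / manifest["atlas"])
    subjects = []
    for e in manifest["subjects"]:
        mats = {}
        for w, rel in e["matrices"].items():
            m = read_matrix(base / rel, atlas, w)
            m.subject_id = e["id"]
            mats[w] = m
        subjects.append(Subject(e["id"], e["group"], mats))
    return StudyCohort(subjects, atlas, meta=manifest.get("meta", {}))
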