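"""Domain types and invariant validation for glomerular-network connectome data.

The central container is :class:`Connectome`, which bundles the four data
sources every downstream analysis consumes:

* neuron skeletons (rooted trees of 3-D points, SWC convention),
* a polyadic synapse table (one row per pre->post pairing; rows sharing a
  ``connector_id`` share one presynaptic site),
* neuron annotations (principal category, subtype, transmitter class,
  home glomerulus, tracing status),
* closed triangulated glomerulus surface meshes.

All coordinates live in one shared frame, in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

ROOT_PARENT = -1

NEURON_CATEGORIES = ("OSN", "uPN", "mPN", "LN", "other", "unknown")
TRANSMITTER_CLASSES = ("excitatory", "inhibitory", "modulatory", "unknown")

#: required columns of the synapse table
CONNECTION_COLUMNS = (
    "connector_id",
    "pre_neuron",
    "post_neuron",
    "pre_x", "pre_y", "pre_z",
    "post_x", "post_y", "post_z",
)

#: required columns of the annotation table
ANNOTATION_COLUMNS = (
    "neuron_id",
    "category",
    "subtype",
    "transmitter_class",
    "home_glomerulus",
    "tracing_status",
)


class GlomnetError(Exception):
    """Base class for all package errors."""


class StructureError(GlomnetError):
    """A skeleton or mesh violates a structural invariant."""


class ValidationError(GlomnetError):
    """Cross-references between connectome components do not resolve."""


class LoadError(GlomnetError):
    """An on-disk input is missing or unreadable."""


class SpecError(GlomnetError):
    """A generator or filter specification violates its invariants."""


class InputError(GlomnetError):
    """An operation received arguments outside its precondition."""


@dataclass
class Skeleton:
    """A neuron skeleton: a rooted tree of labelled 3-D nodes.

    ``node_ids`` are positive integers; ``parent_ids[i]`` is the node id of
    the parent of node ``node_ids[i]`` or :data:`ROOT_PARENT` for the single
    root. Coordinates and radii are in nanometres.
    """

    neuron_id: str
    node_ids: np.ndarray        # (N,) int
    parent_ids: np.ndarray      # (N,) int
    xyz: np.ndarray             # (N, 3) float, nm
    radius: np.ndarray          # (N,) float, nm

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        self.parent_ids = np.asarray(self.parent_ids, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.validate()

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def root(self) -> int:
        return int(self.node_ids[self.parent_ids == ROOT_PARENT][0])

    def index_of(self, node_id: int) -> int:
        idx = self._index_map.get(int(node_id))
        if idx is None:
            raise StructureError(
                f"skeleton {self.neuron_id}: node {node_id} does not exist"
            )
        return idx

    @property
    def _index_map(self) -> dict[int, int]:
        cached = getattr(self, "_index_map_cache", None)
        if cached is None:
            cached = {int(n): i for i, n in enumerate(self.node_ids)}
            object.__setattr__(self, "_index_map_cache", cached)
        return cached

    def validate(self) -> None:
        """Enforce the tree invariants (unique ids, one root, acyclic, connected)."""
        nid = self.node_ids
        if len(nid) == 0:
            raise StructureError(f"skeleton {self.neuron_id}: empty")
        if len(np.unique(nid)) != len(nid):
            dupes = sorted(set(int(n) for n in nid[pd.Series(nid).duplicated().to_numpy()]))
            raise StructureError(
                f"skeleton {self.neuron_id}: duplicate node ids {dupes}"
            )
        if np.any(nid <= 0):
            raise StructureError(f"skeleton {self.neuron_id}: node ids must be positive")
        roots = nid[self.parent_ids == ROOT_PARENT]
        if len(roots) != 1:
            raise StructureError(
                f"skeleton {self.neuron_id}: expected exactly one root, found {len(roots)}"
            )
        known = set(int(n) for n in nid)
        for n, p in zip(nid, self.parent_ids):
            if int(p) != ROOT_PARENT and int(p) not in known:
                raise StructureError(
                    f"skeleton {self.neuron_id}: node {int(n)} references absent parent {int(p)}"
                )
        # acyclicity + connectivity: every node must reach the root by parent hops
        parent_of = {int(n): int(p) for n, p in zip(nid, self.parent_ids)}
        ok: set[int] = set()
        for start in parent_of:
            seen: list[int] = []
            cur = start
            while cur != ROOT_PARENT and cur not in ok:
                if cur in seen:
                    raise StructureError(
                        f"skeleton {self.neuron_id}: cycle involving node {cur}"
                    )
                seen.append(cur)
                cur = parent_of[cur]
            ok.update(seen)
        if not np.all(np.isfinite(self.xyz)):
            raise StructureError(f"skeleton {self.neuron_id}: non-finite coordinates")

    def children_map(self) -> dict[int, list[int]]:
        """node id -> list of child node ids."""
        out: dict[int, list[int]] = {int(n): [] for n in self.node_ids}
        for n, p in zip(self.node_ids, self.parent_ids):
            if int(p) != ROOT_PARENT:
                out[int(p)].append(int(n))
        return out

    def cable_length(self) -> float:
        """Total cable length (sum of parent-child edge lengths), nm."""
        total = 0.0
        for i, p in enumerate(self.parent_ids):
            if int(p) != ROOT_PARENT:
                j = self.index_of(int(p))
                total += float(np.linalg.norm(self.xyz[i] - self.xyz[j]))
        return total


def validate_connections(df: pd.DataFrame) -> list[str]:
    """Check synapse-table invariants; return human-readable failure messages."""
    problems: list[str] = []
    missing = [c for c in CONNECTION_COLUMNS if c not in df.columns]
    if missing:
        return [f"synapse table missing columns {missing}"]
    coords = df[["pre_x", "pre_y", "pre_z", "post_x", "post_y", "post_z"]].to_numpy(float)
    if not np.all(np.isfinite(coords)):
        bad = df.index[~np.isfinite(coords).all(axis=1)].tolist()[:10]
        problems.append(f"non-finite synapse coordinates at rows {bad}")
    # polyadic convention: one presynaptic neuron and site per connector
    grouped = df.groupby("connector_id")
    n_pre = grouped["pre_neuron"].nunique()
    bad_ids = n_pre.index[n_pre > 1].tolist()
    for cid in bad_ids[:20]:
        problems.append(f"connector {cid} has multiple presynaptic neurons")
    site_var = grouped[["pre_x", "pre_y", "pre_z"]].nunique().max(axis=1)
    bad_ids = site_var.index[site_var > 1].tolist()
    for cid in bad_ids[:20]:
        problems.append(f"connector {cid} has multiple presynaptic sites")
    return problems


def validate_annotations(df: pd.DataFrame) -> list[str]:
    problems: list[str] = []
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        return [f"annotation table missing columns {missing}"]
    if df["neuron_id"].duplicated().any():
        dupes = df.loc[df["neuron_id"].duplicated(), "neuron_id"].tolist()
        problems.append(f"duplicate annotations for neurons {dupes}")
    bad_cat = sorted(set(df["category"]) - set(NEURON_CATEGORIES))
    if bad_cat:
        problems.append(f"unknown neuron categories {bad_cat}")
    bad_tx = sorted(set(df["transmitter_class"]) - set(TRANSMITTER_CLASSES))
    if bad_tx:
        problems.append(f"unknown transmitter classes {bad_tx}")
    return problems


def mesh_is_closed(mesh: trimesh.Trimesh) -> bool:
    """True when every edge is shared by exactly two faces (watertight surface)."""
    return bool(mesh.is_watertight)


@dataclass
class Connectome:
    """All co-registered data for one reconstructed volume."""

    skeletons: dict[str, Skeleton]
    connections: pd.DataFrame
    annotations: pd.DataFrame
    meshes: dict[str, trimesh.Trimesh] = field(default_factory=dict)

    @property
    def neuron_ids(self) -> list[str]:
        return list(self.annotations["neuron_id"])

    def annotation_for(self, neuron_id: str) -> pd.Series:
        rows = self.annotations[self.annotations["neuron_id"] == neuron_id]
        if rows.empty:
            raise ValidationError(f"neuron {neuron_id} has no annotation")
        return rows.iloc[0]

    def glomerulus_names(self) -> list[str]:
        return sorted(self.meshes)


@dataclass
class CheckResult:
    name: str
    passed: bool
    offenders: list[str] = field(default_factory=list)


@dataclass
class ValidationReport:
    checks: list[CheckResult] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[CheckResult]:
        return [c for c in self.checks if not c.passed]

    def add(self, name: str, offenders: list[str]) -> None:
        self.checks.append(CheckResult(name, not offenders, offenders))

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "checks": [
                {"name": c.name, "passed": c.passed, "offenders": c.offenders}
                for c in self.checks
            ],
        }


def validate_connectome(cn: Connectome) -> ValidationReport:
    """Run every cross-reference and structural invariant; report pass/fail.

    This never raises: downstream stages inspect the report and refuse to run
    on failures (unless forced via config).
    """
    report = ValidationReport()

    report.add("connection_table", validate_connections(cn.connections))
    report.add("annotation_table", validate_annotations(cn.annotations))

    annotated = set(cn.annotations["neuron_id"]) if "neuron_id" in cn.annotations else set()
    referenced = set(cn.connections.get("pre_neuron", pd.Series(dtype=object))) | set(
        cn.connections.get("post_neuron", pd.Series(dtype=object))
    )
    dangling = sorted(referenced - annotated)
    report.add(
        "connections_reference_annotated_neurons",
        [f"neuron {n} referenced by a connection but not annotated" for n in dangling],
    )

    offenders = []
    for name, mesh in cn.meshes.items():
        if not mesh_is_closed(mesh):
            offenders.append(f"mesh {name} is not closed")
        elif mesh.volume <= 0:
            offenders.append(f"mesh {name} has non-positive volume")
    report.add("meshes_closed_with_positive_volume", offenders)

    glom_names = set(cn.meshes)
    offenders = []
    if "home_glomerulus" in cn.annotations:
        for _, row in cn.annotations.iterrows():
            hg = row["home_glomerulus"]
            if isinstance(hg, str) and hg and hg.lower() != "none" and hg not in glom_names:
                offenders.append(
                    f"neuron {row['neuron_id']} claims home glomerulus {hg} which has no mesh"
                )
    report.add("home_glomeruli_exist", offenders)

    offenders = []
    for nid, sk in cn.skeletons.items():
        try:
            sk.validate()
        except StructureError as exc:  # pragma: no cover - skeletons validate at build
            offenders.append(str(exc))
        if nid != sk.neuron_id:
            offenders.append(f"skeleton keyed {nid} but labelled {sk.neuron_id}")
    report.add("skeletons_valid", offenders)

    return report


def connection_count_identity(cn: Connectome) -> tuple[int, int, int]:
    """(sum of per-neuron outputs, sum of per-neuron inputs, row count).

    All three are equal for any connectome: each row is exactly one neuron's
    output and one neuron's input.
    """
    n_rows = len(cn.connections)
    outputs = int(cn.connections.groupby("pre_neuron").size().sum()) if n_rows else 0
    inputs = int(cn.connections.groupby("post_neuron").size().sum()) if n_rows else 0
    return outputs, inputs, n_rows
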