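"""Readers and writers for the on-disk connectome layout.

A connectome directory contains::

    skeletons/<neuron_id>.swc     one neuron per file, standard 7-column SWC
    meshes/<name>.obj             triangulated glomerulus surfaces
    synapses.tsv                  polyadic synapse table (tab-delimited)
    annotations.tsv               neuron annotation table (tab-delimited)

Coordinates are absolute nanometres in one shared frame; no per-file
transforms are applied.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .model import (
    ANNOTATION_COLUMNS,
    CONNECTION_COLUMNS,
    ROOT_PARENT,
    Connectome,
    LoadError,
    Skeleton,
    StructureError,
    ValidationError,
    validate_connectome,
)

SWC_COLUMNS = ("node_id", "type", "x", "y", "z", "radius", "parent_id")


def read_swc(path: str | Path, neuron_id: str | None = None) -> Skeleton:
    """Parse a standard 7-column SWC file into a :class:`Skeleton`.

    Lines starting with ``#`` are comments. The root has parent -1. A multi-root
    file, a cycle, or a dangling parent raises :class:`StructureError`.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"SWC file not found: {path}")
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise StructureError(f"{path}: malformed SWC line: {line!r}")
        rows.append(parts)
    if not rows:
        raise StructureError(f"{path}: SWC file has no nodes")
    arr = np.asarray(rows)
    return Skeleton(
        neuron_id=neuron_id or path.stem,
        node_ids=arr[:, 0].astype(int),
        parent_ids=arr[:, 6].astype(int),
        xyz=arr[:, 2:5].astype(float),
        radius=arr[:, 5].astype(float),
    )


def write_swc(sk: Skeleton, path: str | Path) -> None:
    path = Path(path)
    lines = ["# node_id type x y z radius parent_id"]
    for i in range(sk.n_nodes):
        lines.append(
            f"{int(sk.node_ids[i])} 0 "
            f"{sk.xyz[i, 0]:.3f} {sk.xyz[i, 1]:.3f} {sk.xyz[i, 2]:.3f} "
            f"{sk.radius[i]:.3f} {int(sk.parent_ids[i])}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    """Load a Wavefront OBJ as a triangle mesh; non-triangular faces are rejected."""
    path = Path(path)
    if not path.exists():
        raise LoadError(f"mesh file not found: {path}")
    for line in path.read_text().splitlines():
        if line.startswith("f "):
            if len(line.split()) != 4:
                raise StructureError(f"{path}: non-triangular face: {line!r}")
    mesh = trimesh.load_mesh(path, file_type="obj", process=False)
    if not isinstance(mesh, trimesh.Trimesh):
        raise StructureError(f"{path}: expected a single triangle mesh")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    Path(path).write_text(trimesh.exchange.obj.export_obj(mesh))


def read_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in ("connector_id",)})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing required columns {missing}")
    return df


def write_connectome(cn: Connectome, directory: str | Path) -> None:
    """Write the full on-disk layout that :func:`load_connectome` consumes."""
    directory = Path(directory)
    (directory / "skeletons").mkdir(parents=True, exist_ok=True)
    (directory / "meshes").mkdir(parents=True, exist_ok=True)
    for nid, sk in cn.skeletons.items():
        write_swc(sk, directory / "skeletons" / f"{nid}.swc")
    for name, mesh in cn.meshes.items():
        write_mesh(mesh, directory / "meshes" / f"{name}.obj")
    cn.connections.to_csv(directory / "synapses.tsv", sep="\t", index=False)
    cn.annotations.to_csv(directory / "annotations.tsv", sep="\t", index=False)


def load_connectome(directory: str | Path, validate: bool = True) -> Connectome:
    """Load and cross-validate a connectome directory.

    Raises :class:`LoadError` for a missing file, :class:`StructureError` for a
    malformed skeleton or mesh, and :class:`ValidationError` when
    cross-references do not resolve (listing the offending ids).
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise LoadError(f"connectome directory not found: {directory}")

    skel_dir = directory / "skeletons"
    mesh_dir = directory / "meshes"
    skeletons = {}
    if skel_dir.is_dir():
        for path in sorted(skel_dir.glob("*.swc")):
            sk = read_swc(path)
            skeletons[sk.neuron_id] = sk
    meshes = {}
    if mesh_dir.is_dir():
        for path in sorted(mesh_dir.glob("*.obj")):
            meshes[path.stem] = read_mesh(path)

    connections = read_table(directory / "synapses.tsv", CONNECTION_COLUMNS)
    annotations = read_table(directory / "annotations.tsv", ANNOTATION_COLUMNS)
    annotations = annotations.fillna({"home_glomerulus": "", "subtype": ""})

    cn = Connectome(
        skeletons=skeletons,
        connections=connections,
        annotations=annotations,
        meshes=meshes,
    )
    if validate:
        report = validate_connectome(cn)
        if not report.passed:
            msgs = [m for c in report.failures() for m in c.offenders]
            raise ValidationError(
                "connectome failed validation:\n" + "\n".join(msgs)
            )
    return cn
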