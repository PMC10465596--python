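"""Mesh assignment of synapses and per-glomerulus connectivity tables.

A neuron's connections are assigned to glomeruli by testing the synapse site
on the *query* neuron (its post_site for inputs, its pre_site for outputs)
for containment in each glomerulus surface mesh. Per (neuron, glomerulus) we
then tabulate input count I_g, output count O_g and the polarity ratio

    R_g = (I_g - O_g) / (I_g + O_g)

which runs from -1 (pure output within the glomerulus) to +1 (pure input).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .model import Connectome, InputError, StructureError, mesh_is_closed

logger = logging.getLogger(__name__)

UNASSIGNED = ""


def _ray_parity(points: np.ndarray, triangles: np.ndarray,
                direction: np.ndarray, eps: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Crossing parity of rays from ``points`` along ``direction``.

    Vectorized Moller-Trumbore over all (point, triangle) pairs. Returns
    (odd-parity flags, on-surface flags, degenerate flags); a degenerate ray
    grazes a triangle edge/vertex or runs parallel in-plane, and must be
    recast in a perturbed direction.
    """
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0
    d = direction / np.linalg.norm(direction)
    h = np.cross(d, e2)                      # (F, 3)
    a = np.einsum("fj,fj->f", e1, h)         # (F,)
    parallel = np.abs(a) < 1e-12
    inv_a = np.where(parallel, np.nan, 1.0 / np.where(parallel, 1.0, a))

    n_pts = len(points)
    inside = np.zeros(n_pts, dtype=bool)
    surface = np.zeros(n_pts, dtype=bool)
    degenerate = np.zeros(n_pts, dtype=bool)
    scale = float(np.abs(triangles).max()) + 1.0
    t_eps = 1e-9 * scale
    for start in range(0, n_pts, 512):
        p = points[start:start + 2048]
        s = p[:, None, :] - v0[None, :, :]                    # (N, F, 3)
        u = np.einsum("nfj,fj->nf", s, h) * inv_a             # (N, F)
        q = np.cross(s, e1[None, :, :])                       # (N, F, 3)
        v = np.einsum("nfj,j->nf", q, d) * inv_a
        t = np.einsum("nfj,fj->nf", q, e2) * inv_a
        w = 1.0 - u - v
        in_tri = (u > eps) & (v > eps) & (w > eps)
        on_surf = in_tri & (np.abs(t) <= t_eps)
        hits = in_tri & (t > t_eps)
        # a ray grazing an edge or vertex (a barycentric coordinate at zero
        # within eps, ahead of the origin) has ambiguous parity
        grazing = (
            (np.minimum(np.minimum(np.abs(u), np.abs(v)), np.abs(w)) <= eps)
            & (u > -eps) & (v > -eps) & (w > -eps) & (t > -t_eps)
        )
        sl = slice(start, start + len(p))
        inside[sl] = np.nansum(hits, axis=1) % 2 == 1
        surface[sl] = np.nan_to_num(on_surf, nan=0).astype(bool).any(axis=1)
        degenerate[sl] = np.nan_to_num(grazing, nan=0).astype(bool).any(axis=1)
    return inside, surface, degenerate


def _near_surface(points: np.ndarray, triangles: np.ndarray,
                  tol: float) -> np.ndarray:
    """True where a point lies within ``tol`` of any triangle (vectorized)."""
    v0, v1, v2 = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    n = np.cross(v1 - v0, v2 - v0)
    n_hat = n / np.linalg.norm(n, axis=1, keepdims=True)
    near = np.zeros(len(points), dtype=bool)
    for start in range(0, len(points), 512):
        p = points[start:start + 512]
        s = p[:, None, :] - v0[None, :, :]
        dist_plane = np.abs(np.einsum("nfj,fj->nf", s, n_hat))
        # barycentric test of the in-plane projection
        d00 = np.einsum("fj,fj->f", v1 - v0, v1 - v0)
        d01 = np.einsum("fj,fj->f", v1 - v0, v2 - v0)
        d11 = np.einsum("fj,fj->f", v2 - v0, v2 - v0)
        d20 = np.einsum("nfj,fj->nf", s, v1 - v0)
        d21 = np.einsum("nfj,fj->nf", s, v2 - v0)
        denom = d00 * d11 - d01 * d01
        u = (d11 * d20 - d01 * d21) / denom
        v = (d00 * d21 - d01 * d20) / denom
        face_hit = (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) \
            & (dist_plane <= tol)
        ok = face_hit.any(axis=1)
        # edge distances for the remainder (covers vertices via clamping)
        rem = ~ok
        if rem.any():
            pr = p[rem]
            d_min = np.full(len(pr), np.inf)
            for a, b in ((v0, v1), (v1, v2), (v2, v0)):
                ab = b - a
                tseg = np.einsum("nfj,fj->nf", pr[:, None, :] - a[None, :, :], ab)
                tseg = np.clip(tseg / np.einsum("fj,fj->f", ab, ab), 0.0, 1.0)
                closest = a[None, :, :] + tseg[..., None] * ab[None, :, :]
                d = np.linalg.norm(pr[:, None, :] - closest, axis=2).min(axis=1)
                d_min = np.minimum(d_min, d)
            ok[np.flatnonzero(rem)[d_min <= tol]] = True
        near[start:start + len(p)] = ok
    return near


def point_in_mesh(points: np.ndarray, mesh: trimesh.Trimesh,
                  seed: int = 0) -> np.ndarray:
    """Even-odd containment of points in a closed mesh (boundary counts inside).

    Casts a ray along +x per point and counts triangle crossings; rays that
    graze an edge or vertex are recast along an epsilon-perturbed direction
    (up to 16 restarts, deterministic). Raises :class:`StructureError` for a
    non-closed mesh. Accepts one point or an (N, 3) array.
    """
    if not mesh_is_closed(mesh):
        raise StructureError("point_in_mesh requires a closed (watertight) mesh")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    triangles = mesh.triangles.view(np.ndarray)
    eps = 1e-10

    inside, surface, degen = _ray_parity(pts, triangles,
                                         np.array([1.0, 0.0, 0.0]), eps)
    rng = np.random.default_rng(seed)
    for _ in range(16):
        if not degen.any():
            break
        idx = np.flatnonzero(degen)
        direction = np.array([1.0, 0.0, 0.0]) + rng.normal(scale=1e-4, size=3)
        sub_in, sub_surf, sub_degen = _ray_parity(pts[idx], triangles,
                                                  direction, eps)
        inside[idx], surface[idx], degen[idx] = sub_in, sub_surf, sub_degen
    result = inside | surface
    # boundary points count as inside even when their rays stay ambiguous
    outside = ~result
    if outside.any():
        lo, hi = mesh.bounds
        tol = 1e-6 * (float(np.linalg.norm(hi - lo)) + 1.0)
        near_box = outside & np.all((pts >= lo - tol) & (pts <= hi + tol), axis=1)
        if near_box.any():
            idx = np.flatnonzero(near_box)
            result[idx[_near_surface(pts[idx], triangles, tol)]] = True
    if np.ndim(points) == 1:
        return bool(result[0])
    return result


def _assign_points(points: np.ndarray, meshes: dict[str, trimesh.Trimesh]) -> np.ndarray:
    """Glomerulus name per point (empty string when inside no mesh).

    Meshes are non-overlapping by invariant, so the first containing mesh
    wins; an axis-aligned bounding-box prefilter keeps the ray casting cheap.
    """
    labels = np.full(len(points), UNASSIGNED, dtype=object)
    unassigned = np.ones(len(points), dtype=bool)
    for name, mesh in meshes.items():
        if not unassigned.any():
            break
        lo, hi = mesh.bounds
        cand = unassigned & np.all((points >= lo) & (points <= hi), axis=1)
        if not cand.any():
            continue
        idx = np.flatnonzero(cand)
        inside = point_in_mesh(points[idx], mesh)
        labels[idx[inside]] = name
        unassigned[idx[inside]] = False
    return labels


def assign_synapses(cn: Connectome) -> pd.DataFrame:
    """Label every connection row with the glomerulus containing each site.

    Returns the connection table with two extra columns,
    ``glomerulus_for_pre_site`` and ``glomerulus_for_post_site`` (empty when
    the site lies inside no mesh).
    """
    df = cn.connections.copy()
    pre = df[["pre_x", "pre_y", "pre_z"]].to_numpy(float)
    post = df[["post_x", "post_y", "post_z"]].to_numpy(float)
    df["glomerulus_for_pre_site"] = _assign_points(pre, cn.meshes)
    df["glomerulus_for_post_site"] = _assign_points(post, cn.meshes)
    return df


def io_ratio(n_input: int, n_output: int) -> float | None:
    """(I - O) / (I + O); None when the neuron makes no connections there."""
    total = n_input + n_output
    if total == 0:
        return None
    return (n_input - n_output) / total


def io_ratio_table(cn: Connectome, assigned: pd.DataFrame,
                   neurons: list[str] | None = None,
                   ipsilateral_only: bool = True) -> pd.DataFrame:
    """Per (neuron, glomerulus) input/output counts and polarity ratio.

    I_g counts rows where the neuron is postsynaptic with its post_site inside
    glomerulus g; O_g counts rows where it is presynaptic with its pre_site
    inside g. When the annotation table carries a ``side`` column and
    ``ipsilateral_only`` is set, only connections on the neuron's own side
    are counted.
    """
    neurons = neurons if neurons is not None else cn.neuron_ids
    gloms = cn.glomerulus_names()
    side_of = {}
    if ipsilateral_only and "side" in cn.annotations.columns:
        side_of = dict(zip(cn.annotations["neuron_id"], cn.annotations["side"]))
    mesh_side = {}
    if side_of and "mesh_side" in cn.annotations.attrs:
        mesh_side = cn.annotations.attrs["mesh_side"]

    rows = []
    for nid in neurons:
        inputs = assigned[(assigned["post_neuron"] == nid)
                          & (assigned["glomerulus_for_post_site"] != UNASSIGNED)]
        outputs = assigned[(assigned["pre_neuron"] == nid)
                           & (assigned["glomerulus_for_pre_site"] != UNASSIGNED)]
        if nid in side_of and mesh_side:
            inputs = inputs[inputs["glomerulus_for_post_site"].map(
                lambda g: mesh_side.get(g) == side_of[nid])]
            outputs = outputs[outputs["glomerulus_for_pre_site"].map(
                lambda g: mesh_side.get(g) == side_of[nid])]
        in_counts = inputs.groupby("glomerulus_for_post_site").size()
        out_counts = outputs.groupby("glomerulus_for_pre_site").size()
        for g in gloms:
            i, o = int(in_counts.get(g, 0)), int(out_counts.get(g, 0))
            rows.append({
                "neuron_id": nid, "glomerulus": g,
                "n_input": i, "n_output": o,
                "ratio": io_ratio(i, o),
            })
    return pd.DataFrame(rows)


def ratio_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Neurons x glomeruli matrix of polarity ratios (NaN = not innervated)."""
    return table.pivot(index="neuron_id", columns="glomerulus", values="ratio")


def partner_demographics(cn: Connectome, neuron: str,
                         direction: str) -> pd.DataFrame:
    """Percent of a neuron's connections per partner category, one direction.

    ``direction`` is ``"upstream"`` (partners presynaptic to the neuron) or
    ``"downstream"``. Unannotated partners fall into the ``unknown`` bin.
    Returns an empty frame (with a logged warning) for a neuron with no
    partners in that direction.
    """
    if direction not in ("upstream", "downstream"):
        raise InputError(f"direction must be upstream or downstream, got {direction!r}")
    if direction == "upstream":
        conns = cn.connections[cn.connections["post_neuron"] == neuron]
        partners = conns["pre_neuron"]
    else:
        conns = cn.connections[cn.connections["pre_neuron"] == neuron]
        partners = conns["post_neuron"]
    if conns.empty:
        logger.warning("neuron %s has no %s partners", neuron, direction)
        return pd.DataFrame(columns=["neuron_id", "direction", "category", "percent"])
    cat_of = dict(zip(cn.annotations["neuron_id"], cn.annotations["category"]))
    cats = partners.map(lambda p: cat_of.get(p, "unknown"))
    counts = cats.value_counts()
    total = counts.sum()
    return pd.DataFrame({
        "neuron_id": neuron,
        "direction": direction,
        "category": counts.index,
        "percent": 100.0 * counts.to_numpy() / total,
    }).reset_index(drop=True)


@dataclass
class PolarityResult:
    """Per-glomerulus transmitter-class breakdown of one neuron's inputs."""

    table: pd.DataFrame
    excluded: dict[str, int] = field(default_factory=dict)  # reason -> count


def polarity_breakdown(cn: Connectome, neuron: str,
                       assigned: pd.DataFrame | None = None) -> PolarityResult:
    """Percent excitatory/inhibitory/modulatory/unknown input per glomerulus.

    Inputs from uniglomerular partners (OSNs and uPNs) are attributed to the
    partner's home glomerulus; inputs from multiglomerular partners are
    attributed by post-site mesh containment. Uniglomerular partners lacking a
    home glomerulus are excluded and the exclusion counts reported.
    """
    if assigned is None:
        assigned = assign_synapses(cn)
    inputs = assigned[assigned["post_neuron"] == neuron]
    ann = cn.annotations.set_index("neuron_id")
    excluded: dict[str, int] = {}
    counts: dict[tuple[str, str], int] = {}
    for _, row in inputs.iterrows():
        partner = row["pre_neuron"]
        if partner in ann.index:
            category = ann.at[partner, "category"]
            tx = ann.at[partner, "transmitter_class"]
            home = ann.at[partner, "home_glomerulus"]
        else:
            category, tx, home = "unknown", "unknown", ""
        if category in ("OSN", "uPN"):
            if not isinstance(home, str) or not home:
                excluded["uniglomerular partner without home glomerulus"] = (
                    excluded.get("uniglomerular partner without home glomerulus", 0) + 1)
                continue
            glom = home
        else:
            glom = row["glomerulus_for_post_site"]
            if glom == UNASSIGNED:
                excluded["post site outside all meshes"] = (
                    excluded.get("post site outside all meshes", 0) + 1)
                continue
        counts[(glom, tx)] = counts.get((glom, tx), 0) + 1
    if excluded:
        logger.info("polarity_breakdown(%s) exclusions: %s", neuron, excluded)
    gloms = sorted({g for g, _ in counts})
    rows = []
    for g in gloms:
        total = sum(v for (gg, _), v in counts.items() if gg == g)
        row = {"neuron_id": neuron, "glomerulus": g, "n_input": total}
        for tx in ("excitatory", "inhibitory", "modulatory", "unknown"):
            row[f"pct_{tx}"] = 100.0 * counts.get((g, tx), 0) / total
        rows.append(row)
    cols = ["neuron_id", "glomerulus", "n_input",
            "pct_excitatory", "pct_inhibitory", "pct_modulatory", "pct_unknown"]
    return PolarityResult(pd.DataFrame(rows, columns=cols), excluded)
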