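"""Synthetic connectomes, clone matrices, and fluorescence traces.

Every generator is a pure function of (spec, seed) and emulates the
statistical structure the downstream analyses assume:

* a glomerulus-partitioned neuropil of closed, non-overlapping ellipsoid
  meshes;
* a mixed LN population (~200 cells) with a planted "patchy" peptidergic
  subset whose glomerular innervation is Bernoulli per glomerulus and whose
  per-glomerulus input:output balance follows a planted ratio;
* binary clone-by-glomerulus innervation matrices sampled through a latent
  Gaussian copula whose correlation is calibrated so that the *binary-scale*
  (phi) correlations hit their targets;
* odor-evoked fluorescence traces with baseline, exponential bleach, an
  exponentially decaying response kernel, and Gaussian noise.

Ground truth (planted memberships, counts, mixtures, calibrated targets) is
returned alongside each artifact for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy.optimize import brentq
from scipy.stats import multivariate_normal, norm

from .imaging import FluorescenceTrace
from .model import Connectome, GlomnetError, Skeleton, SpecError

#: standard antennal-lobe glomerulus names, ordered so that desk-scale runs
#: (which take the first n) include the pairs discussed in the text
AL_GLOMERULI = [
    "DM1", "DM2", "DM3", "DM4", "DM5", "D", "VA6", "VL2p", "VM2", "DP1m",
    "DM6", "DP1l", "VA2", "VM3", "DL5", "DA1", "DA2", "DA3", "DA4l", "DA4m",
    "DC1", "DC2", "DC3", "DC4", "DL1", "DL2d", "DL2v", "DL3", "DL4", "V",
    "VA1d", "VA1v", "VA3", "VA4", "VA5", "VA7l", "VA7m", "VC1", "VC2", "VC3",
    "VC4", "VC5", "VL1", "VL2a", "VM1", "VM4", "VM5d", "VM5v", "VM6", "VM7d",
    "VM7v",
]


class PlacementError(GlomnetError):
    """Could not place non-overlapping glomeruli within the bounding box."""


def glomerulus_names(n: int) -> list[str]:
    if n <= len(AL_GLOMERULI):
        return AL_GLOMERULI[:n]
    return AL_GLOMERULI + [f"G{i:02d}" for i in range(n - len(AL_GLOMERULI))]


# --------------------------------------------------------------------------
# glomerulus meshes

@dataclass
class EllipsoidSpec:
    """Bookkeeping for one generated glomerulus (analytic ground truth)."""

    name: str
    center: np.ndarray
    semi_axes: np.ndarray  # (3,) nm, axis-aligned

    def contains_analytic(self, points: np.ndarray) -> np.ndarray:
        q = (np.atleast_2d(points) - self.center) / self.semi_axes
        return (q ** 2).sum(axis=1) <= 1.0

    def volume_analytic(self) -> float:
        return float(4.0 / 3.0 * np.pi * np.prod(self.semi_axes))


def _ellipsoid_mesh(center: np.ndarray, semi_axes: np.ndarray,
                    subdivisions: int = 3) -> trimesh.Trimesh:
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions)
    mesh.apply_scale(semi_axes)
    mesh.apply_translation(center)
    return mesh


def make_glomeruli(n: int, bounding_box: float = 120_000.0,
                   seed: int = 0, radius_range: tuple[float, float] = (4000.0, 7000.0),
                   subdivisions: int = 3, max_retries: int = 2000,
                   ) -> tuple[dict[str, trimesh.Trimesh], list[EllipsoidSpec]]:
    """n closed, mutually non-overlapping tessellated ellipsoids.

    Centers are sampled uniformly in a cube of side ``bounding_box`` (nm);
    a candidate is accepted when its center is farther from every accepted
    center than the sum of the two maximal semi-axes (conservative
    non-overlap). Deterministic for a fixed seed.
    """
    if n < 1:
        raise SpecError("make_glomeruli requires n >= 1")
    rng = np.random.default_rng([seed, 101])
    names = glomerulus_names(n)
    specs: list[EllipsoidSpec] = []
    meshes: dict[str, trimesh.Trimesh] = {}
    for name in names:
        semi = rng.uniform(*radius_range, size=3)
        placed = False
        for _ in range(max_retries):
            margin = semi.max()
            center = rng.uniform(margin, bounding_box - margin, size=3)
            if all(np.linalg.norm(center - s.center) > semi.max() + s.semi_axes.max()
                   for s in specs):
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place glomerulus {name} without overlap after "
                f"{max_retries} retries; enlarge the bounding box"
            )
        specs.append(EllipsoidSpec(name, center, semi))
        meshes[name] = _ellipsoid_mesh(center, semi, subdivisions)
    return meshes, specs


def sample_inside(spec: EllipsoidSpec, n: int, rng: np.random.Generator,
                  shrink: float = 0.95) -> np.ndarray:
    """Uniform points inside the ellipsoid, shrunk to stay inside the mesh."""
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return spec.center + (u * r) * (spec.semi_axes * shrink)


# --------------------------------------------------------------------------
# connectome generator

@dataclass
class PopulationSpec:
    """Study conditions for the synthetic AL population.

    Defaults follow the system under study: ~200 LNs in total with a
    peptidergic patchy ensemble of 9, each patchy LN innervating any given
    glomerulus with probability 0.5. The glomerulus count (15) and per-
    glomerulus partner counts are desk-scale choices documented in the
    methods note.
    """

    n_glomeruli: int = 15
    n_patchy_lns: int = 9
    n_other_lns: int = 191
    n_osns_per_glomerulus: int = 5
    n_upns_per_glomerulus: int = 3
    innervation_p: float | np.ndarray = 0.5          # p_g
    planted_ratio: float | np.ndarray = 0.4          # r_g in [-1, 1]
    synapses_per_glomerulus: int = 20                # per patchy LN per glomerulus
    input_category_mix: dict[str, float] = field(
        default_factory=lambda: {"OSN": 0.35, "uPN": 0.30, "LN": 0.30, "other": 0.05})
    n_nblast_distractors: int = 2    # patchy subtype + marker input, alien shape
    n_untraced_clones: int = 1       # pass everything but tracing status
    bounding_box: float = 120_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.broadcast_to(np.asarray(self.innervation_p, float),
                            (self.n_glomeruli,)).copy()
        r = np.broadcast_to(np.asarray(self.planted_ratio, float),
                            (self.n_glomeruli,)).copy()
        if np.any((p < 0) | (p > 1)):
            raise SpecError("innervation probabilities must lie in [0, 1]")
        if np.any((r < -1) | (r > 1)):
            raise SpecError("planted ratios must lie in [-1, 1]")
        if self.seed is None:
            raise SpecError("seed is mandatory")
        mix_total = sum(self.input_category_mix.values())
        if not np.isclose(mix_total, 1.0):
            raise SpecError("input_category_mix must sum to 1")
        self.innervation_p = p
        self.planted_ratio = r


@dataclass
class GroundTruth:
    """Planted structure of a generated connectome."""

    patchy_ids: list[str]
    reference_ids: list[str]
    planted_io: pd.DataFrame          # neuron, glomerulus, n_input, n_output, target_ratio
    input_class_counts: pd.DataFrame  # neuron, glomerulus, transmitter_class, count
    upstream_counts: pd.DataFrame     # neuron, category, count
    glomerulus_specs: list[EllipsoidSpec]
    distractor_ids: dict[str, list[str]] = field(default_factory=dict)


def _backbone_skeleton(neuron_id: str, waypoints: np.ndarray,
                       tuft_specs: list[tuple[EllipsoidSpec, int]],
                       rng: np.random.Generator) -> Skeleton:
    """Backbone through waypoints with small intraglomerular tufts."""
    nodes = [waypoints[0]]
    parents = [-1]
    backbone_idx = [0]
    for wp in waypoints[1:]:
        prev = backbone_idx[-1]
        # two interpolated cable points keep resampling well-conditioned
        for frac in (0.34, 0.67, 1.0):
            nodes.append(nodes[prev] * (1 - frac) + wp * frac)
            parents.append(prev)
            prev = len(nodes) - 1
        backbone_idx.append(prev)
    for (spec, n_tuft), anchor in zip(tuft_specs, backbone_idx[1:]):
        pts = sample_inside(spec, n_tuft, rng, shrink=0.7)
        for p in pts:
            nodes.append(p)
            parents.append(anchor)
    xyz = np.asarray(nodes)
    n = len(xyz)
    return Skeleton(
        neuron_id=neuron_id,
        node_ids=np.arange(1, n + 1),
        parent_ids=np.where(np.asarray(parents) < 0, -1,
                            np.asarray(parents) + 1),
        xyz=xyz,
        radius=np.full(n, 100.0),
    )


def _patchy_skeleton(neuron_id: str, soma: np.ndarray,
                     innervated: list[EllipsoidSpec],
                     rng: np.random.Generator) -> Skeleton:
    order = np.argsort([s.center[0] for s in innervated])
    specs = [innervated[i] for i in order]
    waypoints = np.vstack([soma] + [s.center for s in specs])
    return _backbone_skeleton(neuron_id, waypoints, [(s, 4) for s in specs], rng)


def make_connectome(spec: PopulationSpec) -> tuple[Connectome, GroundTruth]:
    """Generate the full synthetic AL connectome plus its ground truth.

    Patchy LNs innervate glomerulus g with probability p_g; within an
    innervated glomerulus the LN's input/output pairing counts are drawn as
    Binomial(n, (1 + r_g)/2) inputs out of n total, so the expected
    input:output ratio equals the planted r_g (and r_g = +-1 forces a pure
    input/output glomerulus). OSN/uPN partners carry home glomeruli with
    synapse sites inside the home mesh. Distractor neurons are planted to
    exercise every stage of the candidate filter; jittered copies of each
    patchy LN form the reference morphology library.
    """
    master = spec.seed
    meshes, gspecs = make_glomeruli(spec.n_glomeruli, spec.bounding_box,
                                    seed=master)
    gnames = [s.name for s in gspecs]
    spec_of = {s.name: s for s in gspecs}
    rng = np.random.default_rng([master, 1])

    annotations: list[dict] = []
    skeletons: dict[str, Skeleton] = {}
    connections: list[dict] = []
    planted_io: list[dict] = []
    class_counts: dict[tuple[str, str, str], int] = {}
    upstream_counts: dict[tuple[str, str], int] = {}
    connector_counter = [0]

    def new_connector() -> str:
        connector_counter[0] += 1
        return f"c{connector_counter[0]:07d}"

    def annotate(nid: str, category: str, subtype: str = "",
                 transmitter: str = "unknown", home: str = "",
                 tracing: str = "Traced") -> None:
        annotations.append({
            "neuron_id": nid, "category": category, "subtype": subtype,
            "transmitter_class": transmitter, "home_glomerulus": home,
            "tracing_status": tracing,
        })

    # --- partner pools per glomerulus -------------------------------------
    osns: dict[str, list[str]] = {g: [] for g in gnames}
    upns: dict[str, list[str]] = {g: [] for g in gnames}
    for g in gnames:
        for i in range(spec.n_osns_per_glomerulus):
            nid = f"OSN_{g}_{i}"
            osns[g].append(nid)
            annotate(nid, "OSN", transmitter="excitatory", home=g)
        for i in range(spec.n_upns_per_glomerulus):
            nid = f"uPN_{g}_{i}"
            upns[g].append(nid)
            annotate(nid, "uPN", transmitter="excitatory", home=g)

    annotate("CSD_L", "other", subtype="CSD", transmitter="modulatory")
    annotate("mPN_0", "mPN", transmitter="excitatory")

    # --- other (non-target) LNs -------------------------------------------
    other_subtypes = ["panglomerular", "multiglomerular", "oligoglomerular",
                      "continuous", "ventral"]
    other_ids = []
    for i in range(spec.n_other_lns):
        nid = f"LN_other_{i:03d}"
        other_ids.append(nid)
        annotate(nid, "LN", subtype=other_subtypes[i % len(other_subtypes)],
                 transmitter="inhibitory")

    # --- the planted patchy ensemble --------------------------------------
    patchy_ids = [f"LN_patchy_{i:02d}" for i in range(spec.n_patchy_lns)]
    innervation: dict[str, np.ndarray] = {}
    for i, nid in enumerate(patchy_ids):
        nrng = np.random.default_rng([master, 2, i])
        z = nrng.random(spec.n_glomeruli) < spec.innervation_p
        if not z.any():
            z[nrng.integers(spec.n_glomeruli)] = True
        innervation[nid] = z
        annotate(nid, "LN", subtype="patchy", transmitter="inhibitory")
        soma = np.full(3, 0.05 * spec.bounding_box)
        skeletons[nid] = _patchy_skeleton(
            nid, soma, [gspecs[j] for j in np.flatnonzero(z)], nrng)

    # --- reference morphology library: jittered copies of the ensemble ----
    reference_ids = []
    for i, nid in enumerate(patchy_ids):
        rid = f"REF_{i:02d}"
        reference_ids.append(rid)
        src = skeletons[nid]
        jrng = np.random.default_rng([master, 3, i])
        skeletons[rid] = Skeleton(
            neuron_id=rid,
            node_ids=src.node_ids.copy(),
            parent_ids=src.parent_ids.copy(),
            xyz=src.xyz + jrng.normal(scale=200.0, size=src.xyz.shape),
            radius=src.radius.copy(),
        )

    # --- filter-stage distractors ------------------------------------------
    distractors: dict[str, list[str]] = {"no_marker": [], "alien_shape": [],
                                         "untraced": []}
    extra_patchy: list[tuple[str, np.ndarray, bool]] = []  # (id, innervation, csd)
    d_counter = 0

    def add_patchy_like(tag: str, csd: bool, tracing: str,
                        alien: bool) -> str:
        nonlocal d_counter
        nid = f"LN_patchy_x{d_counter:02d}"
        d_counter += 1
        nrng = np.random.default_rng([master, 4, d_counter])
        z = nrng.random(spec.n_glomeruli) < spec.innervation_p
        if not z.any():
            z[nrng.integers(spec.n_glomeruli)] = True
        annotate(nid, "LN", subtype="patchy", transmitter="inhibitory",
                 tracing=tracing)
        if alien:
            # a serpentine arbor far from every glomerulus: low NBLAST score
            base = np.full(3, 0.9 * spec.bounding_box)
            steps = nrng.normal(scale=4000.0, size=(30, 3))
            waypoints = base + np.cumsum(steps, axis=0)
            skeletons[nid] = _backbone_skeleton(nid, waypoints, [], nrng)
        else:
            soma = np.full(3, 0.05 * spec.bounding_box)
            skeletons[nid] = _patchy_skeleton(
                nid, soma, [gspecs[j] for j in np.flatnonzero(z)], nrng)
        extra_patchy.append((nid, z, csd))
        distractors[tag].append(nid)
        return nid

    for _ in range(spec.n_nblast_distractors):
        add_patchy_like("alien_shape", csd=True, tracing="Traced", alien=True)
    add_patchy_like("no_marker", csd=False, tracing="Traced", alien=False)
    for i in range(spec.n_untraced_clones):
        # jittered copy of a planted neuron, untraced: passes all shape stages
        nid = f"LN_patchy_u{i:02d}"
        src_id = patchy_ids[i % len(patchy_ids)]
        src = skeletons[src_id]
        jrng = np.random.default_rng([master, 5, i])
        annotate(nid, "LN", subtype="patchy", transmitter="inhibitory",
                 tracing="Assign")
        skeletons[nid] = Skeleton(
            neuron_id=nid, node_ids=src.node_ids.copy(),
            parent_ids=src.parent_ids.copy(),
            xyz=src.xyz + jrng.normal(scale=200.0, size=src.xyz.shape),
            radius=src.radius.copy(),
        )
        extra_patchy.append((nid, innervation[src_id], True))
        distractors["untraced"].append(nid)

    # --- synapses -----------------------------------------------------------
    categories = list(spec.input_category_mix)
    probs = np.array([spec.input_category_mix[c] for c in categories])

    def emit_synapses(nid: str, z: np.ndarray, nrng: np.random.Generator,
                      record: bool) -> None:
        for j in np.flatnonzero(z):
            g = gnames[j]
            gs = spec_of[g]
            n_total = spec.synapses_per_glomerulus
            p_in = 0.5 * (1.0 + spec.planted_ratio[j])
            n_in = int(nrng.binomial(n_total, p_in))
            n_out = n_total - n_in
            sites = sample_inside(gs, 2 * n_total, nrng)
            s = 0
            for _ in range(n_in):
                cat = nrng.choice(categories, p=probs)
                if cat == "OSN":
                    partner = osns[g][nrng.integers(len(osns[g]))]
                    tx = "excitatory"
                elif cat == "uPN":
                    partner = upns[g][nrng.integers(len(upns[g]))]
                    tx = "excitatory"
                elif cat == "LN":
                    partner = other_ids[nrng.integers(len(other_ids))]
                    tx = "inhibitory"
                else:
                    partner = "mPN_0"
                    tx = "excitatory"
                pre_site, post_site = sites[s], sites[s] + nrng.normal(scale=50.0, size=3)
                s += 1
                connections.append({
                    "connector_id": new_connector(),
                    "pre_neuron": partner, "post_neuron": nid,
                    "pre_x": pre_site[0], "pre_y": pre_site[1], "pre_z": pre_site[2],
                    "post_x": post_site[0], "post_y": post_site[1], "post_z": post_site[2],
                })
                if record:
                    class_counts[(nid, g, tx)] = class_counts.get((nid, g, tx), 0) + 1
                    cat_label = "other" if cat == "other" else cat
                    cat_label = "mPN" if partner == "mPN_0" else cat_label
                    upstream_counts[(nid, cat_label)] = (
                        upstream_counts.get((nid, cat_label), 0) + 1)
            out_remaining = n_out
            while out_remaining > 0:
                fanout = min(int(nrng.integers(1, 3)), out_remaining)
                cid = new_connector()
                pre_site = sites[s]
                s += 1
                for _ in range(fanout):
                    tgt_pool = upns[g] if nrng.random() < 0.7 else osns[g]
                    partner = tgt_pool[nrng.integers(len(tgt_pool))]
                    post_site = pre_site + nrng.normal(scale=50.0, size=3)
                    connections.append({
                        "connector_id": cid,
                        "pre_neuron": nid, "post_neuron": partner,
                        "pre_x": pre_site[0], "pre_y": pre_site[1], "pre_z": pre_site[2],
                        "post_x": post_site[0], "post_y": post_site[1],
                        "post_z": post_site[2],
                    })
                out_remaining -= fanout
            if record:
                planted_io.append({
                    "neuron_id": nid, "glomerulus": g,
                    "n_input": n_in, "n_output": n_out,
                    "target_ratio": float(spec.planted_ratio[j]),
                })

    for i, nid in enumerate(patchy_ids):
        nrng = np.random.default_rng([master, 6, i])
        emit_synapses(nid, innervation[nid], nrng, record=True)
        # marker (CSD) input onto every planted neuron
        j = int(np.flatnonzero(innervation[nid])[0])
        site = sample_inside(spec_of[gnames[j]], 1, nrng)[0]
        connections.append({
            "connector_id": new_connector(),
            "pre_neuron": "CSD_L", "post_neuron": nid,
            "pre_x": site[0], "pre_y": site[1], "pre_z": site[2],
            "post_x": site[0] + 50.0, "post_y": site[1], "post_z": site[2],
        })
        class_counts[(nid, gnames[j], "modulatory")] = (
            class_counts.get((nid, gnames[j], "modulatory"), 0) + 1)
        upstream_counts[(nid, "other")] = upstream_counts.get((nid, "other"), 0) + 1

    for i, (nid, z, csd) in enumerate(extra_patchy):
        nrng = np.random.default_rng([master, 7, i])
        emit_synapses(nid, z, nrng, record=False)
        if csd:
            j = int(np.flatnonzero(z)[0])
            site = sample_inside(spec_of[gnames[j]], 1, nrng)[0]
            connections.append({
                "connector_id": new_connector(),
                "pre_neuron": "CSD_L", "post_neuron": nid,
                "pre_x": site[0], "pre_y": site[1], "pre_z": site[2],
                "post_x": site[0] + 50.0, "post_y": site[1], "post_z": site[2],
            })

    cn = Connectome(
        skeletons=skeletons,
        connections=pd.DataFrame(connections),
        annotations=pd.DataFrame(annotations),
        meshes=meshes,
    )
    truth = GroundTruth(
        patchy_ids=patchy_ids,
        reference_ids=reference_ids,
        planted_io=pd.DataFrame(planted_io),
        input_class_counts=pd.DataFrame(
            [{"neuron_id": k[0], "glomerulus": k[1], "transmitter_class": k[2],
              "count": v} for k, v in class_counts.items()]),
        upstream_counts=pd.DataFrame(
            [{"neuron_id": k[0], "category": k[1], "count": v}
             for k, v in upstream_counts.items()]),
        glomerulus_specs=gspecs,
        distractor_ids=distractors,
    )
    return cn, truth


# --------------------------------------------------------------------------
# clone innervation matrices (Gaussian copula)

@dataclass
class CloneMatrixSpec:
    """Conditions for clone-sampling: 50 clones by default, Bernoulli(p)
    marginals, binary-scale target correlations R_target."""

    n_clones: int = 50
    p: np.ndarray | float = 0.5
    R_target: np.ndarray | None = None   # glomeruli x glomeruli, binary scale
    n_glomeruli: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.broadcast_to(np.asarray(self.p, float), (self.n_glomeruli,)).copy()
        if np.any((p < 0) | (p > 1)):
            raise SpecError("marginal probabilities must lie in [0, 1]")
        self.p = p
        if self.R_target is None:
            self.R_target = np.eye(self.n_glomeruli)
        R = np.asarray(self.R_target, float)
        if R.shape != (self.n_glomeruli, self.n_glomeruli):
            raise SpecError("R_target shape must be (n_glomeruli, n_glomeruli)")
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise SpecError("R_target must be symmetric with unit diagonal")
        self.R_target = R
        if self.seed is None:
            raise SpecError("seed is mandatory")


def binary_correlation(rho: float, pa: float, pb: float) -> float:
    """Phi correlation of thresholded bivariate normals with latent corr rho."""
    za, zb = norm.ppf(pa), norm.ppf(pb)
    if abs(rho) < 1e-12:
        p11 = pa * pb
    else:
        p11 = float(multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf([za, zb]))
    denom = np.sqrt(pa * (1 - pa) * pb * (1 - pb))
    if denom == 0:
        return 0.0
    return float((p11 - pa * pb) / denom)


def calibrate_latent(target: float, pa: float, pb: float) -> float:
    """Latent Gaussian correlation whose thresholded phi equals ``target``.

    Inverts the orthant-probability map by root finding; raises
    :class:`SpecError` when the target is infeasible for the given marginals.
    """
    if abs(target) < 1e-12:
        return 0.0
    lo, hi = -0.9999, 0.9999
    f_lo = binary_correlation(lo, pa, pb) - target
    f_hi = binary_correlation(hi, pa, pb) - target
    if f_lo * f_hi > 0:
        raise SpecError(
            f"binary correlation {target:.3f} infeasible for marginals "
            f"({pa:.3f}, {pb:.3f})"
        )
    return float(brentq(lambda r: binary_correlation(r, pa, pb) - target, lo, hi,
                        xtol=1e-10))


def nearest_positive_definite(A: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped repair to the nearest correlation-like PSD matrix."""
    w, v = np.linalg.eigh((A + A.T) / 2.0)
    w = np.clip(w, eps, None)
    B = (v * w) @ v.T
    d = np.sqrt(np.diag(B))
    B = B / np.outer(d, d)
    np.fill_diagonal(B, 1.0)
    return B


def make_clone_matrix(spec: CloneMatrixSpec):
    """Sample a binary clone matrix through the calibrated Gaussian copula.

    Returns ``(InnervationMatrix, achieved)`` where ``achieved`` is the
    binary-scale correlation matrix implied by the (possibly PD-repaired)
    latent correlations — the calibrated targets parameter-recovery tests
    compare against.
    """
    from .clones import InnervationMatrix  # local import to avoid a cycle

    G = spec.n_glomeruli
    names = glomerulus_names(G)
    latent = np.eye(G)
    for i in range(G):
        for j in range(i + 1, G):
            tgt = spec.R_target[i, j]
            if spec.p[i] in (0.0, 1.0) or spec.p[j] in (0.0, 1.0):
                latent[i, j] = latent[j, i] = 0.0
                continue
            latent[i, j] = latent[j, i] = calibrate_latent(
                tgt, spec.p[i], spec.p[j])
    latent = nearest_positive_definite(latent)
    achieved = np.eye(G)
    for i in range(G):
        for j in range(i + 1, G):
            if spec.p[i] in (0.0, 1.0) or spec.p[j] in (0.0, 1.0):
                achieved[i, j] = achieved[j, i] = np.nan
                continue
            achieved[i, j] = achieved[j, i] = binary_correlation(
                latent[i, j], spec.p[i], spec.p[j])

    rng = np.random.default_rng([spec.seed, 8])
    L = np.linalg.cholesky(latent + 1e-12 * np.eye(G))
    z = rng.standard_normal((spec.n_clones, G)) @ L.T
    thresholds = norm.ppf(spec.p)
    values = (z < thresholds).astype(int)
    df = pd.DataFrame(values, columns=names,
                      index=[f"clone_{i:04d}" for i in range(spec.n_clones)])
    return InnervationMatrix(df), pd.DataFrame(achieved, index=names, columns=names)


# --------------------------------------------------------------------------
# fluorescence traces

@dataclass
class TraceSpec:
    """Trace generation conditions: 40 frames at ~9 Hz, onset at frame 20."""

    frame_rate: float = 9.0
    n_frames: int = 40
    onset_frame: int = 20
    amplitude: float = 0.3          # response peak, dF/F units
    decay_tau: float = 1.0          # response kernel decay, s
    bleach_tau: float = np.inf      # s; inf disables bleaching
    noise_sd: float = 0.0           # in raw fluorescence units
    baseline: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise SpecError("frame_rate must be positive")
        if not (0 <= self.onset_frame < self.n_frames):
            raise SpecError("onset_frame must lie within the trace")
        if self.seed is None:
            raise SpecError("seed is mandatory")


def make_trace(spec: TraceSpec, metadata: dict | None = None) -> FluorescenceTrace:
    """baseline * exp(-t/tau_bleach) * (1 + response kernel) + Gaussian noise.

    The kernel is 0 before onset and amplitude * exp(-(t - t_onset)/decay_tau)
    from the onset frame, so a noise- and bleach-free trace has
    max(trace/baseline - 1) exactly equal to the amplitude.
    """
    rng = np.random.default_rng([spec.seed, 9])
    t = np.arange(spec.n_frames) / spec.frame_rate
    t_on = spec.onset_frame / spec.frame_rate
    kernel = np.where(
        t >= t_on, spec.amplitude * np.exp(-(t - t_on) / spec.decay_tau), 0.0)
    bleach = np.exp(-t / spec.bleach_tau) if np.isfinite(spec.bleach_tau) else 1.0
    values = spec.baseline * bleach * (1.0 + kernel)
    if spec.noise_sd > 0:
        values = values + rng.normal(scale=spec.noise_sd, size=spec.n_frames)
    values = np.clip(values, 0.0, None)
    return FluorescenceTrace(values=values, frame_rate=spec.frame_rate,
                             onset_frame=spec.onset_frame,
                             metadata=metadata or {})
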