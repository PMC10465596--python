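"""Mesh containment, synapse assignment, and per-glomerulus tables."""

import numpy as np
import pandas as pd
import pytest
import trimesh

from glomnet import (
    assign_synapses,
    io_ratio,
    io_ratio_table,
    partner_demographics,
    point_in_mesh,
    polarity_breakdown,
    ratio_matrix,
)
from glomnet.model import Connectome, InputError, StructureError
from glomnet.synthetic import make_glomeruli


class TestPointInMesh:
    def test_cube_centroid_inside(self):
        cube = trimesh.creation.box(extents=(2.0, 2.0, 2.0))
        assert point_in_mesh(np.zeros(3), cube)

    def test_far_point_outside(self):
        cube = trimesh.creation.box(extents=(2.0, 2.0, 2.0))
        assert not point_in_mesh(np.array([4.0, 0.0, 0.0]), cube)

    def test_matches_analytic_ellipsoid(self, rng):
        meshes, specs = make_glomeruli(1, seed=9)
        s = specs[0]
        mesh = meshes[s.name]
        pts = s.center + rng.uniform(-1.3, 1.3, size=(1000, 3)) * s.semi_axes
        inside = point_in_mesh(pts, mesh)
        analytic = s.contains_analytic(pts)
        # agreement everywhere except a thin band at tessellation resolution
        q = (pts - s.center) / s.semi_axes
        band = np.abs(np.sqrt((q ** 2).sum(1)) - 1.0) < 0.02
        assert (inside == analytic)[~band].all()

    def test_open_mesh_rejected(self):
        cube = trimesh.creation.box()
        open_mesh = trimesh.Trimesh(cube.vertices, cube.faces[:-1], process=False)
        with pytest.raises(StructureError, match="closed"):
            point_in_mesh(np.zeros(3), open_mesh)

    def test_axis_aligned_grazing_rays_resolve(self):
        # points exactly level with cube edges force the perturbation restart
        cube = trimesh.creation.box(extents=(2.0, 2.0, 2.0))
        pts = np.array([[0.0, 1.0, 0.0], [0.0, 1.0 + 1e-9, 0.5],
                        [-3.0, 1.0, 1.0], [0.5, 0.0, 1.0]])
        got = point_in_mesh(pts, cube)
        assert got[0] and not got[2]


class TestAssignSynapses:
    def test_matches_brute_force_containment(self, small_population, small_assigned):
        cn, truth, _ = small_population
        assigned = small_assigned
        sub = assigned.sample(n=60, random_state=0)
        for _, row in sub.iterrows():
            pre = np.array([row.pre_x, row.pre_y, row.pre_z])
            expected = ""
            for s in truth.glomerulus_specs:
                if point_in_mesh(pre, cn.meshes[s.name]):
                    expected = s.name
                    break
            assert row.glomerulus_for_pre_site == expected

    def test_sites_outside_all_meshes_unlabelled(self, small_population):
        cn, _, _ = small_population
        conns = cn.connections.copy().head(3)
        for c in ("pre_x", "pre_y", "pre_z", "post_x", "post_y", "post_z"):
            conns[c] = 9e9
        far = Connectome(cn.skeletons, conns, cn.annotations, cn.meshes)
        assigned = assign_synapses(far)
        assert (assigned["glomerulus_for_pre_site"] == "").all()
        assert (assigned["glomerulus_for_post_site"] == "").all()

    def test_planted_counts_recovered(self, small_population, small_assigned):
        cn, truth, _ = small_population
        table = io_ratio_table(cn, small_assigned, truth.patchy_ids)
        merged = table.merge(truth.planted_io, on=["neuron_id", "glomerulus"],
                             suffixes=("", "_planted"))
        assert len(merged) == len(truth.planted_io)
        assert (merged["n_output"] == merged["n_output_planted"]).all()
        # inputs may exceed planted counts only by the marker-neuron synapse
        extra = merged["n_input"] - merged["n_input_planted"]
        assert extra.isin([0, 1]).all()
        assert extra.groupby(merged["neuron_id"]).sum().eq(1).all()


class TestIoRatio:
    @pytest.mark.parametrize("i,o,expected", [
        (5, 0, 1.0), (0, 7, -1.0), (3, 1, 0.5), (2, 2, 0.0),
    ])
    def test_formula(self, i, o, expected):
        assert io_ratio(i, o) == pytest.approx(expected)

    def test_null_when_not_innervated(self):
        assert io_ratio(0, 0) is None

    def test_antisymmetric_under_io_exchange(self, rng):
        for _ in range(30):
            i, o = int(rng.integers(0, 20)), int(rng.integers(0, 20))
            if i + o == 0:
                continue
            assert io_ratio(i, o) == pytest.approx(-io_ratio(o, i))

    def test_assigned_inputs_bounded_by_totals(self, small_population, small_assigned):
        cn, truth, _ = small_population
        table = io_ratio_table(cn, small_assigned, truth.patchy_ids)
        for nid in truth.patchy_ids:
            total_in = (cn.connections["post_neuron"] == nid).sum()
            assert table[table.neuron_id == nid]["n_input"].sum() <= total_in

    def test_ratio_matrix_shape(self, small_population, small_assigned):
        cn, truth, _ = small_population
        table = io_ratio_table(cn, small_assigned, truth.patchy_ids)
        mat = ratio_matrix(table)
        assert mat.shape == (len(truth.patchy_ids), len(cn.meshes))


class TestDemographics:
    def test_known_mixture_percentages(self):
        ann = pd.DataFrame({
            "neuron_id": ["q"] + [f"p{i}" for i in range(3)],
            "category": ["LN", "LN", "uPN", "OSN"],
            "subtype": "", "transmitter_class": "unknown",
            "home_glomerulus": "", "tracing_status": "Traced",
        })
        rows = []
        for partner, count in [("p0", 40), ("p1", 33), ("p2", 27)]:
            for k in range(count):
                rows.append({"connector_id": f"{partner}_{k}",
                             "pre_neuron": partner, "post_neuron": "q",
                             "pre_x": 0, "pre_y": 0, "pre_z": 0,
                             "post_x": 0, "post_y": 0, "post_z": 0})
        cn = Connectome({}, pd.DataFrame(rows), ann, {})
        demo = partner_demographics(cn, "q", "upstream")
        got = dict(zip(demo.category, demo.percent))
        assert got == {"LN": 40.0, "uPN": 33.0, "OSN": 27.0}
        assert demo.percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_partner_is_hundred_percent(self, small_population):
        cn, _, _ = small_population
        demo = partner_demographics(cn, "OSN_DM1_0", "upstream")
        if not demo.empty:
            assert demo.percent.iloc[0] == pytest.approx(100.0)

    def test_planted_category_mixture_recovered(self, small_population):
        cn, truth, _ = small_population
        for nid in truth.patchy_ids[:2]:
            demo = partner_demographics(cn, nid, "upstream")
            gt = truth.upstream_counts[truth.upstream_counts.neuron_id == nid]
            expected = 100.0 * gt.set_index("category")["count"] / gt["count"].sum()
            got = demo.set_index("category")["percent"]
            for cat, pct in expected.items():
                assert got[cat] == pytest.approx(pct, abs=1e-9)

    def test_no_partner_direction_is_empty(self, small_population):
        cn, _, _ = small_population
        demo = partner_demographics(cn, "CSD_L", "upstream")
        assert demo.empty

    def test_invalid_direction_rejected(self, small_population):
        cn, _, _ = small_population
        with pytest.raises(InputError):
            partner_demographics(cn, "CSD_L", "sideways")


class TestPolarity:
    def test_known_mixture(self, small_population):
        cn, _, _ = small_population
        name = next(iter(cn.meshes))
        ann = pd.DataFrame({
            "neuron_id": ["q", "osn", "ln"],
            "category": ["LN", "OSN", "LN"],
            "subtype": "",
            "transmitter_class": ["inhibitory", "excitatory", "inhibitory"],
            "home_glomerulus": ["", name, ""],
            "tracing_status": "Traced",
        })
        center = cn.meshes[name].centroid
        rows = []
        for k, partner in enumerate(["osn"] * 8 + ["ln"] * 2):
            rows.append({"connector_id": f"c{k}", "pre_neuron": partner,
                         "post_neuron": "q",
                         "pre_x": center[0], "pre_y": center[1], "pre_z": center[2],
                         "post_x": center[0], "post_y": center[1], "post_z": center[2]})
        toy = Connectome({}, pd.DataFrame(rows), ann, cn.meshes)
        result = polarity_breakdown(toy, "q")
        row = result.table.set_index("glomerulus").loc[name]
        assert row.pct_excitatory == pytest.approx(80.0)
        assert row.pct_inhibitory == pytest.approx(20.0)

    def test_unknown_partners_are_unknown_bin(self, small_population):
        cn, _, _ = small_population
        name = next(iter(cn.meshes))
        center = cn.meshes[name].centroid
        ann = pd.DataFrame({
            "neuron_id": ["q", "m"], "category": ["LN", "other"],
            "subtype": "", "transmitter_class": ["inhibitory", "unknown"],
            "home_glomerulus": "", "tracing_status": "Traced",
        })
        rows = [{"connector_id": "c0", "pre_neuron": "m", "post_neuron": "q",
                 "pre_x": center[0], "pre_y": center[1], "pre_z": center[2],
                 "post_x": center[0], "post_y": center[1], "post_z": center[2]}]
        toy = Connectome({}, pd.DataFrame(rows), ann, cn.meshes)
        result = polarity_breakdown(toy, "q")
        assert result.table.iloc[0].pct_unknown == pytest.approx(100.0)

    def test_planted_mixture_recovered(self, small_population, small_assigned):
        cn, truth, _ = small_population
        nid = truth.patchy_ids[0]
        result = polarity_breakdown(cn, nid, small_assigned)
        gt = truth.input_class_counts[truth.input_class_counts.neuron_id == nid]
        piv = gt.pivot(index="glomerulus", columns="transmitter_class",
                       values="count").fillna(0)
        for glom, row in result.table.set_index("glomerulus").iterrows():
            total = piv.loc[glom].sum()
            for tx in ("excitatory", "inhibitory", "modulatory"):
                expected = 100.0 * piv.loc[glom].get(tx, 0.0) / total
                assert row[f"pct_{tx}"] == pytest.approx(expected, abs=1e-9)

    def test_percentages_sum_to_hundred(self, small_population, small_assigned):
        cn, truth, _ = small_population
        result = polarity_breakdown(cn, truth.patchy_ids[1], small_assigned)
        sums = result.table[[c for c in result.table if c.startswith("pct_")]].sum(axis=1)
        np.testing.assert_allclose(sums, 100.0, atol=1e-9)

    def test_homeless_uniglomerular_partner_excluded(self, small_population):
        cn, truth, _ = small_population
        ann = cn.annotations.copy()
        osn_ids = set(ann.loc[ann.category == "OSN", "neuron_id"])
        used = cn.connections[cn.connections.pre_neuron.isin(osn_ids)]
        partner = used.pre_neuron.iloc[0]
        neuron = used.post_neuron.iloc[0]
        ann.loc[ann.neuron_id == partner, "home_glomerulus"] = ""
        modified = Connectome(cn.skeletons, cn.connections, ann, cn.meshes)
        result = polarity_breakdown(modified, neuron)
        assert sum(result.excluded.values()) >= 1
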