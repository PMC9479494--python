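"""Parametric middle-ear mesh: construction, invariants, validation."""

import dataclasses
import io

import numpy as np
import pytest

from otomech.geometry import (
    CHAIN_REGIONS,
    REGIONS,
    GeometryParameterError,
    GeometrySpec,
    Mesh,
    build_middle_ear_mesh,
    validate_mesh,
    write_vtk,
)


class TestGeometrySpec:
    def test_yaml_round_trip_is_lossless(self, geometry_spec, tmp_path):
        path = tmp_path / "geom.yaml"
        geometry_spec.to_yaml(path)
        assert GeometrySpec.from_yaml(path) == geometry_spec

    @pytest.mark.parametrize(
        "field,value",
        [
            ("tm_thickness", 0.0),
            ("tm_radius", -1e-3),
            ("mesh_resolution", 1e-3),  # coarser than the membrane
            ("ossicle_width", 7e-3),  # wider than the eardrum
        ],
    )
    def test_infeasible_parameters_name_the_field(self, field, value):
        with pytest.raises(GeometryParameterError) as err:
            GeometrySpec(**{field: value})
        assert field.split("_")[0] in str(err.value)


class TestBuildMesh:
    def test_default_mesh_is_valid_with_all_regions(self, mesh):
        assert validate_mesh(mesh) == []
        assert set(mesh.region.tolist()) == set(REGIONS)
        for label in REGIONS:
            assert mesh.region_volume(label) > 0

    def test_deterministic(self, geometry_spec, mesh):
        again = build_middle_ear_mesh(geometry_spec)
        np.testing.assert_array_equal(mesh.node_coordinates, again.node_coordinates)
        np.testing.assert_array_equal(mesh.tetrahedra, again.tetrahedra)
        assert mesh.content_hash() == again.content_hash()

    def test_refinement_scales_element_count_cubically(self, geometry_spec, mesh):
        fine = build_middle_ear_mesh(
            dataclasses.replace(geometry_spec, mesh_resolution=geometry_spec.mesh_resolution / 2)
        )
        ratio = fine.n_elements / mesh.n_elements
        assert 6 <= ratio <= 10

    def test_volume_converges_under_refinement(self, geometry_spec, mesh):
        fine = build_middle_ear_mesh(
            dataclasses.replace(geometry_spec, mesh_resolution=geometry_spec.mesh_resolution / 2)
        )
        v0, v1 = mesh.volumes().sum(), fine.volumes().sum()
        assert abs(v1 / v0 - 1) < 0.01

    def test_positive_volumes(self, mesh):
        assert (mesh.volumes() > 0).all()

    def test_named_sets_present_and_in_range(self, mesh):
        expected = {
            "tm_rim",
            "footplate_nodes",
            "attic_patch_malleus",
            "attic_patch_incus",
            "anchor_aml",
            "anchor_pil",
            "anchor_tensor_tympani",
            "anchor_stapedius",
            "anchor_annular",
        }
        assert expected <= set(mesh.node_sets)
        for nodes in mesh.node_sets.values():
            assert nodes.size > 0
            assert 0 <= nodes.min() and nodes.max() < mesh.n_nodes

    def test_load_faces_lie_on_their_regions(self, mesh):
        tm_nodes = set(mesh.tetrahedra[mesh.region == "tm"].ravel().tolist())
        stapes_nodes = set(mesh.tetrahedra[mesh.region == "stapes"].ravel().tolist())
        assert all(
            int(v) in tm_nodes for tri in mesh.face_sets["tm_load_faces"] for v in tri
        )
        assert all(
            int(v) in stapes_nodes
            for tri in mesh.face_sets["footplate_faces"]
            for v in tri
        )

    def test_chain_regions_share_interface_nodes(self, mesh):
        node_sets = {
            r: set(mesh.tetrahedra[mesh.region == r].ravel().tolist())
            for r in CHAIN_REGIONS
        }
        for r1, r2 in zip(CHAIN_REGIONS[:-1], CHAIN_REGIONS[1:]):
            assert node_sets[r1] & node_sets[r2], f"{r1} and {r2} are detached"

    def test_footplate_faces_point_outward(self, mesh):
        p = mesh.node_coordinates[mesh.face_sets["footplate_faces"]]
        normals = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        assert (normals[:, 0] > 0).all()  # outward = +x (toward the cochlea)

    def test_offset_stapes_variant_builds_valid_mesh(self, geometry_spec):
        offset = dataclasses.replace(geometry_spec, stapes_offset=1.2e-3)
        m = build_middle_ear_mesh(offset)
        assert validate_mesh(m) == []
        # footplate centre is displaced downward by the offset
        fp_z = m.node_coordinates[m.node_sets["footplate_nodes"], 2].mean()
        assert fp_z == pytest.approx(-1.2e-3, abs=1e-4)


class TestValidateMesh:
    def test_inverted_element_reported(self, mesh):
        bad = Mesh(
            node_coordinates=mesh.node_coordinates.copy(),
            tetrahedra=mesh.tetrahedra.copy(),
            region=mesh.region.copy(),
            node_sets=dict(mesh.node_sets),
            face_sets=dict(mesh.face_sets),
        )
        bad.tetrahedra[0] = bad.tetrahedra[0][[0, 1, 3, 2]]  # swap two nodes
        report = validate_mesh(bad)
        assert any("negative-volume" in r for r in report)

    def test_deleted_joint_breaks_the_chain(self, mesh):
        keep = mesh.region != "is_joint"
        bad = Mesh(
            node_coordinates=mesh.node_coordinates.copy(),
            tetrahedra=mesh.tetrahedra[keep],
            region=mesh.region[keep],
            node_sets=dict(mesh.node_sets),
            face_sets=dict(mesh.face_sets),
        )
        report = validate_mesh(bad)
        assert any("chain-connectivity" in r for r in report)

    def test_out_of_range_set_reported(self, mesh):
        bad = Mesh(
            node_coordinates=mesh.node_coordinates.copy(),
            tetrahedra=mesh.tetrahedra.copy(),
            region=mesh.region.copy(),
            node_sets={**mesh.node_sets, "tm_rim": np.array([mesh.n_nodes + 5])},
            face_sets=dict(mesh.face_sets),
        )
        assert any("set-reference" in r for r in validate_mesh(bad))


def test_vtk_export_is_readable_legacy_ascii(mesh, tmp_path):
    path = tmp_path / "mesh.vtk"
    write_vtk(mesh, path)
    text = path.read_text().splitlines()
    assert text[0].startswith("# vtk DataFile")
    assert f"POINTS {mesh.n_nodes} double" in text
    assert f"CELL_TYPES {mesh.n_elements}" in text
    # every cell is a tetrahedron (VTK type 10)
    i = text.index(f"CELL_TYPES {mesh.n_elements}")
    assert set(text[i + 1 : i + 1 + mesh.n_elements]) == {"10"}
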