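"""Geometric feature oracles: ASA, depth, protrusion, Tf, relative change."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from apis.geometry import (
    ALL_STRUCT_COLUMNS,
    STRUCT_FEATURE_NAMES,
    GeometryParams,
    accessible_surface,
    atom_asa,
    atom_protrusion,
    compute_struct_features,
    normalize_bfactor,
    protrusion_index,
    relative_change,
    residue_asa_features,
    residue_depth,
)
from apis.structures import Atom, ComplexPartition, Residue, StructureModel
from apis.synthetic import make_structure


def brute_force_asa(coords, radii, probe, n_points=9600, seed=99):
    """Independent Monte-Carlo-free oracle: dense random sphere sampling."""
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_points, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    ext = radii + probe
    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + ext[i] * dirs
        free = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            free &= np.linalg.norm(pts - coords[j], axis=1) >= ext[j]
        areas[i] = 4 * math.pi * ext[i] ** 2 * free.mean()
    return areas


def brute_force_pi(coords, radius, mean_volume):
    """O(n^2) neighbor-recount oracle for the protrusion index."""
    v_sphere = 4 / 3 * math.pi * radius**3
    out = []
    for i in range(len(coords)):
        count = int((np.linalg.norm(coords - coords[i], axis=1) <= radius).sum())
        v_int = count * mean_volume
        out.append(max(v_sphere - v_int, 0.0) / v_int)
    return np.array(out)


def two_atom_model(separation):
    atoms = [
        Atom(name="CA", element="C", coord=np.zeros(3), serial=1),
        Atom(name="CA", element="C", coord=np.array([separation, 0.0, 0.0]), serial=2),
    ]
    residues = [
        Residue("A", i + 1, "", "ALA", [a]) for i, a in enumerate(atoms)
    ]
    return StructureModel("pair2", {"A": residues})


class TestAtomASA:
    def test_isolated_carbon_matches_sphere_area(self, params):
        model = make_structure("single_atom")
        area = list(atom_asa(model, params).values())[0]
        expected = 4 * math.pi * (1.7 + 1.4) ** 2
        assert area == pytest.approx(expected, rel=0.02)

    def test_caged_atom_fully_occluded(self, params):
        cage = make_structure("cage")
        assert atom_asa(cage, params)[1] == 0.0

    @pytest.mark.parametrize("sep", [2.0, 3.5, 5.0, 6.1])
    def test_two_atom_pair_matches_dense_sampling_oracle(self, sep, params):
        model = two_atom_model(sep)
        got = np.array(list(atom_asa(model, params).values()))
        coords = model.coords()
        radii = np.full(2, 1.7)
        expected = brute_force_asa(coords, radii, params.probe_radius,
                                   n_points=10 * params.sphere_points)
        np.testing.assert_allclose(got, expected, rtol=0.03)

    def test_separated_pair_recovers_full_spheres(self, params):
        model = two_atom_model(10.0)  # beyond r_i + r_j + 2*probe
        full = 4 * math.pi * 3.1**2
        for area in atom_asa(model, params).values():
            assert area == pytest.approx(full, rel=0.02)

    def test_random_cloud_matches_oracle(self, params):
        model = make_structure("random_cloud", seed=5, n=50)
        got = np.array(list(atom_asa(model, params).values()))
        coords = model.coords()
        radii = np.full(50, 1.7)
        expected = brute_force_asa(coords, radii, params.probe_radius,
                                   n_points=10 * params.sphere_points)
        # absolute floor: ten lattice dots of area (sampling quantum)
        dot_floor = 4 * math.pi * 3.1**2 * 10 / params.sphere_points
        np.testing.assert_allclose(got, expected, rtol=0.03, atol=dot_floor)


class TestRelativeChange:
    @pytest.mark.parametrize(
        "u, b, expected", [(100.0, 100.0, 0.0), (100.0, 40.0, 0.6), (0.0, 0.0, 0.0)]
    )
    def test_examples(self, u, b, expected):
        assert relative_change(u, b) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            relative_change(-1.0, 5.0)

    @given(
        x_u=st.one_of(st.just(0.0), st.floats(1e-3, 1e6)),
        x_b=st.one_of(st.just(0.0), st.floats(1e-3, 1e6)),
        a=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance_and_identity(self, x_u, x_b, a):
        assert relative_change(x_u, x_u) == 0.0
        assert relative_change(a * x_u, a * x_b) == pytest.approx(
            relative_change(x_u, x_b), rel=1e-9, abs=1e-9
        )

    def test_bound_denominator_convention_flippable(self):
        assert relative_change(100.0, 50.0, denominator="bound") == pytest.approx(1.0)


class TestResidueDepth:
    def test_single_atom_depth_is_extended_radius(self, params):
        model = make_structure("single_atom")
        di = residue_depth(model, params)
        assert di.iloc[0]["total_mean"] == pytest.approx(1.7 + 1.4, rel=0.01)

    def test_central_atom_deeper_than_peripheral(self, params):
        model = make_structure("random_cloud", seed=3, n=60)
        _, dots = accessible_surface(model, params)
        coords = model.coords()
        centroid = coords.mean(axis=0)
        dist_from_center = np.linalg.norm(coords - centroid, axis=1)
        depths = cKDTree(dots).query(coords)[0]
        assert depths[dist_from_center.argmin()] > depths[dist_from_center.argmax()]

    def test_interface_atoms_deepen_on_binding(self, pair_model, pair_partition, params):
        from apis.structures import partition

        ua, _, bound = partition(pair_model, pair_partition)
        di_bound = residue_depth(bound, params)
        di_unbound = residue_depth(ua, params)
        for key in di_unbound.index:
            assert di_bound.loc[key, "total_mean"] >= di_unbound.loc[key, "total_mean"] - 0.2

    def test_all_depths_non_negative(self, pair_model, params):
        di = residue_depth(pair_model, params)
        assert (di.to_numpy() >= 0).all()


class TestProtrusionIndex:
    def test_single_atom_closed_form(self, params):
        model = make_structure("single_atom")
        pi = protrusion_index(model, params)
        v_sphere = 4 / 3 * math.pi * 10.0**3
        expected = (v_sphere - 20.1) / 20.1
        assert pi.iloc[0]["total_mean"] == pytest.approx(expected)
        assert expected == pytest.approx(207.4, abs=0.05)

    def test_matches_brute_force_recount(self, params):
        model = make_structure("random_cloud", seed=11, n=50)
        got = np.array(list(atom_protrusion(model, params).values()))
        expected = brute_force_pi(model.coords(), 10.0, 20.1)
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_strictly_decreasing_in_occupancy(self, params):
        # adding an atom inside the sphere lowers the center atom's PI
        base = make_structure("single_atom")
        pi0 = atom_protrusion(base, params)[1]
        crowded = two_atom_model(5.0)
        pi1 = atom_protrusion(crowded, params)[1]
        assert pi1 < pi0


class TestNormalizeBfactor:
    def test_two_residue_chain(self):
        residues = [
            Residue("A", i + 1, "", "ALA",
                    [Atom(name="CA", element="C", coord=np.array([3.8 * i, 0, 0]),
                          bfactor=b, serial=i + 1)])
            for i, b in enumerate([10.0, 20.0])
        ]
        tf = normalize_bfactor(residues)
        assert tf[("A", 1, "")] == pytest.approx(-1.0)
        assert tf[("A", 2, "")] == pytest.approx(1.0)

    def test_constant_bfactors_give_zeros(self):
        residues = [
            Residue("A", i + 1, "", "ALA",
                    [Atom(name="CA", element="C", coord=np.array([3.8 * i, 0, 0]),
                          bfactor=15.0, serial=i + 1)])
            for i in range(4)
        ]
        assert all(v == 0.0 for v in normalize_bfactor(residues).values())

    def test_zscore_identity(self, pair_model):
        tf = normalize_bfactor(pair_model.chains["A"])
        values = np.array(list(tf.values()))
        assert values.mean() == pytest.approx(0.0, abs=1e-9)
        assert values.std() == pytest.approx(1.0, abs=1e-9)

    def test_missing_ca_flagged_nan(self):
        residues = [
            Residue("A", 1, "", "ALA",
                    [Atom(name="CA", element="C", coord=np.zeros(3), bfactor=5.0, serial=1)]),
            Residue("A", 2, "", "ALA",
                    [Atom(name="CB", element="C", coord=np.ones(3), bfactor=7.0, serial=2)]),
            Residue("A", 3, "", "ALA",
                    [Atom(name="CA", element="C", coord=2 * np.ones(3), bfactor=9.0, serial=3)]),
        ]
        tf = normalize_bfactor(residues)
        assert math.isnan(tf[("A", 2, "")])


class TestFeatureAssembly:
    def test_exactly_49_structural_features_plus_tf(self):
        assert len(STRUCT_FEATURE_NAMES) == 49
        assert len(ALL_STRUCT_COLUMNS) == 50
        asa = [n for n in STRUCT_FEATURE_NAMES if n.endswith("ASA") and "R" != n[-4]]
        rasa = [n for n in STRUCT_FEATURE_NAMES if n.endswith("RASA")]
        di = [n for n in STRUCT_FEATURE_NAMES if n.endswith("DI")]
        pi = [n for n in STRUCT_FEATURE_NAMES if n.endswith("PI")]
        assert len(rasa) == 10 and len(di) == 12 and len(pi) == 12
        assert len(STRUCT_FEATURE_NAMES) - len(rasa) - len(di) - len(pi) == 15
        for symbol in ("RcsASA", "RctASA", "RcpASA", "BsRASA", "RcsmPI",
                       "BtRASA", "BpRASA", "RctmPI", "BsASA", "UtASA", "RcsmDI"):
            assert symbol in STRUCT_FEATURE_NAMES

    def test_asa_additivity_and_bound_occlusion(self, pair_model, pair_partition, params):
        asa = residue_asa_features(pair_model, pair_partition, params)
        for ctx in ("U", "B"):
            total = asa[f"{ctx}tASA"]
            np.testing.assert_allclose(
                total, asa[f"{ctx}bASA"] + asa[f"{ctx}sASA"], atol=1e-9
            )
            assert (asa[f"{ctx}pASA"] + asa[f"{ctx}nASA"] <= total + 1e-9).all()
        assert (asa["BtASA"] <= asa["UtASA"] + 1e-6).all()

    def test_interface_residues_lose_surface_on_binding(
        self, pair_model, pair_partition, params
    ):
        feats = compute_struct_features(pair_model, pair_partition, params)
        assert (feats["RctASA"] > 0).all()

    def test_rigid_motion_invariance(self, pair_model, pair_partition, params):
        feats = compute_struct_features(pair_model, pair_partition, params)
        rot = Rotation.from_euler("xyz", [31.0, -58.0, 117.0], degrees=True).as_matrix()
        moved = pair_model.transformed(rot, np.array([12.3, -45.6, 7.8]))
        feats_moved = compute_struct_features(moved, pair_partition, params)
        got = feats_moved[list(ALL_STRUCT_COLUMNS)].to_numpy()
        want = feats[list(ALL_STRUCT_COLUMNS)].to_numpy()
        np.testing.assert_allclose(got, want, rtol=1e-6, atol=1e-9)

    def test_rasa_uses_reference_table(self, pair_model, pair_partition, params):
        asa = residue_asa_features(pair_model, pair_partition, params)
        ref = params.reference()["ALA"]
        np.testing.assert_allclose(
            asa["UtRASA"], asa["UtASA"] / ref["total"], rtol=1e-12
        )

    def test_glycine_side_chain_reference_is_nonzero(self, params):
        ref = params.reference()
        assert ref["GLY"]["side_chain"] > 0
        assert set(ref) == set(
            "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
            "SER THR TRP TYR VAL".split()
        )


def test_geometry_params_validation():
    with pytest.raises(ValueError):
        GeometryParams(probe_radius=0.0)
    with pytest.raises(ValueError):
        GeometryParams(sphere_points=10)
    with pytest.raises(KeyError):
        GeometryParams(strict_elements=True).radius_of("XX")
    assert GeometryParams().radius_of("xx") == 1.80
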