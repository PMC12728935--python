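import numpy as np
import pytest

from halopi import model as mdl
from halopi import pdbscan
from halopi.features import FEATURE_NAMES, fit_scaler, apply_scaler
from halopi.geomgen import ComplexGeometry, RandomSpec
from halopi.molgeom import Molecule, build_benzene
from halopi.surrogate import SurrogateParams, generate_dataset

from .conftest import reference_pose


# ---------------------------------------------------------------------------
# Fixture scenes

PHE_RING = build_benzene().coords[build_benzene().ring_carbon_indices()]


def scene_with(*ligands, n_phe=1, offset=30.0):
    """PDB scene: n_phe phenylalanines plus the given ligand molecules."""
    w = pdbscan.PDBSceneWriter()
    w.add_phe(PHE_RING)
    for k in range(1, n_phe):
        w.add_phe(PHE_RING + np.array([0.0, 0.0, k * 2.0]), chain="A")
    for mol in ligands:
        w.add_ligand(mol, chain="B")
    return w


def write_scene(tmp_path, name, scene):
    path = tmp_path / f"{name}.pdb"
    scene.write(path)
    return path


def donor_molecule(pose: ComplexGeometry) -> Molecule:
    return pose.donor


def aliphatic_chloro() -> Molecule:
    # zig-zag hexyl chloride: 7 heavy atoms, no ring
    coords = []
    for i in range(6):
        coords.append([1.3 * i, 8.0 + 0.5 * (i % 2), 0.0])
    coords.append([1.3 * 6, 8.0, 0.6])  # Cl on the chain end
    return Molecule(["C"] * 6 + ["Cl"], np.array(coords), [None] * 7)


def tiny_chloro() -> Molecule:
    # planar 4-ring-ish fragment with Cl: only 5 heavy atoms
    coords = [[0, 8, 0], [1.4, 8, 0], [1.4, 9.4, 0], [0, 9.4, 0], [-1.7, 7.4, 0]]
    return Molecule(["C", "C", "C", "C", "Cl"], np.array(coords, float), [None] * 5)


def chlorothiophene(d=3.0) -> Molecule:
    """Planar 5-ring (4 C + S) with Cl on a ring carbon, sigma-hole pose."""
    r = 1.4 / (2 * np.sin(np.radians(36)))  # circumradius, side 1.4
    center = np.array([0.0, d + 1.74 + r, 0.0])
    ring = []
    for k in range(5):
        phi = np.radians(72.0 * k)
        ring.append(center + r * np.array([np.sin(phi), -np.cos(phi), 0.0]))
    elements = ["C", "C", "S", "C", "C", "Cl"]
    coords = np.array(ring + [[0.0, d, 0.0]])
    return Molecule(elements, coords, [None] * 6)


# ---------------------------------------------------------------------------


class TestFindHalogenArylLigands:
    def test_bromobenzene_ligand_found(self, tmp_path):
        pose = reference_pose("Br", d=3.2)
        path = write_scene(tmp_path, "ok", scene_with(donor_molecule(pose)))
        s = pdbscan.load_structure(path)
        sites = pdbscan.find_halogen_aryl_ligands(s)
        assert len(sites) == 1
        assert sites[0].halogen == "Br"
        assert sites[0].ring_size == 6

    def test_small_ligand_rejected_by_size(self, tmp_path):
        path = write_scene(tmp_path, "small", scene_with(tiny_chloro()))
        s = pdbscan.load_structure(path)
        assert pdbscan.find_halogen_aryl_ligands(s) == []

    def test_aliphatic_halide_rejected(self, tmp_path):
        path = write_scene(tmp_path, "alkyl", scene_with(aliphatic_chloro()))
        s = pdbscan.load_structure(path)
        assert pdbscan.find_halogen_aryl_ligands(s) == []

    def test_five_ring_ligand_found(self, tmp_path):
        path = write_scene(tmp_path, "thio", scene_with(chlorothiophene()))
        s = pdbscan.load_structure(path)
        sites = pdbscan.find_halogen_aryl_ligands(s)
        assert len(sites) == 1
        assert sites[0].ring_size == 5
        assert sites[0].halogen == "Cl"

    def test_unreadable_file_rejected_with_context(self, tmp_path):
        bad = tmp_path / "junk.pdb"
        bad.write_bytes(b"\x00\x01\x02 not a pdb \xff")
        with pytest.raises(ValueError, match="junk.pdb"):
            pdbscan.load_structure(bad)

    def test_phe_itself_is_not_a_ligand(self, tmp_path):
        path = write_scene(tmp_path, "phe_only", scene_with())
        s = pdbscan.load_structure(path)
        assert pdbscan.find_halogen_aryl_ligands(s) == []


class TestFindPiContacts:
    def _contacts(self, tmp_path, name, *ligands, n_phe=1):
        path = write_scene(tmp_path, name, scene_with(*ligands, n_phe=n_phe))
        s = pdbscan.load_structure(path)
        sites = pdbscan.find_halogen_aryl_ligands(s)
        return pdbscan.find_pi_contacts(s, sites)

    def test_contact_within_boundary(self, tmp_path):
        # halogen straight above the centroid; nearest ring atom at 4.9 A
        d = np.sqrt(4.9**2 - 1.39**2)
        contacts = self._contacts(tmp_path, "in", donor_molecule(reference_pose("I", d=d)))
        assert len(contacts) == 1
        assert contacts[0].d_x_aa == pytest.approx(4.9, abs=5e-3)

    def test_no_contact_beyond_boundary(self, tmp_path):
        d = np.sqrt(5.1**2 - 1.39**2)
        contacts = self._contacts(tmp_path, "out", donor_molecule(reference_pose("I", d=d)))
        assert contacts == []

    def test_two_phe_rings_give_two_contacts(self, tmp_path):
        contacts = self._contacts(
            tmp_path, "two", donor_molecule(reference_pose("Br", d=3.2)), n_phe=2
        )
        assert len(contacts) == 2
        assert {c.residue_id for c in contacts} == {"PHE:A:1", "PHE:A:2"}

    def test_pose_measures_recovered(self, tmp_path):
        contacts = self._contacts(tmp_path, "meas", donor_molecule(reference_pose("Br", d=3.2)))
        c = contacts[0]
        assert c.d_plane == pytest.approx(3.2, abs=5e-3)
        assert c.alpha == pytest.approx(0.0, abs=0.2)
        assert c.directional


class TestApplySigmaFilters:
    def _mk(self, alpha, d_x_aa, directional):
        pose = reference_pose("Cl", d=3.1)
        contact = pdbscan.contact_from_complex(pose)
        contact.alpha = alpha
        contact.d_x_aa = d_x_aa
        contact.directional = directional
        return contact

    def test_boundary_pass(self):
        assert pdbscan.apply_sigma_filters(self._mk(49.9, 3.0, True))

    def test_angle_fail(self):
        assert not pdbscan.apply_sigma_filters(self._mk(50.1, 3.0, True))

    def test_distance_fail(self):
        assert not pdbscan.apply_sigma_filters(self._mk(0.0, 0.9, True))

    def test_wrong_side_fail(self):
        assert not pdbscan.apply_sigma_filters(self._mk(30.0, 3.0, False))

    def test_verdict_is_pure_function_of_measures(self):
        a = self._mk(30.0, 3.0, True)
        b = self._mk(30.0, 3.0, True)
        assert pdbscan.apply_sigma_filters(a) == pdbscan.apply_sigma_filters(b)

    def test_tilted_grid_pose_measures(self):
        # built with a 120 deg tilt: C-X points away from the plane
        pose = reference_pose("I", d=3.0, tilt_dev=120.0)
        contact = pdbscan.contact_from_complex(pose)
        assert contact.alpha == pytest.approx(120.0, abs=1e-6)
        assert not contact.directional
        assert not contact.verdict


class TestBuildMmpComplex:
    def _scan_one(self, tmp_path, name, mol):
        path = write_scene(tmp_path, name, scene_with(mol))
        s = pdbscan.load_structure(path)
        contacts = pdbscan.find_pi_contacts(s, pdbscan.find_halogen_aryl_ligands(s))
        assert len(contacts) == 1
        return contacts[0]

    def test_halogen_matched_exactly(self, tmp_path):
        contact = self._scan_one(tmp_path, "mmp", donor_molecule(reference_pose("Br", d=3.2)))
        mmp = pdbscan.build_mmp_complex(contact)
        donor = mmp.complex.donor
        xi = donor.single_atom("halogen")
        assert np.abs(donor.coords[xi] - contact.site.halogen_pos).max() < 1e-9

    def test_cx_direction_matched(self, tmp_path):
        pose = reference_pose("I", d=3.3, x=1.0, tilt_dev=20.0)
        contact = self._scan_one(tmp_path, "mmpdir", donor_molecule(pose))
        mmp = pdbscan.build_mmp_complex(contact)
        donor = mmp.complex.donor
        xi, ci = donor.single_atom("halogen"), donor.single_atom("ipso_carbon")
        v_model = donor.coords[ci] - donor.coords[xi]
        v_lig = contact.site.carbon_pos - contact.site.halogen_pos
        cos = v_model @ v_lig / (np.linalg.norm(v_model) * np.linalg.norm(v_lig))
        assert np.arccos(np.clip(cos, -1, 1)) < 1e-6

    def test_acceptor_normal_parallel_to_phe(self, tmp_path):
        contact = self._scan_one(tmp_path, "mmpn", donor_molecule(reference_pose("Cl", d=3.1)))
        mmp = pdbscan.build_mmp_complex(contact)
        from halopi.molgeom import plane_and_centroid

        n_model, _ = plane_and_centroid(mmp.complex.acceptor)
        _, n_phe, _ = pdbscan._plane_rms(contact.phe_ring_coords)
        cross = np.linalg.norm(np.cross(n_model, n_phe))
        assert cross < 1e-6

    def test_acceptor_is_c6h6(self, tmp_path):
        contact = self._scan_one(tmp_path, "mmp12", donor_molecule(reference_pose("Br", d=3.2)))
        mmp = pdbscan.build_mmp_complex(contact)
        acc = mmp.complex.acceptor
        assert len(acc) == 12
        assert acc.elements.count("C") == 6 and acc.elements.count("H") == 6

    def test_idempotent_on_canonical_complex(self):
        pose = reference_pose("Br", d=3.2, x=0.5, tilt_dev=10.0)
        contact = pdbscan.contact_from_complex(pose)
        assert contact.verdict
        mmp = pdbscan.build_mmp_complex(contact)
        rmsd_d = np.sqrt(np.mean((mmp.complex.donor.coords - pose.donor.coords) ** 2))
        rmsd_a = np.sqrt(np.mean((mmp.complex.acceptor.coords - pose.acceptor.coords) ** 2))
        assert rmsd_d < 1e-9
        assert rmsd_a < 1e-9

    def test_failing_contact_rejected(self):
        pose = reference_pose("Br", d=3.2, tilt_dev=120.0)
        contact = pdbscan.contact_from_complex(pose)
        with pytest.raises(ValueError, match="passing contact"):
            pdbscan.build_mmp_complex(contact)


class TestScanCounting:
    def test_engineered_pass_fail_counts(self, tmp_path):
        # K = 2 passing sigma-hole poses, M = 3 engineered rejections
        passing = [
            donor_molecule(reference_pose("Br", d=3.2)),
            donor_molecule(reference_pose("I", d=3.4, x=0.8, tilt_dev=30.0)),
        ]
        failing = [
            donor_molecule(reference_pose("Cl", d=3.1, tilt_dev=55.0)),  # alpha >= 50
            donor_molecule(reference_pose("Cl", d=0.9, x=1.39)),  # d_X_AA < 1
            donor_molecule(reference_pose("Br", d=3.0, tilt_dev=140.0)),  # wrong side
        ]
        w = pdbscan.PDBSceneWriter()
        w.add_phe(PHE_RING)
        for mol in passing + failing:
            w.add_ligand(mol, chain="B")
        path = tmp_path / "set.pdb"
        w.write(path)
        contacts = pdbscan.scan_structure(path)
        assert len(contacts) == 5
        assert sum(c.verdict for c in contacts) == 2

    def test_contacts_table_columns(self, tmp_path):
        w = scene_with(donor_molecule(reference_pose("Br", d=3.2)))
        path = write_scene(tmp_path, "tab", w)
        table = pdbscan.contacts_to_table(pdbscan.scan_structure(path))
        assert list(table.columns) == [
            "structure", "ligand", "halogen", "residue",
            "d_plane", "alpha", "d_x_aa", "directional", "verdict",
        ]
        assert len(table) == 1
        assert bool(table["verdict"][0])


@pytest.fixture(scope="module")
def tiny_model():
    df = generate_dataset(RandomSpec(n=300, seed=0), SurrogateParams(noise_sd=0.0), halogens=("Cl",))
    X = df[list(FEATURE_NAMES)].to_numpy()
    y = df["energy"].to_numpy()
    scaler = fit_scaler(X)
    Xs = apply_scaler(X, scaler)
    cfg = mdl.ModelConfig(seed=0, max_epochs=30, early_stop_patience=50)
    return mdl.train(Xs[:240], y[:240], Xs[240:], y[240:], cfg, scaler=scaler)


class TestFiveRingFeatureCheck:
    def test_five_ring_difference_reported(self, tmp_path, tiny_model):
        w = scene_with(chlorothiophene(d=3.1))
        path = write_scene(tmp_path, "five", w)
        contacts = pdbscan.scan_structure(path)
        assert len(contacts) == 1 and contacts[0].verdict
        df = pdbscan.five_ring_feature_check(contacts, tiny_model)
        assert len(df) == 1
        summary = df.attrs["summary"]
        assert summary["n"] == 1
        assert np.isfinite(df["difference"].iloc[0])
        assert df["difference"].iloc[0] == pytest.approx(
            df["pred_5ring"].iloc[0] - df["pred_6ring"].iloc[0]
        )

    def test_six_ring_contact_skipped(self, tmp_path, tiny_model):
        w = scene_with(donor_molecule(reference_pose("Br", d=3.2)))
        path = write_scene(tmp_path, "six", w)
        contacts = pdbscan.scan_structure(path)
        df = pdbscan.five_ring_feature_check(contacts, tiny_model)
        assert len(df) == 0

    def test_identical_features_give_zero_difference(self, tiny_model):
        # same descriptor twice -> identical prediction, difference exactly 0
        from halopi.features import features_from_atoms

        pose = reference_pose("Cl", d=3.1)
        donor = pose.donor
        ring = pose.acceptor.coords[pose.acceptor.ring_carbon_indices()]
        xi, ci = donor.single_atom("halogen"), donor.single_atom("ipso_carbon")
        o = donor.atoms_with_role("ortho_carbon")
        fv = features_from_atoms(
            donor.coords[xi], donor.coords[ci], donor.coords[o[0]], donor.coords[o[1]], ring
        )
        p1 = mdl.predict(tiny_model, apply_scaler(fv, tiny_model.scaler))
        p2 = mdl.predict(tiny_model, apply_scaler(fv, tiny_model.scaler))
        assert p1[0] == p2[0]

    def test_missing_scaler_rejected(self, tmp_path):
        import pandas as pd

        bare = mdl.TrainedModel(
            weights=[np.zeros((30, 1)), np.zeros(1)], scaler=None,
            config=mdl.ModelConfig(hidden_sizes=(1,)), history=pd.DataFrame(),
        )
        with pytest.raises(ValueError, match="scaler"):
            pdbscan.five_ring_feature_check([], bare)


class TestPercent:
    def test_rounding(self):
        assert pdbscan.percent(10174, 23536) == 43.23
        assert pdbscan.percent(1, 3, ndigits=1) == 33.3

    def test_zero_whole_rejected(self):
        with pytest.raises(ValueError):
            pdbscan.percent(1, 0)
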