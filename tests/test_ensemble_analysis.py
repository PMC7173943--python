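"""SASA, side-chain variability, and loop-conformation clustering."""

import numpy as np
import pytest

from conftest import make_model, make_residue
from xlgeom._geometry import rotation_about_axis
from xlgeom.ensemble_analysis import (
    cluster_loop_conformations,
    compute_sasa,
    ensemble_profile,
    normalize_sasa,
    side_chain_variability,
)
from xlgeom.errors import EmptyInputError, InsufficientEnsembleError, ResidueLookupError


class TestComputeSasa:
    def test_lone_atom_matches_sphere_area(self):
        # a single heavy atom is a bare probe-expanded sphere: 4*pi*(r+probe)^2
        model = make_model([make_residue("A", 1, "GLY", {"CA": (0, 0, 0)})])
        sasa = compute_sasa(model, probe_radius=1.4)
        expected = 4.0 * np.pi * (1.70 + 1.4) ** 2
        assert sasa.loc["A:1", "total"] == pytest.approx(expected, rel=1e-6)

    def test_fully_enclosed_side_chain_has_zero_sasa(self):
        # Cβ at origin inside a tight shell of occluding atoms
        shell = {}
        golden = np.pi * (3.0**0.5 - 1.0)
        for i in range(60):  # Fibonacci shell at 2.2 Å with 1.7 Å radii overlaps fully
            phi = np.arccos(1 - 2 * (i + 0.5) / 60)
            theta = golden * 2 * i
            shell[f"O{i}"] = 2.2 * np.array(
                [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
            )
        residues = [
            make_residue("A", 1, "ALA", {"CA": (8, 0, 0), "CB": (0, 0, 0)}),
            make_residue("A", 2, "GLY", {name: p for name, p in shell.items()} | {"CA": (0, 0, 6)}),
        ]
        # shell atoms are not standard names but occlude geometrically
        sasa = compute_sasa(make_model(residues))
        assert sasa.loc["A:1", "side_chain"] == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_high_density_oracle(self):
        # two partially occluding residues vs a 10x point-density oracle
        residues = [
            make_residue("A", 1, "ALA", {"N": (0, 1.4, 0), "CA": (0, 0, 0),
                                         "C": (1.2, -0.8, 0), "O": (1.2, -2.0, 0),
                                         "CB": (0, 0, 1.5)}),
            make_residue("A", 2, "SER", {"N": (3.3, -0.5, 0), "CA": (4.0, 0.5, 0),
                                         "C": (5.5, 0.5, 0), "O": (6.2, 1.5, 0),
                                         "CB": (4.0, 1.5, 1.2)}),
        ]
        model = make_model(residues)
        coarse = compute_sasa(model, n_points=960)
        fine = compute_sasa(model, n_points=9600)
        rel = np.abs(coarse["total"] - fine["total"]) / fine["total"]
        assert rel.max() < 0.02

    def test_agrees_with_independent_implementation(self, toy, tmp_path):
        mdtraj = pytest.importorskip("mdtraj")
        from xlgeom.struct_io import write_pdb

        path = tmp_path / "scaffold.pdb"
        write_pdb(toy.scaffold, path)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = mdtraj.load(str(path))
            ref = mdtraj.shrake_rupley(traj, mode="residue", n_sphere_points=960)[0] * 100.0
        ours = compute_sasa(toy.scaffold)["total"].to_numpy()
        assert np.max(np.abs(ours - ref) / np.clip(ref, 1.0, None)) < 0.05

    def test_rigid_invariance(self, toy):
        rot = rotation_about_axis(np.array([0.3, 1.0, -0.5]), 0.9)
        moved = toy.scaffold.transformed(rot, np.array([10.0, -4.0, 2.0]))
        a = compute_sasa(toy.scaffold, n_points=960)["total"]
        b = compute_sasa(moved, n_points=960)["total"]
        # the sphere lattice is fixed in space, so rotation shifts sampling noise
        assert np.max(np.abs(a.to_numpy() - b.to_numpy())) < 3.0

    def test_empty_structure_rejected(self):
        with pytest.raises((EmptyInputError, ValueError)):
            compute_sasa(make_model([]))


class TestNormalizeSasa:
    @pytest.mark.parametrize(
        "sasa,res_type,reference,expected",
        [
            (0.0, "ALA", None, 0.0),
            (129.0, "ALA", None, 1.0),
            (35.0, "ALA", {"ALA": 70.0}, 0.5),
        ],
    )
    def test_fractions(self, sasa, res_type, reference, expected):
        assert normalize_sasa(sasa, res_type, reference) == pytest.approx(expected)

    def test_unknown_residue_type(self):
        with pytest.raises(ResidueLookupError):
            normalize_sasa(10.0, "XXX")


def _conformer(displacement):
    """Three-residue chain; residue 2's side chain displaced by ``displacement``."""
    base = {
        1: {"N": (0, 1, 0), "CA": (0, 0, 0), "C": (1, 0, 0), "O": (1, -1, 0)},
        2: {"N": (3, 1, 0), "CA": (3, 0, 0), "C": (4, 0, 0), "O": (4, -1, 0)},
        3: {"N": (6, 1, 0), "CA": (6, 0, 0), "C": (7, 0, 0), "O": (7, -1, 0)},
    }
    residues = []
    for seq, atoms in base.items():
        atoms = dict(atoms)
        if seq == 2:
            atoms["CB"] = np.array([3.0, 0.0, 1.5]) + displacement
            atoms["SG"] = np.array([3.0, 0.0, 3.0]) + displacement
            residues.append(make_residue("A", seq, "CYS", atoms))
        else:
            residues.append(make_residue("A", seq, "GLY", atoms))
    return make_model(residues)


class TestSideChainVariability:
    def test_identical_ensemble_is_exactly_zero(self):
        ens = [_conformer(np.zeros(3)) for _ in range(3)]
        assert side_chain_variability(ens, ("A", 2)) == 0.0

    def test_planted_displacement_recovered(self):
        ens = [_conformer(np.zeros(3)), _conformer(np.array([0.0, 2.0, 0.0]))]
        assert side_chain_variability(ens, ("A", 2)) == pytest.approx(2.0, abs=1e-9)

    def test_invariant_under_rigid_motion_of_members(self):
        ens = [_conformer(np.zeros(3)), _conformer(np.array([0.0, 2.0, 0.0]))]
        base = side_chain_variability(ens, ("A", 2))
        rot = rotation_about_axis(np.array([1.0, 1.0, 0.0]), 2.2)
        moved = [ens[0], ens[1].transformed(rot, np.array([3.0, 4.0, -1.0]))]
        assert side_chain_variability(moved, ("A", 2)) == pytest.approx(base, abs=1e-6)

    def test_single_structure_is_insufficient(self):
        with pytest.raises(InsufficientEnsembleError):
            side_chain_variability([_conformer(np.zeros(3))], ("A", 2))


def _loop_ensemble(rng):
    """Six structures: two planted loop geometries plus <=0.2 Å jitter."""
    from xlgeom.peptide_sampler import build_extended_peptide, peptide_to_structure

    members = []
    for k in range(6):
        pep = build_extended_peptide("AAAAGGAA", chain_id="A")
        if k >= 3:
            pep.phi[4:6] = -63.0  # alternative loop geometry
            pep.psi[4:6] = -42.0
        model = peptide_to_structure(pep, model_id=f"s{k}")
        for res in model.residues:
            for atom in res.atoms:
                atom.position = atom.position + rng.normal(0.0, 0.2 / np.sqrt(3), 3)
        model.resolution = 1.5 + 0.1 * k
        members.append(model)
    return members


class TestLoopClustering:
    def test_identical_ensemble_is_one_cluster(self, toy):
        ens = [toy.scaffold.copy() for _ in range(3)]
        for i, m in enumerate(ens):
            m.model_id = f"copy{i}"
        clustering = cluster_loop_conformations(ens, ("B", 25, 29), cutoff=1.0)
        assert clustering.n_clusters == 1

    def test_two_planted_geometries_recovered(self):
        rng = np.random.default_rng(11)
        ens = _loop_ensemble(rng)
        clustering = cluster_loop_conformations(ens, ("A", 5, 6), cutoff=1.0)
        labels = dict(zip(clustering.structure_ids, clustering.labels))
        assert clustering.n_clusters == 2
        assert len({labels["s0"], labels["s1"], labels["s2"]}) == 1
        assert len({labels["s3"], labels["s4"], labels["s5"]}) == 1
        assert labels["s0"] != labels["s3"]

    def test_labels_invariant_to_input_order(self):
        rng = np.random.default_rng(11)
        ens = _loop_ensemble(rng)
        c1 = cluster_loop_conformations(ens, ("A", 5, 6), cutoff=1.0)
        c2 = cluster_loop_conformations(ens[::-1], ("A", 5, 6), cutoff=1.0)
        g1 = {tuple(sorted(np.array(c1.structure_ids)[c1.labels == lab])) for lab in set(c1.labels)}
        g2 = {tuple(sorted(np.array(c2.structure_ids)[c2.labels == lab])) for lab in set(c2.labels)}
        assert g1 == g2

    def test_representative_is_best_resolution(self):
        rng = np.random.default_rng(11)
        ens = _loop_ensemble(rng)
        clustering = cluster_loop_conformations(ens, ("A", 5, 6), cutoff=1.0)
        labels = dict(zip(clustering.structure_ids, clustering.labels))
        assert clustering.representatives[labels["s0"]] == "s0"  # 1.5 Å beats 1.6/1.7
        assert clustering.representatives[labels["s3"]] == "s3"

    def test_structure_missing_range_excluded_with_warning(self, toy):
        short = make_model(
            [make_residue("B", 25, "GLY", {"N": (0, 1, 0), "CA": (0, 0, 0),
                                           "C": (1, 0, 0), "O": (1, -1, 0)})],
            model_id="partial",
        )
        ens = [toy.scaffold.copy(), toy.scaffold.copy(), short]
        ens[0].model_id, ens[1].model_id = "a", "b"
        with pytest.warns(UserWarning, match="excluded"):
            clustering = cluster_loop_conformations(ens, ("B", 25, 29), cutoff=1.0)
        assert "partial" not in clustering.structure_ids


def test_profile_covers_all_sidechain_bearing_residues(toy):
    ens = [toy.scaffold.copy(), toy.scaffold.copy()]
    ens[0].model_id, ens[1].model_id = "m0", "m1"
    prof = ensemble_profile(ens, n_points=240)
    assert len(prof.table) == len(toy.scaffold.residues)
    has_sc = [r.label for r in toy.scaffold.residues if r.res_type != "GLY"]
    sub = prof.table.loc[has_sc]
    assert np.isfinite(sub["normalized_sasa"]).all()
    assert (sub["side_chain_variability"].fillna(0.0) == 0.0).all()  # identical members
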