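"""Peptide construction, the reduced energy model, and the MC sampler."""

import math

import numpy as np
import pytest

from conftest import make_model, make_residue
from xlgeom.errors import XlgeomError
from xlgeom.peptide_sampler import (
    EnergyModel,
    SamplerConfig,
    TorsionMCKernel,
    _build_local,
    _cb_indices,
    _DockingSystem,
    _vdw,
    basin_log_density,
    bpmc_sample,
    build_extended_peptide,
    classify_beta_registry,
    combine_models,
    peptide_to_structure,
    pose_energy,
)


class TestBuildExtendedPeptide:
    def test_diglycine_has_backbone_only(self):
        model = peptide_to_structure(build_extended_peptide("GG"))
        for res in model.residues:
            assert {a.name for a in res.atoms} == {"N", "CA", "C", "O"}

    def test_ca_ca_spacing_is_trans_peptide(self):
        pep = build_extended_peptide("GISIYSAKLMNQ")
        model = peptide_to_structure(pep)
        ca = np.array(
            [model.residue(("A", i + 1, "")).atom("CA").position for i in range(pep.n_res)]
        )
        spacing = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.allclose(spacing, 3.8, atol=0.05)

    def test_sulfotyrosine_centroids_carry_negative_charge(self):
        # receptor N-terminus-like 27-mer with sulfation flags at 3 tyrosines
        seq = "MEGISIySSDNySDEWDyGSAEPCPQP"
        pep = build_extended_peptide(seq)
        system = _DockingSystem(pep, None, None, EnergyModel())
        sulfo_idx = [i for i, c in enumerate(seq) if c == "y"]
        assert len(sulfo_idx) == 3
        for i in sulfo_idx:
            sc = system.index_of[i]["SC"]
            assert system.p_q[sc] == -1.0
        assert model_has_tys(pep)

    def test_unknown_residue_code_rejected(self):
        with pytest.raises(XlgeomError):
            build_extended_peptide("GIZ")

    def test_too_short_rejected(self):
        with pytest.raises(XlgeomError):
            build_extended_peptide("G")


def model_has_tys(pep):
    return any(
        r.res_type == "TYS" for r in peptide_to_structure(pep).residues
    )


class TestKinematics:
    @pytest.mark.parametrize("kind,i,delta", [("phi", 2, 20.0), ("psi", 1, -35.0), ("chi", 3, 40.0)])
    def test_subtree_rotation_matches_full_rebuild(self, kind, i, delta):
        pep = build_extended_peptide("GISIYS")
        system = _DockingSystem(pep, None, None, EnergyModel())
        local = _build_local(pep, system.layout)
        moved = system.rotate_torsion(local, kind, i, delta)
        ref = build_extended_peptide("GISIYS")
        getattr(ref, kind)[i] += delta
        rebuilt = _build_local(ref, system.layout)
        assert np.allclose(moved, rebuilt, atol=1e-9)


class TestPoseEnergy:
    def test_decomposition_sums_to_total(self, toy):
        terms = pose_energy(toy.peptide, toy.scaffold)
        parts = sum(v for k, v in terms.items() if k != "total")
        assert abs(parts - terms["total"]) < 1e-9

    def test_opposite_unit_charges_quarter_at_one_angstrom(self):
        # Coulomb with distance-dependent dielectric (4r): q1 q2 / (4 r^2)
        pep = build_extended_peptide("GK")  # Lys centroid carries +1
        system = _DockingSystem(pep, _tys_target(), None, EnergyModel(elec_floor=0.5))
        local = _build_local(pep, system.layout)
        sc = system.index_of[1]["SC"]
        # translate so the Lys centroid sits 1 Å from the sulfate oxygen at origin
        world = local - local[sc] + np.array([1.0, 0.0, 0.0])
        elec = system.energy(world)["elec"]
        # other peptide atoms are uncharged: the pair term dominates entirely
        assert elec == pytest.approx(-1.0 / 4.0, rel=1e-12)

    def test_clashing_pair_capped_exactly(self):
        em = EnergyModel()
        assert _vdw(np.array([1e-3]), np.array([3.4]), em) == pytest.approx(em.vdw_cap)
        assert _vdw(np.array([0.5]), np.array([3.4]), em) == pytest.approx(em.vdw_cap)

    def test_isolated_anchored_peptide_has_zero_tether_and_restraint(self):
        pep = build_extended_peptide("GISIYS")
        system = _DockingSystem(pep, None, None, EnergyModel())
        local = _build_local(pep, system.layout)
        pep.anchor_target = local[system.anchor_atom].copy()
        terms = pose_energy(pep, None, None, EnergyModel())
        assert terms["tether"] == 0.0
        assert terms["restraint"] == 0.0


def _tys_target():
    """A lone sulfotyrosine-like residue whose OH (charge -1) is at the origin."""
    return make_model(
        [
            make_residue(
                "B", 1, "TYS",
                {"CA": (0, 0, 8), "CB": (0, 0, 6), "OH": (0, 0, 0)},
            )
        ],
        roles={"B": "chemokine"},
    )


class TestDetailedBalance:
    def test_two_torsion_sampler_matches_grid_boltzmann(self):
        """MH kernel with zone + local moves reproduces the Boltzmann law.

        Oracle: exhaustive enumeration of the stationary distribution on a
        36 x 36 torsion grid for a separable two-torsion energy.
        """

        rad = math.pi / 180.0

        def energy(state):
            return 0.8 * (1.0 + math.cos(3 * rad * state[0])) + 0.6 * (
                1.0 - math.cos(2 * rad * state[1])
            )

        kernel = TorsionMCKernel(
            energy, n_angles=2, zone_pairs=[(0, 1)], temperature=1.0,
            p_zone=0.7, local_sigma=30.0,
        )
        rng = np.random.default_rng(42)
        state = np.array([0.0, 0.0])
        e = energy(state)
        counts = np.zeros((36, 36))
        burn, n_steps = 5000, 200_000
        for step in range(burn + n_steps):
            state, e, _ = kernel.step(state, e, rng)
            if step >= burn:
                i = min(int((state[0] + 180.0) // 10), 35)
                j = min(int((state[1] + 180.0) // 10), 35)
                counts[i, j] += 1
        centers = np.linspace(-180.0, 180.0, 37)[:-1] + 5.0
        boltz = np.array([[math.exp(-energy((a, b))) for b in centers] for a in centers])
        boltz /= boltz.sum()
        empirical = counts / counts.sum()
        # pool the 36 x 36 grid 3 x 3 so the finite-chain noise floor sits
        # well below the tolerance; any kernel bias would survive pooling
        emp_pooled = empirical.reshape(12, 3, 12, 3).sum(axis=(1, 3))
        boltz_pooled = boltz.reshape(12, 3, 12, 3).sum(axis=(1, 3))
        tv = 0.5 * np.abs(emp_pooled - boltz_pooled).sum()
        assert tv < 0.05

    def test_zone_proposal_density_is_a_proper_mixture(self):
        # log q integrates to ~1 over the (phi, psi) torus
        grid = np.linspace(-180.0, 180.0, 73)[:-1]
        step = 5.0
        total = 0.0
        for a in grid:
            for b in grid:
                total += math.exp(basin_log_density(a, b)) * step * step
        assert total == pytest.approx(1.0, rel=0.02)


class TestSampler:
    def _quick_cfg(self, seed=0, n_steps=6000):
        return SamplerConfig(n_steps=n_steps, n_restarts=3, seed=seed, n_seed_draws=10)

    def test_same_seed_bit_identical(self, toy):
        from xlgeom.synthetic_data import restraints_at_planted_pose

        rs = restraints_at_planted_pose(toy)
        s1 = bpmc_sample(toy.peptide, toy.scaffold, rs, cfg=self._quick_cfg())
        s2 = bpmc_sample(toy.peptide, toy.scaffold, rs, cfg=self._quick_cfg())
        assert [p.energy for p in s1.poses] == [p.energy for p in s2.poses]
        assert all(
            np.array_equal(a.coords, b.coords) for a, b in zip(s1.poses, s2.poses)
        )

    def test_stack_sorted_and_deduplicated(self, toy):
        from xlgeom.synthetic_data import restraints_at_planted_pose

        rs = restraints_at_planted_pose(toy)
        stack = bpmc_sample(toy.peptide, toy.scaffold, rs, cfg=self._quick_cfg(seed=3))
        energies = [p.energy for p in stack.poses]
        assert energies == sorted(energies)
        system = _DockingSystem(toy.peptide, toy.scaffold, rs, EnergyModel())
        cb = _cb_indices(system)
        for i, a in enumerate(stack.poses):
            for b in stack.poses[i + 1:]:
                rmsd = np.sqrt(np.mean(np.sum((a.coords[cb] - b.coords[cb]) ** 2, axis=1)))
                assert rmsd >= 0.5
        assert all(0.0 <= p.restraint_satisfaction <= 1.0 for p in stack.poses)

    def test_more_steps_do_not_worsen_recovery(self, toy):
        """Median best-pose RMSD over seeds is non-worsening with more steps."""
        from xlgeom.synthetic_data import restraints_at_planted_pose

        rs = restraints_at_planted_pose(toy)
        system = _DockingSystem(toy.peptide, toy.scaffold, rs, EnergyModel())
        cb = _cb_indices(system)
        plant = np.array(
            [
                (
                    toy.planted_pose.residue(("A", i + 1, "")).atom("CB")
                    or toy.planted_pose.residue(("A", i + 1, "")).atom("CA")
                ).position
                for i in range(toy.peptide.n_res)
            ]
        )

        def median_rmsd(n_steps):
            vals = []
            for seed in range(5):
                cfg = SamplerConfig(
                    n_steps=n_steps, n_restarts=5, seed=seed, n_seed_draws=20,
                    temperature=2.5, annealing=(0.15 / 2.5) ** (1.0 / (n_steps / 5)),
                )
                stack = bpmc_sample(toy.peptide, toy.scaffold, rs, cfg=cfg)
                best = stack.best().coords[cb]
                vals.append(float(np.sqrt(np.mean(np.sum((best - plant) ** 2, axis=1)))))
            return float(np.median(vals))

        assert median_rmsd(10000) <= median_rmsd(1000) + 0.3


class TestBetaRegistry:
    def _strand_complex(self, rung_map):
        """CA-only complex: chemokine strand 25-29 on a line, peptide above it."""
        chem = [
            make_residue("B", s, "GLY", {"CA": (3.4 * (s - 25), 0.0, 0.0)})
            for s in range(25, 30)
        ]
        pep = [
            make_residue("A", i, "GLY", {"CA": (3.4 * (j - 25), 4.5, 0.0)})
            for i, j in rung_map
        ]
        return make_model(pep + chem, roles={"A": "receptor", "B": "chemokine"})

    def test_antiparallel_ladder(self):
        model = self._strand_complex([(3, 29), (5, 27), (7, 25)])
        out = classify_beta_registry(model, [("A", 3), ("A", 5), ("A", 7)],
                                     [("B", s) for s in range(25, 30)])
        assert out == "antiparallel"

    def test_parallel_ladder(self):
        model = self._strand_complex([(3, 25), (5, 27), (7, 29)])
        out = classify_beta_registry(model, [("A", 3), ("A", 5), ("A", 7)],
                                     [("B", s) for s in range(25, 30)])
        assert out == "parallel"

    def test_single_contact_is_none(self):
        chem = [
            make_residue("B", s, "GLY", {"CA": (3.4 * (s - 25), 0.0, 0.0)})
            for s in range(25, 30)
        ]
        pep = [
            make_residue("A", 3, "GLY", {"CA": (0.0, 4.5, 0.0)}),
            make_residue("A", 5, "GLY", {"CA": (0.0, 40.0, 0.0)}),
            make_residue("A", 7, "GLY", {"CA": (0.0, 60.0, 0.0)}),
        ]
        model = make_model(pep + chem)
        out = classify_beta_registry(model, [("A", 3), ("A", 5), ("A", 7)],
                                     [("B", s) for s in range(25, 30)])
        assert out == "none"

    def test_reversing_one_strand_flips_the_call(self):
        model = self._strand_complex([(3, 29), (5, 27), (7, 25)])
        pep_ids = [("A", 3), ("A", 5), ("A", 7)]
        chem_ids = [("B", s) for s in range(25, 30)]
        forward = classify_beta_registry(model, pep_ids, chem_ids)
        # reversing the chemokine residue order reverses the partner indexing
        reverse = classify_beta_registry(model, pep_ids, chem_ids[::-1])
        assert {forward, reverse} == {"antiparallel", "parallel"}

    def test_planted_pose_is_antiparallel(self, toy):
        model = toy.complex_model()
        out = classify_beta_registry(
            model,
            [("A", i, "") for i in range(1, toy.peptide.n_res + 1)],
            toy.strand1_residues,
        )
        assert out == "antiparallel"
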