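"""Torsion-space Monte Carlo docking of a flexible peptide onto a rigid core.

This is a desk-scale implementation of restraint-guided biased-probability
Monte Carlo (BPMC): the receptor's N-terminal peptide is built ab initio in
internal coordinates with ideal backbone geometry and a reduced side-chain
representation (Cβ plus one centroid pseudo-atom per residue with a
residue-specific radius and formal charge), and docked onto a rigid
chemokine-like core by Metropolis–Hastings sampling of backbone/side-chain
torsions and rigid-body placement. Large backbone moves are independence
draws from a four-basin Ramachandran prior (β, αR, αL, PPII) with the proper
Hastings correction, mixed with small Gaussian perturbations.

The energy model mirrors the class of function used for such simulations:
soft (capped) van der Waals, a hydrogen-bond proxy, Coulomb electrostatics
with a distance-dependent dielectric (εr = 4r), torsional strain, a harmonic
tether holding the peptide's C-terminal anchor near its known position, and
the crosslink-derived local distance restraint penalty. Energies are in
arbitrary reduced units; the sampler's job is pose discovery under the
restraints, not force-field fidelity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from ._geometry import place_atom, random_rotation, rotation_about_axis, wrap_angle
from ._params import (
    AA1_TO_3,
    ANGLE_CA_C_N,
    ANGLE_CA_C_O,
    ANGLE_C_N_CA,
    ANGLE_N_CA_C,
    BOND_CA_C,
    BOND_CA_CB,
    BOND_C_N,
    BOND_C_O,
    BOND_N_CA,
    DEFAULT_RADIUS,
    ELEMENT_RADII,
    OMEGA_TRANS,
    RAMACHANDRAN_BASINS,
    SIDECHAIN_CENTROID,
)
from .errors import SamplingFailureError, XlgeomError
from .restraints import RestraintSet, restraint_energy
from .struct_io import AtomRecord, ResidueRecord, StructureModel, interaction_atom

__all__ = [
    "TorsionPeptide",
    "EnergyModel",
    "SamplerConfig",
    "ConformationStack",
    "build_extended_peptide",
    "bpmc_sample",
    "classify_beta_registry",
    "pose_energy",
    "peptide_to_structure",
    "combine_models",
    "TorsionMCKernel",
]

EXTENDED_PHI = -139.0
EXTENDED_PSI = 135.0


# ---------------------------------------------------------------------------
# peptide representation


@dataclass
class TorsionPeptide:
    """Flexible peptide in internal coordinates.

    ``sequence`` uses 1-letter codes; lowercase ``y`` marks sulfotyrosine.
    Backbone torsions are per residue (φ of the first residue and ψ of the
    last are frame/carbonyl conventions rather than true DOF but are stored
    uniformly). The anchor is the C-terminal residue, optionally tethered to
    a target Cα position with a harmonic force constant.
    """

    sequence: str
    phi: np.ndarray
    psi: np.ndarray
    chi: np.ndarray
    anchor_target: np.ndarray | None = None
    tether_k: float = 5.0
    chain_id: str = "A"

    def __post_init__(self):
        for code in self.sequence:
            if code not in AA1_TO_3 and code != "y":
                raise XlgeomError(f"unknown residue code {code!r}")
        self.phi = wrap_angle(np.asarray(self.phi, dtype=float))
        self.psi = wrap_angle(np.asarray(self.psi, dtype=float))
        self.chi = wrap_angle(np.asarray(self.chi, dtype=float))

    @property
    def n_res(self) -> int:
        return len(self.sequence)

    @property
    def anchor_index(self) -> int:
        return self.n_res - 1

    def res3(self, i: int) -> str:
        return "TYS" if self.sequence[i] == "y" else AA1_TO_3[self.sequence[i]]


def _atom_layout(sequence: str):
    """Atom metadata for the reduced representation of a sequence.

    Returns per-atom arrays: residue index, name, radius, charge, and
    backbone donor/acceptor flags, plus per-residue atom index maps.
    """
    res_index, names, radii, charges, is_n, is_o = [], [], [], [], [], []
    index_of = []  # per residue: dict name -> atom index
    for i, code in enumerate(sequence):
        res3 = "TYS" if code == "y" else AA1_TO_3[code]
        idx = {}
        for name in ("N", "CA", "C", "O"):
            idx[name] = len(names)
            res_index.append(i)
            names.append(name)
            radii.append(ELEMENT_RADII["N" if name == "N" else "O" if name == "O" else "C"])
            charges.append(0.0)
            is_n.append(name == "N" and res3 != "PRO")
            is_o.append(name == "O")
        if res3 != "GLY":
            idx["CB"] = len(names)
            res_index.append(i)
            names.append("CB")
            radii.append(ELEMENT_RADII["C"])
            charges.append(0.0)
            is_n.append(False)
            is_o.append(False)
        if res3 in SIDECHAIN_CENTROID:
            _, rad, q = SIDECHAIN_CENTROID[res3]
            idx["SC"] = len(names)
            res_index.append(i)
            names.append("SC")
            radii.append(rad)
            charges.append(q)
            is_n.append(False)
            is_o.append(False)
        index_of.append(idx)
    return (
        np.array(res_index),
        names,
        np.array(radii),
        np.array(charges),
        np.array(is_n),
        np.array(is_o),
        index_of,
    )


def _build_local(peptide: TorsionPeptide, layout) -> np.ndarray:
    """Cartesian coordinates of the reduced peptide in its local frame (NeRF)."""
    _, _, _, _, _, _, index_of = layout
    n_atoms = sum(len(d) for d in index_of)
    xyz = np.zeros((n_atoms, 3))
    n_prev = ca_prev = c_prev = None
    for i in range(peptide.n_res):
        idx = index_of[i]
        if i == 0:
            n = np.zeros(3)
            ca = np.array([BOND_N_CA, 0.0, 0.0])
            theta = math.radians(ANGLE_N_CA_C)
            c = ca + BOND_CA_C * np.array([-math.cos(theta), math.sin(theta), 0.0])
        else:
            n = place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, peptide.psi[i - 1])
            ca = place_atom(ca_prev, c_prev, n, BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
            c = place_atom(c_prev, n, ca, BOND_CA_C, ANGLE_N_CA_C, peptide.phi[i])
        o = place_atom(n, ca, c, BOND_C_O, ANGLE_CA_C_O, peptide.psi[i] + 180.0)
        xyz[idx["N"]] = n
        xyz[idx["CA"]] = ca
        xyz[idx["C"]] = c
        xyz[idx["O"]] = o
        if "CB" in idx:
            cb = place_atom(c, n, ca, BOND_CA_CB, 110.5, 122.5)
            xyz[idx["CB"]] = cb
            if "SC" in idx:
                dist, _, _ = SIDECHAIN_CENTROID[peptide.res3(i)]
                xyz[idx["SC"]] = place_atom(n, ca, cb, dist, 114.0, peptide.chi[i])
        n_prev, ca_prev, c_prev = n, ca, c
    return xyz


def build_extended_peptide(
    sequence: str,
    anchor_target: np.ndarray | None = None,
    tether_k: float = 5.0,
    chain_id: str = "A",
) -> TorsionPeptide:
    """Ab initio peptide in the extended β conformation (φ=-139°, ψ=135°).

    Side chains are reduced to Cβ plus a single centroid pseudo-atom carrying
    the residue's formal charge (-1 for sulfotyrosine ``y``); glycine has no
    side-chain atoms and alanine's side chain is its Cβ.
    """
    if len(sequence) < 2:
        raise XlgeomError("peptide needs at least 2 residues")
    n = len(sequence)
    return TorsionPeptide(
        sequence=sequence,
        phi=np.full(n, EXTENDED_PHI),
        psi=np.full(n, EXTENDED_PSI),
        chi=np.full(n, 180.0),
        anchor_target=None if anchor_target is None else np.asarray(anchor_target, float),
        tether_k=tether_k,
        chain_id=chain_id,
    )


def peptide_to_structure(
    peptide: TorsionPeptide,
    coords: np.ndarray | None = None,
    role: str = "receptor",
    model_id: str = "peptide",
) -> StructureModel:
    """Materialize a peptide (posed if ``coords`` given) as a StructureModel."""
    layout = _atom_layout(peptide.sequence)
    if coords is None:
        coords = _build_local(peptide, layout)
    _, names, _, _, _, _, index_of = layout
    residues = []
    for i in range(peptide.n_res):
        atoms = [
            AtomRecord(
                name=name,
                element="N" if name == "N" else "O" if name == "O" else "C",
                position=coords[ai],
            )
            for name, ai in index_of[i].items()
        ]
        residues.append(
            ResidueRecord(
                chain_id=peptide.chain_id,
                seq_number=i + 1,
                res_type=peptide.res3(i),
                atoms=atoms,
            )
        )
    return StructureModel(
        model_id=model_id,
        residues=residues,
        chain_roles={peptide.chain_id: role},
    )


def combine_models(a: StructureModel, b: StructureModel, model_id: str = "complex") -> StructureModel:
    """Merge two structures (disjoint chains) into one complex model."""
    roles = dict(a.chain_roles)
    roles.update(b.chain_roles)
    return StructureModel(
        model_id=model_id,
        residues=[*a.copy().residues, *b.copy().residues],
        chain_roles=roles,
    )


# ---------------------------------------------------------------------------
# energy model


@dataclass
class EnergyModel:
    """Term weights for the reduced docking energy (arbitrary units).

    The van der Waals term is capped at ``vdw_cap`` per atom pair (soft vdW);
    electrostatics use a distance-dependent dielectric εr = 4r, evaluated at
    an effective distance floored at ``elec_floor`` to keep charge pairs from
    collapsing; ``cn_weight`` scales the restraint penalty.
    """

    vdw_cap: float = 7.0
    vdw_eps: float = 0.2
    w_vdw: float = 1.0
    w_hb: float = 0.5
    w_el: float = 1.0
    w_tor: float = 0.1
    cn_weight: float = 5.0
    elec_floor: float = 2.0
    hb_r0: float = 2.9
    hb_sigma: float = 0.3

    def __post_init__(self):
        for name in ("w_vdw", "w_hb", "w_el", "w_tor", "cn_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def _scaffold_arrays(model: StructureModel):
    pos, rad, q, is_n, is_o = [], [], [], [], []
    for res in model.residues:
        for a in res.atoms:
            if a.element == "H":
                continue
            pos.append(a.position)
            if a.name == "SC" and res.res_type in SIDECHAIN_CENTROID:
                _, r_sc, q_sc = SIDECHAIN_CENTROID[res.res_type]
                rad.append(r_sc)
                q.append(q_sc)
            else:
                rad.append(ELEMENT_RADII.get(a.element, DEFAULT_RADIUS))
                q.append(_atom_charge(res.res_type, a.name))
            is_n.append(a.name == "N" and res.res_type != "PRO")
            is_o.append(a.name == "O")
    return (
        np.array(pos),
        np.array(rad),
        np.array(q),
        np.array(is_n, dtype=bool),
        np.array(is_o, dtype=bool),
    )


def _atom_charge(res_type: str, atom_name: str) -> float:
    """Formal charges for full-atom structures (charged side-chain termini)."""
    table = {
        ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
        ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
        ("LYS", "NZ"): 1.0,
        ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5,
        ("TYS", "OH"): -1.0,
    }
    return table.get((res_type, atom_name), 0.0)


def _vdw(d: np.ndarray, sigma: np.ndarray, em: EnergyModel) -> float:
    d = np.maximum(d, 1e-3)
    sr6 = (sigma / d) ** 6
    return float(np.sum(np.minimum(em.vdw_cap, em.vdw_eps * (sr6**2 - 2.0 * sr6))))


class _DockingSystem:
    """Precomputed arrays for fast energy evaluation of peptide-on-scaffold."""

    def __init__(
        self,
        peptide: TorsionPeptide,
        chemokine: StructureModel | None,
        rs: RestraintSet | None,
        em: EnergyModel,
    ):
        self.peptide = peptide
        self.em = em
        self.layout = _atom_layout(peptide.sequence)
        (self.p_res, self.p_names, self.p_rad, self.p_q, self.p_isn, self.p_iso,
         self.index_of) = self.layout
        self.anchor_atom = self.index_of[peptide.anchor_index]["CA"]
        if chemokine is not None:
            self.s_pos, self.s_rad, self.s_q, self.s_isn, self.s_iso = _scaffold_arrays(chemokine)
        else:
            self.s_pos = np.zeros((0, 3))
            self.s_rad = self.s_q = np.zeros(0)
            self.s_isn = self.s_iso = np.zeros(0, dtype=bool)
        # intra-peptide nonbonded pairs: residues separated by >= 2
        sep = np.abs(self.p_res[:, None] - self.p_res[None, :])
        iu = np.triu_indices(len(self.p_res), k=1)
        keep = sep[iu] >= 2
        self.intra_i = iu[0][keep]
        self.intra_j = iu[1][keep]
        self.intra_sigma = self.p_rad[self.intra_i] + self.p_rad[self.intra_j]
        self.intra_qq = self.p_q[self.intra_i] * self.p_q[self.intra_j]
        self.inter_sigma = self.p_rad[:, None] + self.s_rad[None, :]
        self.inter_qq = self.p_q[:, None] * self.s_q[None, :]
        # restraints: peptide interaction atom index -> fixed scaffold position
        self.restraint_terms = []
        if rs is not None:
            for r in rs:
                seq = r.receptor_key[1]
                if not 1 <= seq <= peptide.n_res:
                    raise XlgeomError(
                        f"restraint residue {seq} outside peptide 1..{peptide.n_res}"
                    )
                idx = self.index_of[seq - 1]
                atom = idx.get("CB", idx["CA"])
                if chemokine is None:
                    raise XlgeomError("restraints require a chemokine model")
                target = interaction_atom(chemokine.residue(r.chemokine_key)).position
                self.restraint_terms.append((atom, target, r))
            self.cn_weight = rs.cn_weight
        else:
            self.cn_weight = em.cn_weight
        if self.restraint_terms:
            self.r_atoms = np.array([t[0] for t in self.restraint_terms])
            self.r_targets = np.array([t[1] for t in self.restraint_terms])
            self.r_w = np.array([t[2].weight for t in self.restraint_terms])
            self.r_d0 = np.array([t[2].d0 for t in self.restraint_terms])
            self.r_lam = np.array([t[2].lam for t in self.restraint_terms])
        # kinematic subtrees: atom index sets rotated by each torsion
        n_atoms = len(self.p_res)
        self._phi_sub, self._psi_sub, self._chi_sub = [], [], []
        for i in range(peptide.n_res):
            idx = self.index_of[i]
            downstream = [
                a for j in range(i + 1, peptide.n_res) for a in self.index_of[j].values()
            ]
            phi_set = [idx["C"], idx["O"]]
            if "CB" in idx:
                phi_set.append(idx["CB"])
            if "SC" in idx:
                phi_set.append(idx["SC"])
            self._phi_sub.append(np.array(phi_set + downstream))
            self._psi_sub.append(np.array([idx["O"]] + downstream))
            self._chi_sub.append(np.array([idx["SC"]]) if "SC" in idx else None)

    def rotate_torsion(
        self, local: np.ndarray, kind: str, i: int, delta_deg: float
    ) -> np.ndarray:
        """Return a copy of ``local`` with one torsion changed by ``delta_deg``.

        Equivalent to rebuilding the chain with the new angle: the torsion's
        downstream subtree is rotated about its bond axis.
        """
        idx = self.index_of[i]
        if kind == "phi":
            a, b = local[idx["N"]], local[idx["CA"]]
            sub = self._phi_sub[i]
        elif kind == "psi":
            a, b = local[idx["CA"]], local[idx["C"]]
            sub = self._psi_sub[i]
        else:
            a, b = local[idx["CA"]], local[idx["CB"]]
            sub = self._chi_sub[i]
        rot = rotation_about_axis(b - a, math.radians(delta_deg))
        out = local.copy()
        out[sub] = a + (out[sub] - a) @ rot.T
        return out

    def build_local(self) -> np.ndarray:
        return _build_local(self.peptide, self.layout)

    def energy(self, world: np.ndarray) -> dict[str, float]:
        em = self.em
        terms = {"vdw": 0.0, "hbond": 0.0, "elec": 0.0, "torsion": 0.0,
                 "tether": 0.0, "restraint": 0.0}
        # intra-peptide
        if len(self.intra_i):
            d = np.linalg.norm(world[self.intra_i] - world[self.intra_j], axis=1)
            terms["vdw"] += em.w_vdw * _vdw(d, self.intra_sigma, em)
            nz = self.intra_qq != 0.0
            if nz.any():
                de = np.maximum(d[nz], em.elec_floor)
                terms["elec"] += em.w_el * float(np.sum(self.intra_qq[nz] / (4.0 * de**2)))
        # peptide-scaffold
        if len(self.s_pos):
            d = cdist(world, self.s_pos)
            terms["vdw"] += em.w_vdw * _vdw(d, self.inter_sigma, em)
            nz = self.inter_qq != 0.0
            if nz.any():
                de = np.maximum(d[nz], em.elec_floor)
                terms["elec"] += em.w_el * float(np.sum(self.inter_qq[nz] / (4.0 * de**2)))
            if em.w_hb > 0:
                for pmask, smask in ((self.p_isn, self.s_iso), (self.p_iso, self.s_isn)):
                    if pmask.any() and smask.any():
                        dd = d[np.ix_(pmask, smask)]
                        terms["hbond"] -= em.w_hb * float(
                            np.sum(np.exp(-((dd - em.hb_r0) ** 2) / (2.0 * em.hb_sigma**2)))
                        )
        # torsional strain (3-fold cosine on sampled torsions)
        p = self.peptide
        angles = np.concatenate([p.phi[1:], p.psi[:-1], p.chi])
        terms["torsion"] = em.w_tor * float(np.sum(1.0 + np.cos(3.0 * np.radians(angles))))
        # anchor tether
        if p.anchor_target is not None:
            dv = world[self.anchor_atom] - p.anchor_target
            terms["tether"] = p.tether_k * float(dv @ dv)
        # crosslink restraints (flat well then Lorentzian shoulder, vectorized)
        if self.restraint_terms:
            dist = np.linalg.norm(world[self.r_atoms] - self.r_targets, axis=1)
            excess = np.maximum(dist - self.r_d0, 0.0)
            terms["restraint"] = self.cn_weight * float(
                np.sum(-self.r_w / (1.0 + (excess / self.r_lam) ** 2))
            )
        terms["total"] = sum(v for k, v in terms.items() if k != "total")
        return terms

    def restraint_satisfaction(self, world: np.ndarray) -> float:
        if not self.restraint_terms:
            return 1.0
        ok = 0
        for atom, target, r in self.restraint_terms:
            if np.linalg.norm(world[atom] - target) <= r.d0 + r.lam:
                ok += 1
        return ok / len(self.restraint_terms)


def pose_energy(
    peptide: TorsionPeptide,
    chemokine: StructureModel | None = None,
    rs: RestraintSet | None = None,
    em: EnergyModel | None = None,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
) -> dict[str, float]:
    """Per-term energy report for a peptide pose; terms sum to ``total``."""
    em = em or EnergyModel()
    system = _DockingSystem(peptide, chemokine, rs, em)
    local = system.build_local()
    world = local if rotation is None else local @ rotation.T + translation
    return system.energy(world)


# ---------------------------------------------------------------------------
# Metropolis-Hastings torsion kernel (shared by the sampler and unit checks)

_BASINS = np.array([RAMACHANDRAN_BASINS[k] for k in sorted(RAMACHANDRAN_BASINS)])


def _log_wrapped_normal(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """log density of a wrapped (period 360°) Gaussian, 3-term approximation."""
    acc = np.zeros_like(np.asarray(x, dtype=float))
    for k in (-360.0, 0.0, 360.0):
        acc += np.exp(-((x - mu + k) ** 2) / (2.0 * sigma**2))
    return np.log(acc / (sigma * math.sqrt(2.0 * math.pi)) + 1e-300)


def basin_log_density(phi, psi) -> float:
    """log q(φ, ψ) under the uniform-mixture Ramachandran basin prior."""
    comps = [
        _log_wrapped_normal(phi, mphi, s) + _log_wrapped_normal(psi, mpsi, s)
        for mphi, mpsi, s in _BASINS
    ]
    m = np.max(comps, axis=0)
    return float(m + np.log(np.mean(np.exp(np.array(comps) - m), axis=0)))


def draw_basin(rng: np.random.Generator) -> tuple[float, float]:
    """Draw (φ, ψ) from the Ramachandran basin prior (uniform basin choice)."""
    mphi, mpsi, s = _BASINS[rng.integers(len(_BASINS))]
    return wrap_angle(rng.normal(mphi, s)), wrap_angle(rng.normal(mpsi, s))


def draw_basin_window(rng: np.random.Generator, length: int) -> tuple[np.ndarray, np.ndarray]:
    """Concerted draw: one basin, ``length`` (φ, ψ) pairs from it.

    Proposes secondary-structure-like segments (e.g. a strand stretch) in a
    single move; the matching density is :func:`window_log_density`.
    """
    mphi, mpsi, s = _BASINS[rng.integers(len(_BASINS))]
    return (
        wrap_angle(rng.normal(mphi, s, size=length)),
        wrap_angle(rng.normal(mpsi, s, size=length)),
    )


def window_log_density(phis: np.ndarray, psis: np.ndarray) -> float:
    """log q of a window draw: mixture over basins of the product density."""
    comps = []
    for mphi, mpsi, s in _BASINS:
        comps.append(
            float(np.sum(_log_wrapped_normal(phis, mphi, s)))
            + float(np.sum(_log_wrapped_normal(psis, mpsi, s)))
        )
    comps = np.array(comps)
    m = comps.max()
    return float(m + np.log(np.mean(np.exp(comps - m))))


class TorsionMCKernel:
    """Metropolis–Hastings kernel on a vector of torsion angles.

    Moves: ``zone`` — replace one (φ, ψ) pair by an independence draw from
    the Ramachandran basin prior, accepted with the Hastings factor
    q(old)/q(new); ``local`` — symmetric Gaussian perturbation of one angle.
    Used directly for detailed-balance checks and embedded in the docking
    sampler.
    """

    def __init__(
        self,
        energy_fn,
        n_angles: int,
        zone_pairs: list[tuple[int, int]],
        temperature: float = 1.0,
        p_zone: float = 0.3,
        local_sigma: float = 8.0,
    ):
        self.energy_fn = energy_fn
        self.n_angles = n_angles
        self.zone_pairs = zone_pairs
        self.temperature = temperature
        self.p_zone = p_zone if zone_pairs else 0.0
        self.local_sigma = local_sigma

    def propose(self, state: np.ndarray, rng: np.random.Generator):
        """Return (new_state, log Hastings correction log[q(old)/q(new)])."""
        new = state.copy()
        if self.zone_pairs and rng.random() < self.p_zone:
            i, j = self.zone_pairs[rng.integers(len(self.zone_pairs))]
            log_q_old = basin_log_density(state[i], state[j])
            new[i], new[j] = draw_basin(rng)
            log_q_new = basin_log_density(new[i], new[j])
            return new, log_q_old - log_q_new
        k = rng.integers(self.n_angles)
        new[k] = wrap_angle(new[k] + rng.normal(0.0, self.local_sigma))
        return new, 0.0

    def step(self, state: np.ndarray, energy: float, rng: np.random.Generator):
        new, log_hastings = self.propose(state, rng)
        e_new = self.energy_fn(new)
        log_alpha = -(e_new - energy) / self.temperature + log_hastings
        if log_alpha >= 0 or rng.random() < math.exp(max(log_alpha, -700.0)):
            return new, e_new, True
        return state, energy, False


# ---------------------------------------------------------------------------
# the docking sampler


@dataclass
class SamplerConfig:
    """Monte Carlo schedule. ``n_steps`` is the TOTAL step budget, split
    evenly across restarts; a fixed seed fixes the full trajectory."""

    n_steps: int = 200_000
    n_restarts: int = 10
    temperature: float = 1.0
    annealing: float = 1.0  # geometric per-step factor; 1.0 = constant T
    seed: int = 0
    p_zone: float = 0.2
    p_segment: float = 0.15  # concerted basin draw over a 2-3 residue window
    p_local: float = 0.3
    p_sidechain: float = 0.05
    p_rigid: float = 0.3
    local_sigma: float = 8.0
    rigid_trans_sigma: float = 0.4  # Å
    rigid_rot_sigma: float = 6.0  # degrees
    top_k: int = 10
    dedup_rmsd: float = 0.5  # Å, mutual Cβ RMSD below which poses are duplicates
    polish_steps: int | None = None  # per restart; None = steps_per_restart // 4
    polish_temperature: float = 0.05
    n_seed_draws: int = 40  # random starts scored per restart; best one seeds the MC

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        total = self.p_zone + self.p_segment + self.p_local + self.p_sidechain + self.p_rigid
        if abs(total - 1.0) > 1e-9:
            raise ValueError("move probabilities must sum to 1")


@dataclass
class Pose:
    energy: float
    terms: dict[str, float]
    coords: np.ndarray  # posed world coordinates of every peptide atom
    phi: np.ndarray
    psi: np.ndarray
    chi: np.ndarray
    restraint_satisfaction: float
    origin: tuple[int, int] = (0, 0)  # (restart, step) for deterministic ties


@dataclass
class ConformationStack:
    poses: list[Pose] = field(default_factory=list)
    peptide: TorsionPeptide | None = None

    def __post_init__(self):
        energies = [p.energy for p in self.poses]
        if any(b < a - 1e-9 for a, b in zip(energies, energies[1:])):
            raise ValueError("stack must be sorted by nondecreasing energy")

    def __len__(self):
        return len(self.poses)

    def best(self) -> Pose:
        return self.poses[0]

    def to_structure(self, rank: int = 0, model_id: str | None = None) -> StructureModel:
        pose = self.poses[rank]
        return peptide_to_structure(
            self.peptide, coords=pose.coords, model_id=model_id or f"pose_{rank}"
        )

    def summary(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "rank": i,
                    "total": p.energy,
                    **{k: v for k, v in p.terms.items() if k != "total"},
                    "restraint_satisfaction": p.restraint_satisfaction,
                }
                for i, p in enumerate(self.poses)
            ]
        )


def _cb_indices(system: _DockingSystem) -> np.ndarray:
    idx = []
    for d in system.index_of:
        idx.append(d.get("CB", d["CA"]))
    return np.array(idx)


def bpmc_sample(
    peptide: TorsionPeptide,
    chemokine: StructureModel | None,
    rs: RestraintSet | None,
    em: EnergyModel | None = None,
    cfg: SamplerConfig | None = None,
) -> ConformationStack:
    """Dock a flexible peptide onto a rigid core by biased-probability MC.

    Each restart begins from a random conformation (backbone torsions drawn
    from the Ramachandran basin prior) placed with its anchor Cα near the
    tether target (or near the scaffold centroid when untethered). Moves mix
    basin zone jumps, local torsion perturbations, side-chain torsion moves,
    and rigid-body translations/rotations; acceptance is Metropolis–Hastings
    at the configured temperature. The ``top_k`` lowest-energy mutually
    distinct poses (mutual Cβ RMSD above ``dedup_rmsd``) are returned, sorted
    by energy. The same seed reproduces the stack bit-for-bit.
    """
    em = em or EnergyModel()
    cfg = cfg or SamplerConfig()
    system = _DockingSystem(peptide, chemokine, rs, em)
    rng = np.random.default_rng(cfg.seed)
    cb_idx = _cb_indices(system)
    steps_per_restart = max(1, cfg.n_steps // cfg.n_restarts)
    n = peptide.n_res
    zone_res = list(range(1, n))  # φ of residue 0 is frame-fixed
    chi_res = [i for i in range(n) if "SC" in system.index_of[i]]
    candidates: list[Pose] = []

    if peptide.anchor_target is not None:
        center = np.asarray(peptide.anchor_target, dtype=float)
    elif len(system.s_pos):
        center = system.s_pos.mean(axis=0)
    else:
        center = np.zeros(3)

    for restart in range(cfg.n_restarts):
        work = replace(
            peptide,
            phi=peptide.phi.copy(),
            psi=peptide.psi.copy(),
            chi=peptide.chi.copy(),
        )
        system.peptide = work
        # best-of-N seeding: draw random starts, begin from the lowest energy
        seed_best = None
        for _ in range(cfg.n_seed_draws):
            for i in range(1, n):
                work.phi[i], work.psi[i - 1] = draw_basin(rng)
            if len(chi_res):
                work.chi[chi_res] = rng.uniform(-180.0, 180.0, size=len(chi_res))
            cand_local = _build_local(work, system.layout)
            cand_rot = random_rotation(rng)
            cand_trans = (
                center - cand_rot @ cand_local[system.anchor_atom] + rng.normal(0.0, 1.0, 3)
            )
            cand_world = cand_local @ cand_rot.T + cand_trans
            cand_terms = system.energy(cand_world)
            if seed_best is None or cand_terms["total"] < seed_best[0]["total"]:
                seed_best = (
                    cand_terms,
                    cand_local,
                    cand_rot,
                    cand_trans,
                    cand_world,
                    work.phi.copy(),
                    work.psi.copy(),
                    work.chi.copy(),
                )
        terms, local, rot, trans, world, sphi, spsi, schi = seed_best
        work.phi[:], work.psi[:], work.chi[:] = sphi, spsi, schi
        energy = terms["total"]
        if not np.isfinite(energy):
            raise SamplingFailureError(
                f"restart {restart}: non-finite starting energy"
            )
        temp = cfg.temperature
        best_seen = np.inf
        best_state = None
        polish = (
            cfg.polish_steps if cfg.polish_steps is not None else steps_per_restart // 4
        )
        for step in range(steps_per_restart + polish):
            if step == steps_per_restart:
                # cold polish: restart from this restart's best state so that
                # downhill basin flips (e.g. misfolded termini) can settle
                if best_state is None:
                    break
                local, rot, trans, bph, bps, bch = best_state
                local = local.copy()
                work.phi[:], work.psi[:], work.chi[:] = bph, bps, bch
                world = local @ rot.T + trans
                terms = system.energy(world)
                energy = terms["total"]
                temp = cfg.polish_temperature
            move = rng.random()
            log_hastings = 0.0
            undo = None
            rot_new, trans_new = rot, trans
            if move < cfg.p_zone:
                i = zone_res[rng.integers(len(zone_res))]
                old = (work.phi[i], work.psi[i - 1])
                log_q_old = basin_log_density(*old)
                new_phi, new_psi = draw_basin(rng)
                log_hastings = log_q_old - basin_log_density(new_phi, new_psi)
                local_new = system.rotate_torsion(local, "phi", i, new_phi - old[0])
                local_new = system.rotate_torsion(local_new, "psi", i - 1, new_psi - old[1])
                work.phi[i], work.psi[i - 1] = new_phi, new_psi
                undo = ("bb", i, old)
            elif move < cfg.p_zone + cfg.p_segment and len(zone_res) >= 2:
                length = int(rng.integers(2, min(3, len(zone_res)) + 1))
                start = int(rng.integers(len(zone_res) - length + 1))
                window = zone_res[start : start + length]
                old_phis = work.phi[window].copy()
                old_psis = work.psi[[i - 1 for i in window]].copy()
                log_q_old = window_log_density(old_phis, old_psis)
                new_phis, new_psis = draw_basin_window(rng, length)
                log_hastings = log_q_old - window_log_density(new_phis, new_psis)
                local_new = local
                for k, i in enumerate(window):
                    local_new = system.rotate_torsion(
                        local_new, "phi", i, new_phis[k] - work.phi[i]
                    )
                    local_new = system.rotate_torsion(
                        local_new, "psi", i - 1, new_psis[k] - work.psi[i - 1]
                    )
                    work.phi[i] = new_phis[k]
                    work.psi[i - 1] = new_psis[k]
                undo = ("window", window, old_phis, old_psis)
            elif move < cfg.p_zone + cfg.p_segment + cfg.p_local:
                i = zone_res[rng.integers(len(zone_res))]
                delta = rng.normal(0.0, cfg.local_sigma)
                if rng.integers(2) == 0:
                    undo = ("single", ("phi", i, work.phi[i]))
                    local_new = system.rotate_torsion(local, "phi", i, delta)
                    work.phi[i] = wrap_angle(work.phi[i] + delta)
                else:
                    undo = ("single", ("psi", i - 1, work.psi[i - 1]))
                    local_new = system.rotate_torsion(local, "psi", i - 1, delta)
                    work.psi[i - 1] = wrap_angle(work.psi[i - 1] + delta)
            elif (
                move < cfg.p_zone + cfg.p_segment + cfg.p_local + cfg.p_sidechain and chi_res
            ):
                i = chi_res[rng.integers(len(chi_res))]
                delta = rng.normal(0.0, 25.0)
                undo = ("single", ("chi", i, work.chi[i]))
                local_new = system.rotate_torsion(local, "chi", i, delta)
                work.chi[i] = wrap_angle(work.chi[i] + delta)
            else:
                axis = rng.normal(size=3)
                dr = rotation_about_axis(axis, math.radians(rng.normal(0.0, cfg.rigid_rot_sigma)))
                pivot = world.mean(axis=0)
                rot_new = dr @ rot
                trans_new = pivot - dr @ (pivot - trans) + rng.normal(
                    0.0, cfg.rigid_trans_sigma, 3
                )
                local_new = local
                undo = ("rigid",)
            world_new = local_new @ rot_new.T + trans_new
            terms_new = system.energy(world_new)
            log_alpha = -(terms_new["total"] - energy) / temp + log_hastings
            if log_alpha >= 0 or rng.random() < math.exp(max(log_alpha, -700.0)):
                local, world, rot, trans = local_new, world_new, rot_new, trans_new
                terms, energy = terms_new, terms_new["total"]
                if energy < best_seen - 1e-12:
                    best_seen = energy
                    best_state = (
                        local.copy(),
                        rot,
                        trans,
                        work.phi.copy(),
                        work.psi.copy(),
                        work.chi.copy(),
                    )
                    candidates.append(
                        Pose(
                            energy=energy,
                            terms=dict(terms),
                            coords=world.copy(),
                            phi=work.phi.copy(),
                            psi=work.psi.copy(),
                            chi=work.chi.copy(),
                            restraint_satisfaction=system.restraint_satisfaction(world),
                            origin=(restart, step),
                        )
                    )
            else:
                if undo[0] == "bb":
                    _, i, (oph, ops) = undo
                    work.phi[i], work.psi[i - 1] = oph, ops
                elif undo[0] == "window":
                    _, window, old_phis, old_psis = undo
                    for k, i in enumerate(window):
                        work.phi[i] = old_phis[k]
                        work.psi[i - 1] = old_psis[k]
                elif undo[0] == "single":
                    kind, i, val = undo[1]
                    getattr(work, kind)[i] = val
            if step < steps_per_restart:
                temp *= cfg.annealing
        # keep memory bounded
        candidates.sort(key=lambda p: (p.energy, p.origin))
        candidates = candidates[: max(cfg.top_k * 10, 50)]

    system.peptide = peptide
    candidates.sort(key=lambda p: (p.energy, p.origin))
    kept: list[Pose] = []
    for pose in candidates:
        dup = False
        for other in kept:
            diff = pose.coords[cb_idx] - other.coords[cb_idx]
            if math.sqrt(float(np.mean(np.sum(diff**2, axis=1)))) < cfg.dedup_rmsd:
                dup = True
                break
        if not dup:
            kept.append(pose)
        if len(kept) >= cfg.top_k:
            break
    if not kept:
        raise SamplingFailureError("no poses recorded; increase n_steps")
    return ConformationStack(poses=kept, peptide=peptide)


# ---------------------------------------------------------------------------
# β-registry classification


def classify_beta_registry(
    model: StructureModel,
    peptide_strand_residues,
    chemokine_strand_residues,
    cutoff: float = 6.5,
) -> str:
    """Classify the pairing direction of two β-strand stretches.

    A Cα contact map (cutoff Å) between the two residue lists is reduced to
    rungs (each peptide residue's closest in-contact partner). With at least
    3 rungs, a decreasing partner index along the peptide means antiparallel,
    increasing means parallel; anything else is ``'none'``.
    """
    pep = list(peptide_strand_residues)
    chem = list(chemokine_strand_residues)
    if len(pep) < 3 or len(chem) < 3:
        raise XlgeomError("need >= 3 residues per strand")
    from scipy.stats import spearmanr

    rungs = []
    for rid in pep:
        res = model.residue(rid)
        ca = res.atom("CA")
        if ca is None:
            continue
        best_j, best_d = None, np.inf
        for j, cid in enumerate(chem):
            other = model.residue(cid)
            ca2 = other.atom("CA")
            if ca2 is None:
                continue
            d = float(np.linalg.norm(ca.position - ca2.position))
            if d < cutoff and d < best_d:
                best_j, best_d = j, d
        if best_j is not None:
            rungs.append((res.seq_number, best_j))
    if len(rungs) < 3:
        return "none"
    i_idx = [r[0] for r in rungs]
    j_idx = [r[1] for r in rungs]
    if len(set(j_idx)) < 2:
        return "none"
    rho = spearmanr(i_idx, j_idx).statistic
    if rho <= -0.5:
        return "antiparallel"
    if rho >= 0.5:
        return "parallel"
    return "none"
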