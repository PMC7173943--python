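"""Per-residue profiling of a crystallographic ensemble.

Given several crystal structures of the same protein (e.g. a chemokine solved
in many space groups and complexes), this module computes, per residue:

* solvent-accessible surface area (SASA) by numerical sphere sampling,
  normalized to a maximal reference area per residue type, and
* side-chain conformational variability — the mean pairwise RMSD of the
  residue's side-chain heavy atoms after all members are superposed on a
  common backbone core,

and clusters the ensemble by the backbone geometry of a stated loop region
(e.g. the chemokine 30s/40s loops), selecting the highest-resolution member
of each cluster as its representative. Surface-exposed, conformationally
variable residues are the natural candidates for cysteine-scanning
crosslink panels, which is what these profiles are used to choose.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

from ._geometry import kabsch
from ._params import BACKBONE_ATOMS, DEFAULT_RADIUS, ELEMENT_RADII, MAX_SASA
from .errors import EmptyInputError, InsufficientEnsembleError, ResidueLookupError
from .struct_io import StructureModel, superpose

__all__ = [
    "compute_sasa",
    "normalize_sasa",
    "side_chain_variability",
    "cluster_loop_conformations",
    "ensemble_profile",
    "EnsembleProfile",
    "LoopClustering",
]


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def compute_sasa(
    structure: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> pd.DataFrame:
    """Per-residue SASA (Å²) by rolling-probe numerical sphere sampling.

    Each heavy atom is covered with ``n_points`` quasi-uniform test points at
    radius (vdW + probe); a point is accessible if it lies outside every
    neighboring atom's probe-expanded sphere. Hydrogens are ignored.

    Returns a DataFrame indexed by residue label with columns
    ``total``, ``backbone``, ``side_chain`` and ``res_type``.
    """
    atoms = []
    for ri, res in enumerate(structure.residues):
        for a in res.atoms:
            if a.element == "H":
                continue
            atoms.append((ri, a.name, a.position, ELEMENT_RADII.get(a.element, DEFAULT_RADIUS)))
    if not atoms:
        raise EmptyInputError(f"model {structure.model_id!r} has no heavy atoms")
    pos = np.array([a[2] for a in atoms])
    rad = np.array([a[3] for a in atoms]) + probe_radius
    unit = _sphere_points(n_points)
    nbr_dist = cdist(pos, pos)
    per_atom = np.zeros(len(atoms))
    for i in range(len(atoms)):
        neighbors = np.where((nbr_dist[i] < rad[i] + rad) & (np.arange(len(atoms)) != i))[0]
        pts = pos[i] + rad[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - pos[j]) ** 2, axis=1)
            accessible &= d2 > rad[j] ** 2
            if not accessible.any():
                break
        per_atom[i] = 4.0 * np.pi * rad[i] ** 2 * accessible.sum() / n_points

    rows = {}
    for (ri, name, _, _), area in zip(atoms, per_atom):
        res = structure.residues[ri]
        rec = rows.setdefault(
            res.label, {"res_type": res.res_type, "total": 0.0, "backbone": 0.0, "side_chain": 0.0}
        )
        rec["total"] += area
        if name in BACKBONE_ATOMS:
            rec["backbone"] += area
        else:
            rec["side_chain"] += area
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "residue"
    return df


def normalize_sasa(sasa: float, res_type: str, reference: dict | None = None) -> float:
    """SASA divided by the residue type's maximal reference area.

    Values may slightly exceed 1 for distorted conformers; no clamping is
    applied here (profile tables carry a clamped companion column).
    """
    ref = (reference or MAX_SASA).get(res_type)
    if ref is None:
        raise ResidueLookupError(f"no reference SASA for residue type {res_type!r}")
    return float(sasa) / float(ref)


def _side_chain_coords(model: StructureModel, res_id) -> dict[str, np.ndarray]:
    res = model.residue(res_id)
    return {
        a.name: a.position
        for a in res.atoms
        if a.name not in BACKBONE_ATOMS and a.element != "H"
    }


def side_chain_variability(
    ensemble: list[StructureModel],
    res_id,
    core_selection=None,
) -> float:
    """Side-chain conformational spread of one residue across an ensemble (Å).

    All members are superposed onto the first on core backbone atoms
    (``core_selection`` residues, default: all shared residues); the result
    is the mean pairwise RMSD of the residue's side-chain heavy atoms over
    all member pairs, using atom names common to each pair. Identical
    structures give exactly 0.
    """
    if len(ensemble) < 2:
        raise InsufficientEnsembleError("need >= 2 structures")
    reference = ensemble[0]
    aligned = [reference]
    for m in ensemble[1:]:
        rot, trans, _ = superpose(m, reference, selection=core_selection)
        aligned.append(m.transformed(rot, trans))
    coords = []
    for m in aligned:
        if m.has_residue(res_id):
            sc = _side_chain_coords(m, res_id)
            if sc:
                coords.append(sc)
    if len(coords) < 2:
        raise InsufficientEnsembleError(
            f"residue {res_id} has side-chain atoms in fewer than 2 members"
        )
    rmsds = []
    for a, b in itertools.combinations(coords, 2):
        shared = sorted(set(a) & set(b))
        if not shared:
            continue
        pa = np.array([a[n] for n in shared])
        pb = np.array([b[n] for n in shared])
        rmsds.append(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))
    if not rmsds:
        raise InsufficientEnsembleError(f"no shared side-chain atoms for {res_id}")
    mean = float(np.mean(rmsds))
    # identical members leave only superposition round-off; report exact zero
    return mean if mean > 1e-10 else 0.0


@dataclass
class EnsembleProfile:
    """Per-residue ensemble summary table plus the thresholds that set flags."""

    table: pd.DataFrame
    exposed_threshold: float = 0.3
    flexible_threshold: float = 1.0


@dataclass
class LoopClustering:
    structure_ids: list[str]
    rmsd_matrix: np.ndarray  # pairwise backbone RMSD over the loop range, Å
    labels: np.ndarray  # cluster label per structure (1-based)
    representatives: dict[int, str] = field(default_factory=dict)
    cutoff: float = 1.0

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.tolist()))

    def to_frame(self) -> pd.DataFrame:
        rep = {v: k for k, v in self.representatives.items()}
        return pd.DataFrame(
            {
                "structure": self.structure_ids,
                "cluster": self.labels,
                "representative": [s in rep for s in self.structure_ids],
            }
        )


def _range_keys(model: StructureModel, residue_range) -> list:
    chain, start, end = residue_range
    return [
        r.key
        for r in model.residues
        if r.chain_id == chain and start <= r.seq_number <= end
    ]


def _loop_backbone(model: StructureModel, keys) -> np.ndarray | None:
    pts = []
    for key in keys:
        res = model.residue(key)
        for name in ("N", "CA", "C", "O"):
            a = res.atom(name)
            if a is None:
                return None
            pts.append(a.position)
    return np.array(pts)


def cluster_loop_conformations(
    ensemble: list[StructureModel],
    residue_range: tuple[str, int, int],
    cutoff: float = 1.0,
) -> LoopClustering:
    """Cluster ensemble members by the backbone geometry of a loop region.

    ``residue_range`` is ``(chain_id, first_seq, last_seq)``. Each member is
    superposed on the first over core backbone atoms (everything outside the
    range); average-linkage hierarchical clustering of the pairwise loop
    backbone (N, Cα, C, O) RMSD matrix is cut at ``cutoff`` Å. The
    representative of each cluster is its best-resolution member (lowest Å,
    missing resolutions last), ties broken by structure id.
    """
    chain, start, end = residue_range
    usable, coords = [], []
    reference = None
    for m in ensemble:
        keys = _range_keys(m, residue_range)
        expected = set(range(start, end + 1))
        present = {k[1] for k in keys}
        if not expected <= present:
            warnings.warn(
                f"{m.model_id}: residues {sorted(expected - present)} of range "
                f"{chain}:{start}-{end} absent; structure excluded"
            )
            continue
        if reference is None:
            reference = m
            aligned = m
        else:
            core = [
                r.key
                for r in m.residues
                if not (r.chain_id == chain and start <= r.seq_number <= end)
            ]
            rot, trans, _ = superpose(m, reference, selection=core or None)
            aligned = m.transformed(rot, trans)
        bb = _loop_backbone(aligned, _range_keys(aligned, residue_range))
        if bb is None:
            warnings.warn(f"{m.model_id}: incomplete loop backbone; excluded")
            continue
        usable.append(m)
        coords.append(bb)
    if len(usable) < 2:
        raise InsufficientEnsembleError("need >= 2 structures containing the range")
    n = len(usable)
    rmat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        # loop RMSD in the common core frame (no per-pair refit: geometry
        # differences relative to the core are the signal)
        rmat[i, j] = rmat[j, i] = np.sqrt(
            np.mean(np.sum((coords[i] - coords[j]) ** 2, axis=1))
        )
    z = linkage(squareform(rmat, checks=False), method="average")
    labels = fcluster(z, t=cutoff, criterion="distance")
    reps: dict[int, str] = {}
    for lab in sorted(set(labels.tolist())):
        members = [usable[i] for i in np.where(labels == lab)[0]]
        best = min(
            members,
            key=lambda m: (m.resolution if m.resolution is not None else np.inf, m.model_id),
        )
        reps[lab] = best.model_id
    return LoopClustering(
        structure_ids=[m.model_id for m in usable],
        rmsd_matrix=rmat,
        labels=labels,
        representatives=reps,
        cutoff=cutoff,
    )


def ensemble_profile(
    ensemble: list[StructureModel],
    probe_radius: float = 1.4,
    n_points: int = 960,
    exposed_threshold: float = 0.3,
    flexible_threshold: float = 1.0,
    core_selection=None,
) -> EnsembleProfile:
    """Assemble the per-residue profile table over a structural ensemble.

    Columns: mean normalized side-chain SASA (unclamped and clamped),
    side-chain variability (Å), and the derived exposed/flexible flags.
    """
    if not ensemble:
        raise EmptyInputError("empty ensemble")
    sasa_frames = [compute_sasa(m, probe_radius, n_points) for m in ensemble]
    labels = sasa_frames[0].index
    rows = []
    for label in labels:
        res = None
        for r in ensemble[0].residues:
            if r.label == label:
                res = r
                break
        norm_vals = []
        for df in sasa_frames:
            if label in df.index:
                col = "side_chain" if res.res_type != "GLY" else "total"
                norm_vals.append(normalize_sasa(df.loc[label, col], res.res_type))
        mean_norm = float(np.mean(norm_vals)) if norm_vals else np.nan
        try:
            var = (
                side_chain_variability(ensemble, res.key, core_selection)
                if len(ensemble) > 1
                else np.nan
            )
        except InsufficientEnsembleError:
            var = np.nan
        rows.append(
            {
                "residue": label,
                "res_type": res.res_type,
                "normalized_sasa": mean_norm,
                "normalized_sasa_clamped": float(np.clip(mean_norm, 0.0, 1.0)),
                "side_chain_variability": var,
                "exposed": bool(mean_norm > exposed_threshold),
                "flexible": bool(var > flexible_threshold) if np.isfinite(var) else False,
            }
        )
    table = pd.DataFrame(rows).set_index("residue")
    return EnsembleProfile(table, exposed_threshold, flexible_threshold)
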