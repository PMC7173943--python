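"""Synthetic inputs for the whole pipeline.

Everything the analysis consumes can be generated here with a planted ground
truth: a toy peptide-on-β-sheet complex whose true pose and true distance
matrix are recorded; per-replicate GMFI tables whose expected crosslinking
efficiency decays sigmoidally with the true interaction-atom distance (with
promiscuous residues that crosslink regardless of distance and misfolded
mutants that display nothing); and logistic concentration-response data with
stated pEC50/Emax truths. All generators are deterministic under a fixed
seed.

What the simulation emulates — and what it does not — is discussed in the
package methods note; briefly, it reproduces the *statistical structure* of
a cysteine-scanning crosslink panel (values above 100%, replicate noise,
ladder contacts, promiscuity, misfolding) without claiming any biophysical
realism for the toy fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geometry import kabsch
from ._params import AA1_TO_3
from .errors import XlgeomError
from .peptide_sampler import (
    TorsionPeptide,
    build_extended_peptide,
    combine_models,
    peptide_to_structure,
)
from .model_assessment import DistanceMatrix, distance_map
from .restraints import DEFAULT_CN_WEIGHT, DEFAULT_D0, DEFAULT_LAMBDA, DistanceRestraint, RestraintSet
from .struct_io import StructureModel
from .xlink_quant import EfficiencyTable, flag_misfolded, normalize_efficiency

__all__ = [
    "SimulationSpec",
    "ToyComplex",
    "generate_toy_complex",
    "simulate_efficiencies",
    "simulate_dose_response",
    "restraints_at_planted_pose",
]

CONTROL_RECEPTOR = "D187C"
CONTROL_CHEMOKINE = "W5C"


@dataclass
class SimulationSpec:
    """Ground-truth parameters for all synthetic inputs.

    Distance-to-efficiency model: expected efficiency (% of control) is
    ``e_max / (1 + exp((d - d50) / steepness))`` so that contacts at typical
    disulfide Cβ–Cβ distances land in the experimentally observed 80-135%
    band, the inclusion threshold (65%) is crossed at d50, and pairs beyond
    ~10 Å fall into the noise. Replicate noise is multiplicative Gaussian
    with relative SD ``noise_sigma``.
    """

    seed: int = 1
    peptide_sequence: str = "GISIYS"  # receptor-side peptide, numbered 1..n
    e_max: float = 130.0  # %
    d50: float = 8.0  # Å
    steepness: float = 1.5  # Å
    noise_sigma: float = 0.10  # relative SD of replicate noise
    promiscuous: tuple = ("H25C",)  # crosslink regardless of distance
    promiscuity_floor: float = 40.0  # %
    misfolded: tuple = ("L26C", "I28C")  # export-deficient chemokine mutants
    control_gmfi: float = 1000.0
    # concentration-response truths: (ligand, receptor) -> (pEC50, Emax, baseline)
    dose_truths: dict = field(
        default_factory=lambda: {
            ("CK-WT", "R-WT"): (7.40, 100.0, 0.0),
            ("CK-WT", "R-E26R"): (6.68, 87.9, 0.0),
        }
    )
    dose_noise_sigma: float = 5.0  # % points
    dose_n_replicates: int = 3

    def __post_init__(self):
        if not 6 <= len(self.peptide_sequence) <= 27:
            raise XlgeomError("peptide length must be 6..27")
        if self.noise_sigma < 0 or self.d50 <= 0:
            raise XlgeomError("noise_sigma must be >= 0 and d50 > 0")


# scaffold segments (chain B, author-style numbering with gaps):
#   21-29 exposed β1-like strand with lead-in ('SDYAHLKIL')
#   32-36 second strand, antiparallel beneath the first ('VELKV')
#   39-46 α-helix a further layer down ('AEALAKEA')
# The solvent-exposed face of the first strand (opposite the second strand)
# is where the peptide gets planted.
_STRAND1_SEQ, _STRAND1_FIRST = "SDYAHLKIL", 21
_STRAND1 = (25, 29)  # the 'HLKIL' rung positions
_STRAND2_SEQ, _STRAND2_FIRST = "VELKV", 32
_HELIX_SEQ, _HELIX_FIRST = "AEALAKEA", 39
_HELIX = (39, 46)
_SHEET_SPACING = 4.8  # Å between adjacent strand axes
_HELIX_DEPTH = 9.5  # Å below the exposed strand


def _renumber(model: StructureModel, first_seq: int) -> StructureModel:
    for res in model.residues:
        res.seq_number += first_seq - 1
    return StructureModel(
        model_id=model.model_id,
        residues=model.residues,
        chain_roles=dict(model.chain_roles),
        provenance=model.provenance,
    )


def _ca_positions(model: StructureModel) -> np.ndarray:
    return np.array([r.atom("CA").position for r in model.residues])


def _place_onto(model: StructureModel, local_ca: np.ndarray, targets: np.ndarray) -> StructureModel:
    rot, trans, _ = kabsch(local_ca, targets)
    return model.transformed(rot, trans)


def _build_scaffold() -> StructureModel:
    s1 = peptide_to_structure(
        build_extended_peptide(_STRAND1_SEQ, chain_id="B"), model_id="toy_chemokine"
    )
    s1 = _renumber(s1, _STRAND1_FIRST)
    ca1 = _ca_positions(s1)
    axis = ca1[-1] - ca1[0]
    axis /= np.linalg.norm(axis)
    # sheet plane: strands side by side perpendicular to the Cβ up/down axis
    cbs = np.array(
        [r.atom("CB").position - r.atom("CA").position for r in s1.residues if r.atom("CB")]
    )
    cb_dir = cbs[::2].mean(axis=0)
    cb_dir -= (cb_dir @ axis) * axis
    cb_dir /= np.linalg.norm(cb_dir)
    away = np.cross(axis, cb_dir)  # in-plane, perpendicular to the strand

    s2 = peptide_to_structure(
        build_extended_peptide(_STRAND2_SEQ, chain_id="B"), model_id="s2"
    )
    s2 = _renumber(s2, _STRAND2_FIRST)
    rungs = ca1[-len(s2.residues):][::-1]  # antiparallel to strand 1
    s2 = _place_onto(s2, _ca_positions(s2), rungs - _SHEET_SPACING * away)

    hx_pep = build_extended_peptide(_HELIX_SEQ, chain_id="B")
    hx_pep.phi[:] = -63.0
    hx_pep.psi[:] = -42.0
    hx = _renumber(peptide_to_structure(hx_pep, model_id="hx"), _HELIX_FIRST)
    n_hx = len(hx.residues)
    center = ca1.mean(axis=0) - _HELIX_DEPTH * away
    hx_targets = center + np.outer((np.arange(n_hx) - (n_hx - 1) / 2) * 1.5, axis)
    hx = _place_onto(hx, _ca_positions(hx), hx_targets)

    residues = [*s1.residues, *s2.residues, *hx.residues]
    return StructureModel(
        model_id="toy_chemokine",
        residues=residues,
        chain_roles={"B": "chemokine"},
        provenance="synthetic toy chemokine scaffold (explicitly placed segments)",
    )


_SCAFFOLD_LETTERS = {
    **{_STRAND1_FIRST + i: c for i, c in enumerate(_STRAND1_SEQ)},
    **{_STRAND2_FIRST + i: c for i, c in enumerate(_STRAND2_SEQ)},
    **{_HELIX_FIRST + i: c for i, c in enumerate(_HELIX_SEQ)},
}


def _chem_mutant(seq_number: int) -> str:
    return f"{_SCAFFOLD_LETTERS[seq_number].upper()}{seq_number}C"


def _relax_sidechain_centroids(model: StructureModel, context: list[np.ndarray]) -> None:
    """Rotate SC centroids about their Cα–Cβ axes to relieve steric clashes.

    Deterministic 24-step torsion scan per residue, minimizing a soft overlap
    penalty against all context atoms plus the model's other atoms. Backbone
    and Cβ positions are untouched.
    """
    from ._geometry import rotation_about_axis

    all_atoms = [(r.key, a.name, a) for r in model.residues for a in r.atoms]
    for res in model.residues:
        sc = res.atom("SC")
        cb = res.atom("CB")
        ca = res.atom("CA")
        if sc is None or cb is None or ca is None:
            continue
        others = np.array(
            [a.position for key, name, a in all_atoms if not (key == res.key and name == "SC")]
        )
        env = np.vstack([others, *[c[None, :] if c.ndim == 1 else c for c in context]]) \
            if context else others
        axis = cb.position - ca.position
        best_pos, best_pen = sc.position, np.inf
        for ang in np.arange(0.0, 360.0, 15.0):
            rot = rotation_about_axis(axis, np.deg2rad(ang))
            cand = cb.position + rot @ (sc.position - cb.position)
            d = np.linalg.norm(env - cand, axis=1)
            pen = float(np.sum(np.maximum(0.0, 3.4 - d) ** 2))
            if pen < best_pen - 1e-12:
                best_pen, best_pos = pen, cand
        sc.position = best_pos


@dataclass
class ToyComplex:
    """A synthetic complex with a planted peptide pose and recorded truth."""

    scaffold: StructureModel
    peptide: TorsionPeptide
    planted_pose: StructureModel  # the peptide at its true position
    true_distances: DistanceMatrix  # interaction-atom distances at the truth
    ladder_pairs: list  # (receptor mutant, chemokine mutant) rungs of the sheet
    receptor_mutants: list
    chemokine_mutants: list
    anchor_target: np.ndarray  # true Cα position of the C-terminal residue

    def complex_model(self) -> StructureModel:
        return combine_models(self.planted_pose, self.scaffold, model_id="toy_true")

    @property
    def strand1_residues(self) -> list[tuple[str, int, str]]:
        return [("B", s, "") for s in range(_STRAND1[0], _STRAND1[1] + 1)]


def generate_toy_complex(spec: SimulationSpec | None = None) -> ToyComplex:
    """Build the toy chemokine-like scaffold and plant the peptide on it.

    The peptide is built ab initio in the extended conformation and rigidly
    placed as an extra antiparallel strand along the scaffold's exposed
    strand, on the solvent side, with the lateral offset and axial shift
    chosen (by a small deterministic grid search) to minimize the worst
    ladder interaction-atom distance. The placement, the resulting true
    distance matrix, and the ladder pair list are all recorded.
    """
    spec = spec or SimulationSpec()
    scaffold = _build_scaffold()
    pep = build_extended_peptide(spec.peptide_sequence, chain_id="A")
    pep_model = peptide_to_structure(pep, model_id="toy_peptide")
    s1_lo, s1_hi = _STRAND1
    strand_keys = [("B", s, "") for s in range(s1_lo, s1_hi + 1)]
    strand_ca = np.array([scaffold.residue(k).atom("CA").position for k in strand_keys])
    strand2_ca = np.array(
        [r.atom("CA").position for r in scaffold.residues
         if _STRAND2_FIRST <= r.seq_number < _STRAND2_FIRST + len(_STRAND2_SEQ)]
    )
    axis = strand_ca[-1] - strand_ca[0]
    axis /= np.linalg.norm(axis)
    away = strand_ca.mean(axis=0) - strand2_ca.mean(axis=0)
    away -= (away @ axis) * axis
    away /= np.linalg.norm(away)

    n_rungs = min(pep.n_res, len(strand_keys))
    pep_ca_local = np.array(
        [pep_model.residue(("A", i + 1, "")).atom("CA").position for i in range(pep.n_res)]
    )
    # antiparallel: peptide residue 1 pairs with the strand's C-terminal rung
    target_rungs = strand_ca[::-1][:n_rungs]

    def placement(offset: float, shift: float):
        targets = target_rungs + offset * away + shift * axis
        rot, trans, _ = kabsch(pep_ca_local[:n_rungs], targets)
        posed = pep_ca_local @ rot.T + trans
        worst = max(
            float(np.linalg.norm(posed[i] - t)) for i, t in enumerate(targets)
        )
        return worst, rot, trans

    best = None
    for offset in np.arange(4.2, 5.61, 0.2):
        for shift in np.arange(-1.0, 1.01, 0.25):
            worst, rot, trans = placement(float(offset), float(shift))
            if best is None or worst < best[0]:
                best = (worst, rot, trans)
    _, rot, trans = best
    planted = peptide_to_structure(pep, model_id="toy_peptide_true").transformed(rot, trans)
    planted = StructureModel(
        model_id="toy_peptide_true",
        residues=planted.residues,
        chain_roles={"A": "receptor"},
        provenance="planted true pose",
    )

    # relieve side-chain interdigitation at the interface (Cβ traces untouched)
    pep_atoms = np.array([a.position for r in planted.residues for a in r.atoms])
    _relax_sidechain_centroids(scaffold, [pep_atoms])
    scaf_atoms = np.array([a.position for r in scaffold.residues for a in r.atoms])
    _relax_sidechain_centroids(planted, [scaf_atoms])

    receptor_mutants = [
        f"{spec.peptide_sequence[i].upper()}{i + 1}C" for i in range(pep.n_res)
    ]
    chem_positions = list(range(s1_lo, s1_hi + 1)) + list(range(_HELIX[0], _HELIX[1] + 1, 2))
    chemokine_mutants = [_chem_mutant(p) for p in chem_positions]
    true_dm = distance_map(
        combine_models(planted, scaffold, model_id="toy_true"),
        receptor_mutants,
        chemokine_mutants,
    )
    # the realized rungs of the planted sheet: panel pairs in disulfide range
    ladder_pairs = [
        (r, c)
        for r in true_dm.distances.index
        for c in true_dm.distances.columns
        if np.isfinite(true_dm.distances.loc[r, c]) and true_dm.distances.loc[r, c] <= 5.0
    ]
    if len(ladder_pairs) < 3:
        raise XlgeomError("degenerate toy geometry: fewer than 3 ladder contacts")
    anchor_target = np.array(
        planted.residue(("A", pep.n_res, "")).atom("CA").position
    )
    pep.anchor_target = anchor_target
    return ToyComplex(
        scaffold=scaffold,
        peptide=pep,
        planted_pose=planted,
        true_distances=true_dm,
        ladder_pairs=ladder_pairs,
        receptor_mutants=receptor_mutants,
        chemokine_mutants=chemokine_mutants,
        anchor_target=anchor_target,
    )


def restraints_at_planted_pose(
    toy: ToyComplex,
    cutoff: float = 7.5,
    weight: float = 5.0,
    cn_weight: float = DEFAULT_CN_WEIGHT,
) -> RestraintSet:
    """Noiseless dense restraints generated from the planted pose itself.

    Every panel pair with true interaction-atom distance <= ``cutoff`` gets a
    restraint of the stated weight whose flat-well edge sits exactly at its
    true distance, so at the planted pose every restraint is at its well
    floor (d <= d0 with equality) and any outward displacement is penalized
    immediately. This is the idealized no-noise fixture for pose-recovery
    experiments.
    """
    from .xlink_quant import parse_mutant

    restraints = []
    for r in toy.true_distances.distances.index:
        for c in toy.true_distances.distances.columns:
            d = toy.true_distances.distances.loc[r, c]
            if np.isfinite(d) and d <= cutoff:
                restraints.append(
                    DistanceRestraint(
                        receptor_res=r,
                        chemokine_res=c,
                        weight=weight,
                        d0=float(d),
                        lam=DEFAULT_LAMBDA,
                        receptor_key=("A", parse_mutant(r)[1], ""),
                        chemokine_key=("B", parse_mutant(c)[1], ""),
                    )
                )
    return RestraintSet(restraints, cn_weight=cn_weight)


def parallel_decoy_restraints(toy: ToyComplex, **kwargs) -> RestraintSet:
    """The planted restraints with the strand registry mirrored.

    Each chemokine strand position s is reflected within the strand
    (s -> first+last-s), converting the antiparallel ladder into the
    hypothetical parallel pairing of the same residues. Docking under this
    decoy set should produce a pose the registry classifier calls parallel —
    the discrimination the crosslink ladder itself provides.
    """
    from .xlink_quant import parse_mutant

    true_set = restraints_at_planted_pose(toy, **kwargs)
    lo, hi = _STRAND1
    decoys = []
    for r in true_set:
        s = r.chemokine_key[1]
        if not lo <= s <= hi:
            continue
        mirrored = lo + hi - s
        decoys.append(
            DistanceRestraint(
                receptor_res=r.receptor_res,
                chemokine_res=_chem_mutant(mirrored),
                weight=r.weight,
                d0=r.d0,
                lam=r.lam,
                receptor_key=r.receptor_key,
                chemokine_key=("B", mirrored, ""),
            )
        )
    # mirroring can collide two pairs onto one; keep the tighter restraint
    seen = {}
    for d in decoys:
        key = (d.receptor_res, d.chemokine_res)
        if key not in seen or d.d0 < seen[key].d0:
            seen[key] = d
    return RestraintSet(list(seen.values()), cn_weight=true_set.cn_weight)


def simulate_efficiencies(
    true_distances: DistanceMatrix,
    spec: SimulationSpec | None = None,
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, EfficiencyTable, pd.DataFrame]:
    """Simulate per-replicate GMFI records from true pair distances.

    Expected efficiency follows the sigmoid of ``spec``; promiscuous
    chemokine mutants get a floor regardless of distance; misfolded mutants
    emit near-zero GMFI and near-zero display on the folding-control
    receptor. The control pair is emitted in every replicate. Returns
    ``(records, table, display)`` where ``table`` already carries the
    misfolded-partner flags derived from the display control.
    """
    spec = spec or SimulationSpec()
    if n_replicates < 1:
        raise XlgeomError("n_replicates must be >= 1")
    rng = np.random.default_rng(spec.seed + 101)
    rows = []
    for rep in range(1, n_replicates + 1):
        ctrl = spec.control_gmfi * float(np.exp(rng.normal(0.0, 0.05)))
        rows.append(
            {
                "receptor_mutant": CONTROL_RECEPTOR,
                "chemokine_mutant": CONTROL_CHEMOKINE,
                "replicate": rep,
                "gmfi": ctrl,
                "is_control": True,
            }
        )
        for r in true_distances.distances.index:
            for c in true_distances.distances.columns:
                d = float(true_distances.distances.loc[r, c])
                if not np.isfinite(d):
                    continue
                e = spec.e_max / (1.0 + np.exp((d - spec.d50) / spec.steepness))
                if c in spec.promiscuous:
                    e = max(e, spec.promiscuity_floor)
                if c in spec.misfolded:
                    e = 1.0  # no surface chemokine, flow signal at background
                gmfi = (e / 100.0) * ctrl * (1.0 + rng.normal(0.0, spec.noise_sigma))
                rows.append(
                    {
                        "receptor_mutant": r,
                        "chemokine_mutant": c,
                        "replicate": rep,
                        "gmfi": max(float(gmfi), 0.0),
                        "is_control": False,
                    }
                )
    records = pd.DataFrame(rows)
    table = normalize_efficiency(records)
    display_rows = []
    misfolded = []
    for c in true_distances.distances.columns:
        level = 2.0 if c in spec.misfolded else 100.0
        display = max(0.0, level * (1.0 + rng.normal(0.0, spec.noise_sigma)))
        display_rows.append({"chemokine_mutant": c, "ackr3_display_pct": display})
        if flag_misfolded(c, display) == "misfolded":
            misfolded.append(c)
    display = pd.DataFrame(display_rows)
    table = table.apply_misfolded(misfolded)
    return records, table, display


def simulate_dose_response(
    spec: SimulationSpec | None = None,
    concentrations_m: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate BRET-style concentration-response tables.

    Default concentrations span 0.1 nM to 1 µM (eight half-log steps, four
    log units); each (ligand, receptor) truth in the spec yields
    ``dose_n_replicates`` replicates with additive Gaussian noise of
    ``dose_noise_sigma`` % points. Returns the tidy table and the truth map.
    """
    spec = spec or SimulationSpec()
    if concentrations_m is None:
        concentrations_m = 10.0 ** np.arange(-10.0, -5.9, 0.5)
    concentrations_m = np.asarray(concentrations_m, dtype=float)
    if len(concentrations_m) < 6 or (
        np.log10(concentrations_m.max() / concentrations_m.min()) < 3
    ):
        raise XlgeomError("need >= 6 concentrations spanning >= 3 log units")
    rng = np.random.default_rng(spec.seed + 202)
    rows = []
    for (ligand, receptor), (pec50, emax, baseline) in spec.dose_truths.items():
        for rep in range(1, spec.dose_n_replicates + 1):
            mu = baseline + (emax - baseline) / (
                1.0 + 10.0 ** (-pec50 - np.log10(concentrations_m))
            )
            y = mu + rng.normal(0.0, spec.dose_noise_sigma, size=mu.shape)
            for c, v in zip(concentrations_m, y):
                rows.append(
                    {
                        "ligand": ligand,
                        "receptor": receptor,
                        "conc_M": c,
                        "response_pct": v,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows), dict(spec.dose_truths)
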