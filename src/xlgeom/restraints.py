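"""Weighted local distance restraints derived from crosslinking efficiencies.

Pairs that crosslink with efficiency above an inclusion threshold (default
65% of the control pair) become distance restraints between the residues'
interaction atoms (Cβ, or Cα for Gly). Efficiencies of included pairs are
mapped linearly onto restraint weights in [0.5, 5], so the strongest
crosslink carries a 10x deeper well than the weakest included one.

The restraint penalty is *local*: a flat well of depth -w for distances up
to d0 (default 4 Å, the Cβ–Cβ separation typical of a disulfide bond), then
a Lorentzian shoulder -w / (1 + ((d - d0)/λ)²) that rises toward 0 as the
atoms separate. Unlike a harmonic restraint it never grows without bound, so
an unsatisfiable restraint stops influencing the pose once the pair is far
apart instead of dominating the energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyInputError, ResidueLookupError, XlgeomError
from .struct_io import StructureModel, interaction_atom, pair_distance
from .xlink_quant import MEASURED, EfficiencyTable

__all__ = [
    "WeightTransform",
    "DistanceRestraint",
    "RestraintSet",
    "efficiencies_to_weights",
    "restraint_energy",
    "build_restraint_set",
    "total_restraint_energy",
]

DEFAULT_D0 = 4.0
DEFAULT_LAMBDA = 2.0
DEFAULT_CN_WEIGHT = 5.0


@dataclass
class WeightTransform:
    """Linear efficiency-to-weight mapping with an inclusion threshold.

    ``anchor_mode='range_of_included'`` (default) maps the min/max *included*
    efficiencies onto [weight_min, weight_max]; ``'threshold'`` anchors the
    lower end at the inclusion threshold instead.
    """

    inclusion_threshold: float = 65.0  # %
    weight_min: float = 0.5
    weight_max: float = 5.0
    anchor_mode: str = "range_of_included"

    def __post_init__(self):
        if not self.weight_min < self.weight_max:
            raise ValueError("weight_min must be < weight_max")
        if self.inclusion_threshold <= 0:
            raise ValueError("inclusion threshold must be positive")
        if self.anchor_mode not in ("range_of_included", "threshold"):
            raise ValueError(f"unknown anchor mode {self.anchor_mode!r}")


@dataclass
class DistanceRestraint:
    receptor_res: str  # mutant/position id on the receptor side, e.g. "G3C"
    chemokine_res: str
    weight: float
    d0: float = DEFAULT_D0  # flat-well edge, Å
    lam: float = DEFAULT_LAMBDA  # shoulder decay length, Å
    # resolved attachment points, set by build_restraint_set
    receptor_key: tuple | None = None
    chemokine_key: tuple | None = None

    def __post_init__(self):
        if self.d0 <= 0 or self.lam <= 0:
            raise ValueError("d0 and lambda must be positive")


@dataclass
class RestraintSet:
    restraints: list[DistanceRestraint] = field(default_factory=list)
    cn_weight: float = DEFAULT_CN_WEIGHT  # global penalty multiplier
    transform: WeightTransform | None = None

    def __post_init__(self):
        pairs = [(r.receptor_res, r.chemokine_res) for r in self.restraints]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate residue pairs in restraint set")

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)


def efficiencies_to_weights(
    table: EfficiencyTable,
    transform: WeightTransform | None = None,
) -> RestraintSet:
    """Select above-threshold pairs and assign linear weights.

    Only measured, non-misfolded cells are considered; the efficiency must
    strictly exceed the threshold. With the default anchoring, weight
    ``w = w_min + (w_max - w_min) * (e - e_min) / (e_max - e_min)`` over the
    included efficiencies; a degenerate included set (all equal, or a single
    pair) gets ``w_max`` with a warning.
    """
    t = transform or WeightTransform()
    measured = table.measured_pairs()  # control pair already excluded there
    if measured.empty and table.efficiency.isna().all().all():
        raise EmptyInputError("efficiency table has no measured cells")
    included = measured[measured["efficiency"] > t.inclusion_threshold]
    if included.empty:
        warnings.warn(
            f"no pair exceeds the {t.inclusion_threshold}% threshold; empty restraint set"
        )
        return RestraintSet([], transform=t)
    e = included["efficiency"].to_numpy(dtype=float)
    if t.anchor_mode == "threshold":
        lo, hi = t.inclusion_threshold, float(e.max())
    else:
        lo, hi = float(e.min()), float(e.max())
    if hi - lo < 1e-12:
        warnings.warn("included efficiencies are degenerate; assigning weight_max to all")
        weights = np.full_like(e, t.weight_max)
    else:
        weights = t.weight_min + (t.weight_max - t.weight_min) * (e - lo) / (hi - lo)
    restraints = [
        DistanceRestraint(row.receptor, row.chemokine, float(w))
        for row, w in zip(included.itertuples(), weights)
    ]
    return RestraintSet(restraints, transform=t)


def restraint_energy(d: float, r: DistanceRestraint) -> float:
    """Local restraint penalty at interatomic distance ``d`` (Å).

    E(d) = -w for d <= d0; -w / (1 + ((d - d0)/λ)²) beyond; continuous,
    nondecreasing past the well edge, and asymptotically 0.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise XlgeomError("distance must be nonnegative")
    excess = np.maximum(d - r.d0, 0.0)
    e = -r.weight / (1.0 + (excess / r.lam) ** 2)
    if e.ndim == 0:
        return float(e)
    return e


def build_restraint_set(
    table: EfficiencyTable,
    transform: WeightTransform | None = None,
    receptor: StructureModel | None = None,
    chemokine: StructureModel | None = None,
    receptor_chain: str | None = None,
    chemokine_chain: str | None = None,
    cn_weight: float = DEFAULT_CN_WEIGHT,
) -> RestraintSet:
    """Full restraint construction: filter, weight, and attach to atoms.

    Mutant ids are resolved to residues by author sequence number in the
    stated chain (default: the first chain with the matching role). Pairs
    flagged ``misfolded_partner`` in the table never yield restraints; an
    included pair whose residue cannot be resolved is an error naming it.

    ``receptor`` may be omitted when the receptor side is an ab initio
    peptide whose residues are numbered 1..n (attachment keys resolved later
    by the sampler).
    """
    from .xlink_quant import parse_mutant

    rs = efficiencies_to_weights(table, transform)
    if chemokine is not None and chemokine_chain is None:
        role_chains = chemokine.chains_with_role("chemokine")
        chemokine_chain = role_chains[0] if role_chains else chemokine.residues[0].chain_id
    if receptor is not None and receptor_chain is None:
        role_chains = receptor.chains_with_role("receptor")
        receptor_chain = role_chains[0] if role_chains else receptor.residues[0].chain_id
    for r in rs.restraints:
        _, rpos, _ = parse_mutant(r.receptor_res)
        _, cpos, _ = parse_mutant(r.chemokine_res)
        if receptor is not None:
            key = (receptor_chain, rpos, "")
            if not receptor.has_residue(key):
                raise ResidueLookupError(
                    f"pair {r.receptor_res}/{r.chemokine_res}: receptor residue "
                    f"{rpos} not in chain {receptor_chain}"
                )
            interaction_atom(receptor.residue(key))  # validates atom presence
            r.receptor_key = key
        else:
            r.receptor_key = (receptor_chain or "A", rpos, "")
        if chemokine is not None:
            key = (chemokine_chain, cpos, "")
            if not chemokine.has_residue(key):
                raise ResidueLookupError(
                    f"pair {r.receptor_res}/{r.chemokine_res}: chemokine residue "
                    f"{cpos} not in chain {chemokine_chain}"
                )
            interaction_atom(chemokine.residue(key))
            r.chemokine_key = key
        else:
            r.chemokine_key = (chemokine_chain or "B", cpos, "")
    rs.cn_weight = cn_weight
    return rs


def total_restraint_energy(model: StructureModel, rs: RestraintSet) -> float:
    """cn_weight-scaled sum of restraint penalties over a posed complex."""
    total = 0.0
    for r in rs:
        d = pair_distance(model, r.receptor_key, r.chemokine_key)
        total += restraint_energy(d, r)
    return rs.cn_weight * total


def write_restraints(rs: RestraintSet, path) -> None:
    """Serialize a restraint set as a tab-delimited table."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "receptor_res": r.receptor_res,
                "chemokine_res": r.chemokine_res,
                "weight": r.weight,
                "d0": r.d0,
                "lambda": r.lam,
            }
            for r in rs
        ]
    ).to_csv(path, sep="\t", index=False)
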