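"""Quantification of pairwise disulfide cross-linking efficiencies.

Cells co-expressing a cysteine-substituted receptor and a cysteine-substituted
chemokine form a covalent complex when the two engineered cysteines are close
enough to form a disulfide; the surface-retained chemokine is detected by flow
cytometry via its epitope tag. The live-population geometric mean fluorescence
intensity (GMFI) of each pair is expressed as a percentage of a reference
covalent pair measured in the same replicate (the reference is set to 100%),
and replicate percentages are averaged. Values above 100% are legitimate and
are not clamped.

Chemokine mutants that fail to fold export poorly; a display control on an
unrelated scavenger receptor (ACKR3-type) flags such mutants, and every pair
involving a flagged mutant is excluded from restraint building downstream.

Mutant identifiers follow the ``G3C`` convention: wild-type residue letter,
author sequence number, substituted residue letter.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import EmptyInputError, XlgeomError

__all__ = [
    "EfficiencyTable",
    "BlotQuant",
    "parse_mutant",
    "normalize_efficiency",
    "flag_misfolded",
    "western_quant",
    "enumerate_pairs",
    "concordance",
]

MEASURED = "measured"
NOT_STUDIED = "not_studied"
MISFOLDED_PARTNER = "misfolded_partner"

_MUTANT_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


def parse_mutant(mutant: str) -> tuple[str, int, str]:
    """Split ``'G3C'`` into (wild-type residue, position, substitution)."""
    m = _MUTANT_RE.match(mutant.strip())
    if not m:
        raise XlgeomError(f"cannot parse mutant id {mutant!r}")
    return m.group(1).upper(), int(m.group(2)), m.group(3).upper()


@dataclass
class EfficiencyTable:
    """Receptor-residue x chemokine-residue cross-linking efficiency matrix.

    ``efficiency``/``sem`` are % of the control pair; ``n`` counts replicates;
    ``status`` distinguishes measured cells from not-studied ones and from
    pairs invalidated by a misfolded partner. All four frames share the same
    index (receptor mutants) and columns (chemokine mutants).
    """

    efficiency: pd.DataFrame
    sem: pd.DataFrame
    n: pd.DataFrame
    status: pd.DataFrame
    control_pair: tuple[str, str] | None = None
    misfolded: set = field(default_factory=set)

    def measured_pairs(self, exclude_control: bool = True) -> pd.DataFrame:
        """Long-format table of measured, non-misfolded cells.

        The control pair defines the 100% reference and is not part of the
        mutagenesis panel; by default it is excluded.
        """
        rows = []
        for r in self.efficiency.index:
            for c in self.efficiency.columns:
                if exclude_control and self.control_pair == (r, c):
                    continue
                if self.status.loc[r, c] == MEASURED:
                    rows.append(
                        {
                            "receptor": r,
                            "chemokine": c,
                            "efficiency": self.efficiency.loc[r, c],
                            "sem": self.sem.loc[r, c],
                            "n": self.n.loc[r, c],
                        }
                    )
        return pd.DataFrame(rows, columns=["receptor", "chemokine", "efficiency", "sem", "n"])

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "EfficiencyTable":
        """Build a table from long-format rows (receptor, chemokine, efficiency
        [, sem, n, status]); cells absent from the rows are not_studied."""
        receptors = sorted(df["receptor"].unique(), key=lambda m: parse_mutant(m)[1])
        chemokines = sorted(df["chemokine"].unique(), key=lambda m: parse_mutant(m)[1])
        shape = (len(receptors), len(chemokines))
        eff = pd.DataFrame(np.full(shape, np.nan), index=receptors, columns=chemokines)
        sem = eff.copy()
        n = pd.DataFrame(np.zeros(shape, dtype=int), index=receptors, columns=chemokines)
        status = pd.DataFrame(NOT_STUDIED, index=receptors, columns=chemokines)
        for row in df.itertuples():
            eff.loc[row.receptor, row.chemokine] = row.efficiency
            sem.loc[row.receptor, row.chemokine] = getattr(row, "sem", np.nan)
            n.loc[row.receptor, row.chemokine] = int(getattr(row, "n", 1))
            status.loc[row.receptor, row.chemokine] = getattr(row, "status", MEASURED)
        return cls(eff, sem, n, status)

    def apply_misfolded(self, mutants) -> "EfficiencyTable":
        """Mark every cell involving a misfolded mutant as invalid."""
        status = self.status.copy()
        for m in mutants:
            if m in status.index:
                status.loc[m, :] = MISFOLDED_PARTNER
            if m in status.columns:
                status.loc[:, m] = MISFOLDED_PARTNER
        return EfficiencyTable(
            self.efficiency, self.sem, self.n, status,
            self.control_pair, set(self.misfolded) | set(mutants),
        )


def normalize_efficiency(records: pd.DataFrame) -> EfficiencyTable:
    """Build an :class:`EfficiencyTable` from raw per-replicate GMFI records.

    ``records`` columns: receptor_mutant, chemokine_mutant, replicate, gmfi,
    is_control. Within each replicate the control pair's GMFI defines 100%;
    each pair's efficiency is the mean over replicates of its per-replicate
    percentage (mean of ratios, not ratio of means), with SEM and n.

    A replicate lacking a control measurement is rejected with an error
    naming it.
    """
    required = {"receptor_mutant", "chemokine_mutant", "replicate", "gmfi", "is_control"}
    missing = required - set(records.columns)
    if missing:
        raise XlgeomError(f"records missing columns: {sorted(missing)}")
    if records.empty:
        raise EmptyInputError("no GMFI records")
    if (records["gmfi"] < 0).any():
        raise XlgeomError("negative GMFI values")
    controls = records[records["is_control"].astype(bool)]
    if controls.empty:
        raise XlgeomError("no control pair present in any replicate")
    ctrl_ids = controls[["receptor_mutant", "chemokine_mutant"]].drop_duplicates()
    if len(ctrl_ids) != 1:
        raise XlgeomError(
            f"expected exactly one control pair identity, found {len(ctrl_ids)}"
        )
    control_pair = tuple(ctrl_ids.iloc[0])
    ctrl_by_rep = controls.set_index("replicate")["gmfi"]
    bad = sorted(set(records["replicate"]) - set(ctrl_by_rep.index))
    if bad:
        raise XlgeomError(f"replicate batch(es) without control measurement: {bad}")

    work = records.copy()
    work["ratio_pct"] = 100.0 * work["gmfi"] / work["replicate"].map(ctrl_by_rep)
    grouped = work.groupby(["receptor_mutant", "chemokine_mutant"])["ratio_pct"]
    mean = grouped.mean()
    sem = grouped.sem()  # SEM over replicate percentages (ddof=1); NaN for n=1
    n = grouped.count()

    receptors = sorted(work["receptor_mutant"].unique(), key=lambda m: parse_mutant(m)[1])
    chemokines = sorted(work["chemokine_mutant"].unique(), key=lambda m: parse_mutant(m)[1])
    shape = (len(receptors), len(chemokines))
    eff = pd.DataFrame(np.full(shape, np.nan), index=receptors, columns=chemokines)
    sem_df = eff.copy()
    n_df = pd.DataFrame(np.zeros(shape, dtype=int), index=receptors, columns=chemokines)
    status = pd.DataFrame(NOT_STUDIED, index=receptors, columns=chemokines)
    for (r, c), v in mean.items():
        eff.loc[r, c] = v
        sem_df.loc[r, c] = sem.loc[(r, c)]
        n_df.loc[r, c] = int(n.loc[(r, c)])
        status.loc[r, c] = MEASURED
    return EfficiencyTable(eff, sem_df, n_df, status, control_pair=control_pair)


def flag_misfolded(
    chemokine_mutant: str,
    ackr3_display_pct: float | None,
    threshold: float = 20.0,
) -> str:
    """QC status of a chemokine mutant from its scavenger-receptor display level.

    ``ackr3_display_pct`` is surface display normalized to the wild-type
    chemokine (100%). Below ``threshold`` (default 20%) the mutant is judged
    misfolded/export-deficient; without a control measurement the status is
    unknown (with a warning).
    """
    if ackr3_display_pct is None or not np.isfinite(ackr3_display_pct):
        warnings.warn(f"{chemokine_mutant}: no display control; folding status unknown")
        return "unknown"
    return "misfolded" if ackr3_display_pct < threshold else "ok"


@dataclass
class BlotQuant:
    """Western-blot quantitation for one receptor-chemokine pair lane."""

    pair_id: str
    ha_ir800: float
    flag_ir680_upper: float
    flag_ir680_total: float
    efficiency_wb: float | None = None
    fraction_crosslinked: float | None = None


def western_quant(bands: list[BlotQuant], control_pair_id: str) -> list[BlotQuant]:
    """Quantify crosslinking from blot band intensities measured on one blot.

    Efficiency is the chemokine-channel (IR800) band intensity as % of the
    control pair's on the same blot; the fraction of receptor crosslinked is
    the crosslinked-receptor (upper) band over total receptor signal in the
    receptor channel (IR680).
    """
    ctrl = [b for b in bands if b.pair_id == control_pair_id]
    if not ctrl:
        raise XlgeomError(f"control pair {control_pair_id!r} not on this blot")
    ctrl_ha = ctrl[0].ha_ir800
    if ctrl_ha <= 0:
        raise XlgeomError("control chemokine band intensity must be positive")
    out = []
    for b in bands:
        if min(b.ha_ir800, b.flag_ir680_upper, b.flag_ir680_total) < 0:
            raise XlgeomError(f"lane {b.pair_id}: negative band intensity")
        if b.flag_ir680_total == 0:
            raise XlgeomError(f"lane {b.pair_id}: zero total receptor intensity")
        frac = b.flag_ir680_upper / b.flag_ir680_total
        if frac > 1:
            raise XlgeomError(f"lane {b.pair_id}: upper band exceeds total receptor signal")
        out.append(
            BlotQuant(
                pair_id=b.pair_id,
                ha_ir800=b.ha_ir800,
                flag_ir680_upper=b.flag_ir680_upper,
                flag_ir680_total=b.flag_ir680_total,
                efficiency_wb=100.0 * b.ha_ir800 / ctrl_ha,
                fraction_crosslinked=frac,
            )
        )
    return out


def enumerate_pairs(receptor_residues, chemokine_residues):
    """Cartesian product of candidate receptor and chemokine positions.

    Returns ``(count, pairs)`` where count = |receptor| x |chemokine|.
    """
    receptor_residues = list(receptor_residues)
    chemokine_residues = list(chemokine_residues)
    if not receptor_residues or not chemokine_residues:
        raise EmptyInputError("both residue lists must be nonempty")
    pairs = [(r, c) for r in receptor_residues for c in chemokine_residues]
    return len(pairs), pairs


def concordance(flow: EfficiencyTable, wb: list[BlotQuant]) -> tuple[pd.DataFrame, float]:
    """Flow-vs-Western agreement over shared pairs (Spearman rank correlation).

    Blot ``pair_id`` follows ``'receptor/chemokine'`` using the same mutant
    identifiers as the flow table.
    """
    rows = []
    for b in wb:
        if b.efficiency_wb is None:
            raise XlgeomError("run western_quant before concordance")
        try:
            r, c = b.pair_id.split("/")
        except ValueError:
            raise XlgeomError(f"pair id {b.pair_id!r} not in 'receptor/chemokine' form")
        if (r, c) == flow.control_pair:
            continue  # the 100% reference anchors both scales; not a data point
        if r in flow.efficiency.index and c in flow.efficiency.columns:
            if flow.status.loc[r, c] == MEASURED:
                rows.append(
                    {
                        "pair": b.pair_id,
                        "flow_efficiency": flow.efficiency.loc[r, c],
                        "wb_efficiency": b.efficiency_wb,
                    }
                )
    paired = pd.DataFrame(rows, columns=["pair", "flow_efficiency", "wb_efficiency"])
    if len(paired) < 3:
        raise EmptyInputError(f"only {len(paired)} shared pairs; need >= 3")
    rho = spearmanr(paired["flow_efficiency"], paired["wb_efficiency"]).statistic
    return paired, float(rho)
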