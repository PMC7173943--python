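"""Benchmarking complex geometries against crosslinking data.

Any candidate model of the receptor-chemokine complex can be scored by how
well its short inter-residue distances identify the strongest experimental
crosslinks: the Cβ–Cβ (Cα for Gly) distance map over the mutagenesis panel
is computed, the measured pairs are split into positives (the top fraction
by crosslinking efficiency) and negatives, each pair is scored by its
negated model distance, and a receiver operating characteristic (ROC) curve
with its area (AUC) summarizes the concordance. Pairs whose residues are
absent from a model are excluded from that model's ROC rather than scored
as failures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import EmptyInputError, XlgeomError
from .struct_io import StructureModel, pair_distance
from .xlink_quant import MEASURED, EfficiencyTable, parse_mutant

__all__ = [
    "DistanceMatrix",
    "RocResult",
    "distance_map",
    "top_positives",
    "roc_benchmark",
    "compare_models",
]


@dataclass
class DistanceMatrix:
    """Receptor-residue x chemokine-residue interaction-atom distances (Å).

    Missing residues give NaN entries; ``missing`` lists them explicitly.
    """

    distances: pd.DataFrame
    model_id: str
    missing: list[tuple[str, str]]

    def lookup(self, receptor: str, chemokine: str) -> float:
        return float(self.distances.loc[receptor, chemokine])


@dataclass
class RocResult:
    fraction: float
    n_positives: int
    n_negatives: int
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    excluded_pairs: list[tuple[str, str]]
    model_id: str = ""

    def __post_init__(self):
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC outside [0, 1]")


def _position_of(mutant_or_pos) -> int:
    if isinstance(mutant_or_pos, (int, np.integer)):
        return int(mutant_or_pos)
    return parse_mutant(str(mutant_or_pos))[1]


def distance_map(
    model: StructureModel,
    receptor_residues,
    chemokine_residues,
    receptor_chain: str | None = None,
    chemokine_chain: str | None = None,
) -> DistanceMatrix:
    """Cβ–Cβ (Cα for Gly) distance matrix over a residue panel.

    Residue lists may hold author positions or mutant ids (``'G3C'``); the
    labels are preserved as matrix index/columns. Residues not present in
    the model yield NaN entries, reported in ``missing``.
    """
    rc = receptor_chain or (model.chains_with_role("receptor") or [None])[0]
    cc = chemokine_chain or (model.chains_with_role("chemokine") or [None])[0]
    if rc is None or cc is None:
        raise XlgeomError("model needs receptor and chemokine chain roles")
    rows = [str(r) for r in receptor_residues]
    cols = [str(c) for c in chemokine_residues]
    mat = pd.DataFrame(np.nan, index=rows, columns=cols)
    missing = []
    for r, rl in zip(receptor_residues, rows):
        for c, cl in zip(chemokine_residues, cols):
            rkey = (rc, _position_of(r), "")
            ckey = (cc, _position_of(c), "")
            if model.has_residue(rkey) and model.has_residue(ckey):
                mat.loc[rl, cl] = pair_distance(model, rkey, ckey)
            else:
                missing.append((rl, cl))
    return DistanceMatrix(distances=mat, model_id=model.model_id, missing=missing)


def top_positives(
    table: EfficiencyTable,
    fraction: float,
    rounding: str = "round",
) -> tuple[set[tuple[str, str]], int]:
    """The top fraction of measured crosslinks, ranked by efficiency.

    The nominal count is ``fraction x n_measured`` rounded half-up
    (``rounding='floor'`` truncates instead); efficiency ties at the
    boundary are all included and the realized count returned. Misfolded
    and not-studied cells never enter the ranking.
    """
    if not 0.0 < fraction <= 1.0:
        raise XlgeomError("fraction must be in (0, 1]")
    measured = table.measured_pairs()
    if measured.empty:
        raise EmptyInputError("no measured pairs in efficiency table")
    n = len(measured)
    if rounding == "round":
        count = int(math.floor(fraction * n + 0.5))
    elif rounding == "floor":
        count = int(math.floor(fraction * n))
    else:
        raise XlgeomError(f"unknown rounding {rounding!r}")
    count = max(count, 1)
    ranked = measured.sort_values(
        ["efficiency", "receptor", "chemokine"], ascending=[False, True, True]
    )
    if count >= n:
        chosen = ranked
    else:
        boundary = ranked.iloc[count - 1]["efficiency"]
        chosen = ranked[ranked["efficiency"] >= boundary]  # tie expansion
    pairs = {(row.receptor, row.chemokine) for row in chosen.itertuples()}
    return pairs, len(pairs)


def roc_benchmark(
    dm: DistanceMatrix,
    table: EfficiencyTable,
    fraction: float,
    rounding: str = "round",
) -> RocResult:
    """ROC of a model's distances against the top-fraction crosslink positives.

    Measured pairs are labeled positive if in the top fraction by efficiency;
    each pair is scored by its negated model distance, so short distances
    rank first. Pairs without a finite model distance are excluded and
    reported. AUC is the trapezoidal area under the threshold-swept curve.
    """
    positives, _ = top_positives(table, fraction, rounding)
    measured = table.measured_pairs()
    labels, scores, excluded = [], [], []
    for row in measured.itertuples():
        pair = (row.receptor, row.chemokine)
        try:
            d = dm.lookup(row.receptor, row.chemokine)
        except KeyError:
            excluded.append(pair)
            continue
        if not np.isfinite(d):
            excluded.append(pair)
            continue
        labels.append(pair in positives)
        scores.append(-d)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise XlgeomError(
            f"undefined AUC: {n_pos} positives and {n_neg} negatives with finite distances"
        )
    fpr, tpr, _ = _sk_roc_curve(labels, np.asarray(scores))
    return RocResult(
        fraction=fraction,
        n_positives=n_pos,
        n_negatives=n_neg,
        fpr=fpr,
        tpr=tpr,
        auc=float(_sk_auc(fpr, tpr)),
        excluded_pairs=excluded,
        model_id=dm.model_id,
    )


def compare_models(
    models: list[StructureModel],
    table: EfficiencyTable,
    fractions=(0.10, 0.25, 0.50),
    receptor_residues=None,
    chemokine_residues=None,
    rounding: str = "round",
) -> pd.DataFrame:
    """AUC per model per positive fraction, with per-fraction ranks.

    The residue panel defaults to the table's rows/columns. Returns a tidy
    DataFrame (model, fraction, n_positives, auc, rank) where rank 1 is the
    best AUC at that fraction.
    """
    if len(models) < 2:
        raise XlgeomError("need >= 2 models to compare")
    receptor_residues = list(receptor_residues or table.efficiency.index)
    chemokine_residues = list(chemokine_residues or table.efficiency.columns)
    rows = []
    for model in models:
        dm = distance_map(model, receptor_residues, chemokine_residues)
        for frac in fractions:
            roc = roc_benchmark(dm, table, frac, rounding)
            rows.append(
                {
                    "model": model.model_id,
                    "fraction": frac,
                    "n_positives": roc.n_positives,
                    "auc": roc.auc,
                }
            )
    report = pd.DataFrame(rows)
    report["rank"] = (
        report.groupby("fraction")["auc"].rank(ascending=False, method="min").astype(int)
    )
    return report.sort_values(["fraction", "rank"]).reset_index(drop=True)
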