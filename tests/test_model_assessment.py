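"""Distance maps and the top-X% ROC benchmark."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_model, make_residue
from xlgeom.errors import EmptyInputError, XlgeomError
from xlgeom.model_assessment import (
    DistanceMatrix,
    compare_models,
    distance_map,
    roc_benchmark,
    top_positives,
)
from xlgeom.xlink_quant import EfficiencyTable


def table_from(pairs):
    rows = [
        {"receptor": r, "chemokine": c, "efficiency": e} for (r, c), e in pairs.items()
    ]
    return EfficiencyTable.from_long(pd.DataFrame(rows))


def dm_from(values, model_id="m"):
    """values: {(receptor, chemokine): distance}; NaN for missing."""
    receptors = sorted({r for r, _ in values}, key=lambda m: int(m[1:-1]))
    chems = sorted({c for _, c in values}, key=lambda m: int(m[1:-1]))
    mat = pd.DataFrame(np.nan, index=receptors, columns=chems)
    for (r, c), d in values.items():
        mat.loc[r, c] = d
    missing = [(r, c) for r in receptors for c in chems if not np.isfinite(mat.loc[r, c])]
    return DistanceMatrix(distances=mat, model_id=model_id, missing=missing)


class TestDistanceMap:
    def test_hand_computed_two_by_two(self):
        residues = [
            make_residue("A", 1, "ALA", {"CA": (0, 0, 0), "CB": (0, 0, 0)}),
            make_residue("A", 2, "ALA", {"CA": (1, 0, 0), "CB": (3, 0, 0)}),
            make_residue("B", 10, "ALA", {"CA": (0, 4, 0), "CB": (0, 4, 0)}),
            make_residue("B", 11, "ALA", {"CA": (3, 4, 0), "CB": (3, 4, 0)}),
        ]
        model = make_model(residues, roles={"A": "receptor", "B": "chemokine"})
        dm = distance_map(model, ["A1C", "A2C"], ["A10C", "A11C"])
        assert dm.distances.loc["A1C", "A10C"] == pytest.approx(4.0)
        assert dm.distances.loc["A1C", "A11C"] == pytest.approx(5.0)
        assert dm.distances.loc["A2C", "A10C"] == pytest.approx(5.0)
        assert dm.distances.loc["A2C", "A11C"] == pytest.approx(4.0)

    def test_coincident_atoms_give_zero(self):
        residues = [
            make_residue("A", 1, "ALA", {"CA": (0, 0, 0), "CB": (1, 1, 1)}),
            make_residue("B", 2, "ALA", {"CA": (5, 5, 5), "CB": (1, 1, 1)}),
        ]
        model = make_model(residues, roles={"A": "receptor", "B": "chemokine"})
        dm = distance_map(model, ["A1C"], ["A2C"])
        assert dm.distances.loc["A1C", "A2C"] == 0.0

    def test_unmodeled_residue_is_missing_not_zero(self, toy):
        dm = distance_map(toy.complex_model(), ["G1C", "G99C"], ["H25C"])
        assert np.isnan(dm.distances.loc["G99C", "H25C"])
        assert ("G99C", "H25C") in dm.missing
        assert np.isfinite(dm.distances.loc["G1C", "H25C"])


class TestTopPositives:
    def _table(self, n, start=10.0):
        return table_from(
            {(f"G{i+1}C", "K27C"): start + i for i in range(n)}
        )

    def test_half_of_ten_is_five(self):
        pairs, count = top_positives(self._table(10), 0.5)
        assert count == 5
        assert all(int(r[1:-1]) >= 6 for r, _ in pairs)  # five highest efficiencies

    def test_fraction_one_takes_all(self):
        pairs, count = top_positives(self._table(10), 1.0)
        assert count == 10

    def test_boundary_ties_all_included_and_reported(self):
        table = table_from(
            {("G1C", "K27C"): 50.0, ("G2C", "K27C"): 80.0,
             ("G3C", "K27C"): 80.0, ("G4C", "K27C"): 90.0}
        )
        pairs, count = top_positives(table, 0.5)
        assert count == 3  # nominal 2, expanded by the 80% tie
        assert ("G2C", "K27C") in pairs and ("G3C", "K27C") in pairs

    def test_round_vs_floor_counts(self):
        table = self._table(14)  # 10% of 14 = 1.4
        _, n_round = top_positives(table, 0.10, rounding="round")
        _, n_floor = top_positives(table, 0.10, rounding="floor")
        assert (n_round, n_floor) == (1, 1)
        table = self._table(15)  # 10% of 15 = 1.5 -> round half up
        _, n_round = top_positives(table, 0.10, rounding="round")
        _, n_floor = top_positives(table, 0.10, rounding="floor")
        assert (n_round, n_floor) == (2, 1)

    def test_empty_table_rejected(self):
        empty = table_from({("G1C", "K27C"): 50.0})
        empty.status.loc["G1C", "K27C"] = "not_studied"
        with pytest.raises(EmptyInputError):
            top_positives(empty, 0.5)


def brute_force_auc(scores, labels):
    """Mann-Whitney probability: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocBenchmark:
    def test_perfectly_concordant_distances_auc_one(self):
        effs = {(f"G{i+1}C", "K27C"): 100.0 - 10 * i for i in range(8)}
        dists = {(f"G{i+1}C", "K27C"): 3.0 + i for i in range(8)}
        roc = roc_benchmark(dm_from(dists), table_from(effs), 0.25)
        assert roc.auc == pytest.approx(1.0)

    def test_reversed_distances_auc_zero(self):
        effs = {(f"G{i+1}C", "K27C"): 100.0 - 10 * i for i in range(8)}
        dists = {(f"G{i+1}C", "K27C"): 20.0 - i for i in range(8)}
        roc = roc_benchmark(dm_from(dists), table_from(effs), 0.25)
        assert roc.auc == pytest.approx(0.0)

    def test_random_distances_auc_near_half(self):
        rng = np.random.default_rng(5)
        n = 400
        effs = {(f"G{i+1}C", "K27C"): float(100 - 0.1 * i) for i in range(n)}
        dists = {(f"G{i+1}C", "K27C"): float(rng.uniform(3, 30)) for i in range(n)}
        roc = roc_benchmark(dm_from(dists), table_from(effs), 0.5)
        assert roc.auc == pytest.approx(0.5, abs=0.08)

    @given(
        dists=st.lists(
            st.integers(min_value=3, max_value=12), min_size=4, max_size=20
        ),
        frac=st.sampled_from([0.1, 0.25, 0.5]),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_mann_whitney_oracle_exhaustively(self, dists, frac):
        n = len(dists)
        effs = {(f"G{i+1}C", "K27C"): 130.0 - 7.0 * i for i in range(n)}
        dvals = {(f"G{i+1}C", "K27C"): float(d) for i, d in enumerate(dists)}
        table = table_from(effs)
        positives, count = top_positives(table, frac)
        if count == n:
            return  # degenerate: no negatives
        roc = roc_benchmark(dm_from(dvals), table, frac)
        labels = [(f"G{i+1}C", "K27C") in positives for i in range(n)]
        scores = [-dvals[(f"G{i+1}C", "K27C")] for i in range(n)]
        assert roc.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_distance_transform(self):
        rng = np.random.default_rng(7)
        effs = {(f"G{i+1}C", "K27C"): float(rng.uniform(10, 130)) for i in range(12)}
        dists = {k: float(rng.uniform(3, 25)) for k in effs}
        base = roc_benchmark(dm_from(dists), table_from(effs), 0.25).auc
        warped = {k: float(np.exp(0.3 * v)) for k, v in dists.items()}
        assert roc_benchmark(dm_from(warped), table_from(effs), 0.25).auc == pytest.approx(base)

    def test_auc_of_negated_map_complements(self):
        rng = np.random.default_rng(9)
        effs = {(f"G{i+1}C", "K27C"): float(rng.uniform(10, 130)) for i in range(15)}
        dists = {k: float(rng.uniform(3, 25)) for k in effs}
        a = roc_benchmark(dm_from(dists), table_from(effs), 0.25).auc
        neg = {k: 100.0 - v for k, v in dists.items()}
        b = roc_benchmark(dm_from(neg), table_from(effs), 0.25).auc
        assert a + b == pytest.approx(1.0)

    def test_missing_pairs_excluded_and_reported(self):
        effs = {(f"G{i+1}C", "K27C"): 100.0 - 10 * i for i in range(8)}
        dists = {(f"G{i+1}C", "K27C"): 3.0 + i for i in range(8)}
        dists[("G8C", "K27C")] = np.nan
        roc = roc_benchmark(dm_from(dists), table_from(effs), 0.25)
        assert ("G8C", "K27C") in roc.excluded_pairs
        assert roc.n_positives + roc.n_negatives == 7

    def test_all_positive_is_undefined(self):
        effs = {("G1C", "K27C"): 100.0, ("G2C", "K27C"): 100.0}
        dists = {("G1C", "K27C"): 4.0, ("G2C", "K27C"): 5.0}
        with pytest.raises(XlgeomError, match="undefined AUC"):
            roc_benchmark(dm_from(dists), table_from(effs), 1.0)


class TestCompareModels:
    def test_model_vs_itself_identical_aucs(self, toy, spec):
        from xlgeom.synthetic_data import simulate_efficiencies

        _, table, _ = simulate_efficiencies(toy.true_distances, spec, 3)
        m1 = toy.complex_model()
        m2 = toy.complex_model()
        m2.model_id = "copy"
        report = compare_models([m1, m2], table, fractions=(0.25,))
        aucs = report.set_index("model")["auc"]
        assert aucs["toy_true"] == pytest.approx(aucs["copy"])

    def test_true_model_beats_displaced_decoy(self, toy, spec):
        from xlgeom.synthetic_data import simulate_efficiencies
        from xlgeom.peptide_sampler import combine_models

        _, table, _ = simulate_efficiencies(toy.true_distances, spec, 3)
        decoy_pep = toy.planted_pose.transformed(np.eye(3), np.array([10.0, 0.0, 0.0]))
        decoy_pep.model_id = "decoy_pose"
        decoy = combine_models(decoy_pep, toy.scaffold, model_id="decoy")
        report = compare_models(
            [toy.complex_model(), decoy], table, fractions=(0.10, 0.25, 0.50)
        )
        for frac in (0.10, 0.25, 0.50):
            sub = report[report["fraction"] == frac].set_index("model")["auc"]
            assert sub["toy_true"] > sub["decoy"]

    def test_input_order_does_not_change_aucs(self, toy, spec):
        from xlgeom.synthetic_data import simulate_efficiencies
        from xlgeom.peptide_sampler import combine_models

        _, table, _ = simulate_efficiencies(toy.true_distances, spec, 3)
        decoy_pep = toy.planted_pose.transformed(np.eye(3), np.array([8.0, 0.0, 0.0]))
        decoy = combine_models(decoy_pep, toy.scaffold, model_id="decoy")
        a = compare_models([toy.complex_model(), decoy], table, fractions=(0.25,))
        b = compare_models([decoy, toy.complex_model()], table, fractions=(0.25,))
        av = a.set_index("model")["auc"]
        bv = b.set_index("model")["auc"]
        assert av["toy_true"] == pytest.approx(bv["toy_true"])
        assert av["decoy"] == pytest.approx(bv["decoy"])
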