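import numpy as np
import pytest

from srmf.datamodel import Direction, ResponseMatrix, SrmfConfig
from srmf.evaluation import (
    UndefinedMetricError,
    cross_validate,
    default_lambda_grid,
    evaluate,
    grid_search,
    kfold_entries,
    pcc_per_drug,
    relative_improvement,
    rmse_per_drug,
    sensitive_resistant_split,
)
from srmf.factorization import fit, predict
from srmf.simulation import SimulationConfig, simulate_instance


class TestPerDrugMetrics:
    def test_rmse_examples(self):
        assert rmse_per_drug([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse_per_drug([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(25 / 2))
        x = np.array([0.3, -1.2, 4.0])
        assert rmse_per_drug(x, x + 0.7) == pytest.approx(0.7)

    def test_rmse_empty_errors(self):
        with pytest.raises(ValueError):
            rmse_per_drug([], [])

    def test_rmse_triangle_bound(self, rng):
        a, b, c = rng.standard_normal((3, 30))
        assert rmse_per_drug(a, c) <= rmse_per_drug(a, b) + rmse_per_drug(b, c) + 1e-12

    def test_pcc_examples(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pcc_per_drug(x, 2 * x + 1) == pytest.approx(1.0)
        assert pcc_per_drug(x, -x) == pytest.approx(-1.0)
        assert pcc_per_drug(x, [1.0, 2.0, 4.0]) == pytest.approx(0.98198, abs=1e-5)

    def test_pcc_undefined_cases(self):
        with pytest.raises(UndefinedMetricError):
            pcc_per_drug([1.0, 2.0], [1.0, 2.0])  # fewer than 3 cells
        with pytest.raises(UndefinedMetricError):
            pcc_per_drug([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])  # zero variance


class TestSensitiveResistantSplit:
    def _resp(self, values, direction=Direction.LOWER_IS_SENSITIVE):
        values = np.asarray(values, dtype=float)[None, :]
        return ResponseMatrix(
            ["d"], [f"c{j}" for j in range(values.shape[1])], values, direction=direction
        )

    def test_first_and_fourth_quartiles_at_n8(self):
        R = self._resp(range(1, 9))
        sens, res = sensitive_resistant_split(R, "d")
        # Q1 = 2.75, Q3 = 6.25 under linear interpolation
        assert sens == ["c0", "c1"] and res == ["c6", "c7"]

    def test_direction_flip_swaps_groups(self):
        lo = self._resp(range(1, 9))
        hi = self._resp(range(1, 9), Direction.HIGHER_IS_SENSITIVE)
        s1, r1 = sensitive_resistant_split(lo, "d")
        s2, r2 = sensitive_resistant_split(hi, "d")
        assert (s1, r1) == (r2, s2)
        assert set(s1) | set(r1) == set(s2) | set(r2)

    def test_constant_values_excluded(self):
        with pytest.raises(UndefinedMetricError, match="quartile"):
            sensitive_resistant_split(self._resp([2.0] * 8), "d")

    def test_too_few_cells_excluded(self):
        with pytest.raises(UndefinedMetricError, match=">= 8"):
            sensitive_resistant_split(self._resp(range(5)), "d")


def naive_report_oracle(R, pred, heldout):
    """Independent per-drug loop re-implementation of evaluate."""
    import math

    out = {}
    for i, drug in enumerate(R.drug_ids):
        cols = sorted(j for (a, j) in heldout if a == i)
        if not cols:
            continue
        o = [R.values[i, j] for j in cols]
        p = [pred[i, j] for j in cols]
        n = len(o)
        rmse = math.sqrt(sum((a - b) ** 2 for a, b in zip(o, p)) / n)
        pcc = float("nan")
        if n >= 3:
            mo, mp = sum(o) / n, sum(p) / n
            so = math.sqrt(sum((a - mo) ** 2 for a in o))
            sp = math.sqrt(sum((b - mp) ** 2 for b in p))
            if so > 0 and sp > 0:
                pcc = sum((a - mo) * (b - mp) for a, b in zip(o, p)) / (so * sp)
        out[drug] = (pcc, rmse)
    return out


class TestEvaluate:
    def test_perfect_prediction(self, small_response):
        heldout = [tuple(e) for e in small_response.observed_entries()]
        rep = evaluate(small_response, np.nan_to_num(small_response.values), heldout)
        assert np.allclose(rep.per_drug["rmse"], 0.0)
        defined = rep.per_drug["pcc"].dropna()
        assert np.allclose(defined, 1.0)

    def test_matches_naive_loop_oracle(self, rng):
        m, n = 5, 20
        values = rng.standard_normal((m, n))
        values[rng.random((m, n)) < 0.2] = np.nan
        R = ResponseMatrix([f"d{i}" for i in range(m)], [f"c{j}" for j in range(n)], values)
        pred = rng.standard_normal((m, n))
        heldout = [tuple(e) for e in R.observed_entries() if rng.random() < 0.6]
        rep = evaluate(R, pred, heldout)
        oracle = naive_report_oracle(R, pred, heldout)
        for drug, (pcc, rmse) in oracle.items():
            assert rep.per_drug.loc[drug, "rmse"] == pytest.approx(rmse, abs=1e-12)
            if np.isnan(pcc):
                assert np.isnan(rep.per_drug.loc[drug, "pcc"])
            else:
                assert rep.per_drug.loc[drug, "pcc"] == pytest.approx(pcc, abs=1e-12)

    def test_drug_averaged_equals_column_means(self, rng):
        m, n = 6, 15
        values = rng.standard_normal((m, n))
        R = ResponseMatrix([f"d{i}" for i in range(m)], [f"c{j}" for j in range(n)], values)
        pred = values + 0.1 * rng.standard_normal((m, n))
        rep = evaluate(R, pred, [tuple(e) for e in R.observed_entries()])
        for col in ("pcc", "rmse", "pcc_sr", "rmse_sr"):
            assert rep.drug_averaged[col] == pytest.approx(
                float(np.nanmean(rep.per_drug[col])), abs=1e-15
            )

    def test_cell_permutation_invariance(self, rng):
        m, n = 4, 12
        values = rng.standard_normal((m, n))
        R1 = ResponseMatrix([f"d{i}" for i in range(m)], [f"c{j}" for j in range(n)], values)
        pred = rng.standard_normal((m, n))
        perm = rng.permutation(n)
        R2 = ResponseMatrix(R1.drug_ids, [R1.cell_ids[j] for j in perm], values[:, perm])
        rep1 = evaluate(R1, pred, [tuple(e) for e in R1.observed_entries()])
        rep2 = evaluate(R2, pred[:, perm], [tuple(e) for e in R2.observed_entries()])
        for col in ("pcc", "rmse", "pcc_sr", "rmse_sr"):
            assert rep1.drug_averaged[col] == pytest.approx(rep2.drug_averaged[col], abs=1e-12)

    def test_heldout_must_be_observed(self, small_response):
        missing = tuple(np.argwhere(small_response.mask == 0)[0])
        with pytest.raises(ValueError, match="not an observed"):
            evaluate(small_response, np.zeros(small_response.shape), [missing])

    def test_drug_without_heldout_is_counted(self, small_response):
        heldout = [(0, 0), (0, 1), (0, 3)]
        rep = evaluate(small_response, np.zeros(small_response.shape), heldout)
        assert rep.excluded["no_heldout"] == 3
        assert list(rep.per_drug.index) == ["d0"]


class TestKFold:
    def _resp(self, n_obs, rng):
        values = rng.standard_normal((10, 12))
        flat = rng.choice(values.size, size=values.size - n_obs, replace=False)
        values.flat[flat] = np.nan
        return ResponseMatrix([f"d{i}" for i in range(10)], [f"c{j}" for j in range(12)], values)

    def test_equal_fold_sizes(self, rng):
        R = self._resp(100, rng)
        folds = kfold_entries(R, 10, seed=1)
        sizes = [len(folds.fold_entries(f)) for f in range(1, 11)]
        assert sizes == [10] * 10

    def test_almost_equal_fold_sizes(self, rng):
        R = self._resp(101, rng)
        sizes = sorted(
            len(kfold_entries(R, 10, seed=1).fold_entries(f)) for f in range(1, 11)
        )
        assert sizes == [10] * 9 + [11]

    def test_deterministic_and_observed_only(self, rng):
        R = self._resp(90, rng)
        f1, f2 = kfold_entries(R, 7, seed=3), kfold_entries(R, 7, seed=3)
        assert np.array_equal(f1.fold_ids, f2.fold_ids)
        assert all(R.mask[i, j] == 1 for i, j in f1.entries)

    def test_k_larger_than_observed_errors(self, rng):
        R = self._resp(5, rng)
        with pytest.raises(ValueError, match="exceeds"):
            kfold_entries(R, 6)


class TestCrossValidate:
    def test_noiseless_recovery_small(self):
        inst = simulate_instance(
            SimulationConfig(m=25, n=30, k_true=3, noise_level=0.0, missing_fraction=0.0, seed=5)
        )
        cfg = SrmfConfig(K=3, lambda_l=0.02, lambda_d=0.01, lambda_c=0.01, max_iter=200)
        rep = cross_validate(inst.response, inst.Sd, inst.Sc, cfg, k=5, seed=2)
        assert rep.drug_averaged["pcc"] > 0.99

    def test_leave_one_entry_out_boundary(self):
        inst = simulate_instance(
            SimulationConfig(m=4, n=5, k_true=2, noise_level=0.0, missing_fraction=0.0, seed=1)
        )
        cfg = SrmfConfig(K=2, lambda_l=0.1, lambda_d=0.0, lambda_c=0.0, max_iter=30)
        rep = cross_validate(inst.response, None, None, cfg, k=20, seed=0)
        assert len(rep.per_drug) == 4

    def test_heldout_values_do_not_leak_into_training(self, tiny_instance, rng):
        from srmf.evaluation import _mask_entries

        R = tiny_instance.response
        ent = R.observed_entries()[:10]
        R1 = _mask_entries(R, ent)
        R2_vals = R.values.copy()
        R2_vals[ent[:, 0], ent[:, 1]] = 99.0  # arbitrary junk at held-out cells
        R2 = _mask_entries(
            ResponseMatrix(R.drug_ids, R.cell_ids, R2_vals, R.mask, R.direction), ent
        )
        cfg = SrmfConfig(K=3, lambda_l=0.1, lambda_d=0.0, lambda_c=0.1)
        p1 = predict(R1, fit(R1, None, tiny_instance.Sc, cfg)[0])
        p2 = predict(R2, fit(R2, None, tiny_instance.Sc, cfg)[0])
        assert np.array_equal(p1, p2)


class TestGridSearch:
    def test_single_point_grid(self, tiny_instance):
        cfg = SrmfConfig(K=3, max_iter=40)
        best, table = grid_search(
            tiny_instance.response, tiny_instance.Sd, tiny_instance.Sc,
            [(0.1, 0.0, 0.1)], cfg, k=3,
        )
        assert (best.lambda_l, best.lambda_d, best.lambda_c) == (0.1, 0.0, 0.1)
        assert len(table) == 1

    def test_selected_point_is_argmax(self, tiny_instance):
        cfg = SrmfConfig(K=3, max_iter=40)
        grid = [(0.1, 0.0, 0.1), (4.0, 0.0, 0.0), (0.05, 0.01, 0.05)]
        best, table = grid_search(
            tiny_instance.response, tiny_instance.Sd, tiny_instance.Sc, grid, cfg, k=3
        )
        best_row = table[
            (table.lambda_l == best.lambda_l)
            & (table.lambda_d == best.lambda_d)
            & (table.lambda_c == best.lambda_c)
        ]
        assert best_row["pcc"].iloc[0] >= table["pcc"].max() - 1e-15

    def test_default_grid_size(self):
        assert len(default_lambda_grid()) == 6 * 8 * 8

    def test_empty_grid_errors(self, tiny_instance):
        with pytest.raises(ValueError, match="empty"):
            grid_search(tiny_instance.response, None, None, [], SrmfConfig(K=3))


def test_relative_improvement_both_orientations():
    assert relative_improvement(0.71, 0.59) == pytest.approx(20.34, abs=0.005)
    assert relative_improvement(1.73, 2.00, higher_is_better=False) == pytest.approx(13.50, abs=0.005)
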