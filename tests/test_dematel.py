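"""DEMATEL normalization, total relation, marginals, classification."""

import numpy as np
import pandas as pd
import pytest

from hfrisk import (
    ConvergenceError,
    ValidationError,
    classify_cause_effect,
    load_fixture,
    normalize_direct_relation,
    relation_scores,
    run_dematel,
    total_relation,
)

from conftest import labeled


def series_oracle(d, k_max):
    """Truncated geometric series sum_{k=1..K} D^k (independent oracle)."""
    acc = np.zeros_like(d)
    power = np.eye(d.shape[0])
    for _ in range(k_max):
        power = power @ d
        acc += power
    return acc


class TestNormalize:
    def test_row_sums_already_one(self):
        z = labeled([[0, 1], [1, 0]])
        d = normalize_direct_relation(z)
        assert d.scale_constant == 1.0
        pd.testing.assert_frame_equal(d.matrix, z.astype(float))

    def test_max_row_sum_divisor(self):
        d = normalize_direct_relation(labeled([[0, 2], [4, 0]]))
        assert d.scale_constant == 4.0
        np.testing.assert_allclose(d.matrix.to_numpy(), [[0, 0.5], [1, 0]])

    def test_max_row_sum_of_result_is_one(self, random_direct_relation):
        d = normalize_direct_relation(random_direct_relation(7, seed=0))
        assert d.matrix.sum(axis=1).max() == pytest.approx(1.0)

    def test_scale_cancellation(self, random_direct_relation):
        z = random_direct_relation(5, seed=1)
        for c in (0.1, 3.0, 17.0):
            dc = normalize_direct_relation(z * c)
            d0 = normalize_direct_relation(z)
            np.testing.assert_allclose(dc.matrix.to_numpy(), d0.matrix.to_numpy())

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError, match="all-zero"):
            normalize_direct_relation(labeled(np.zeros((3, 3))))

    def test_column_variant_uses_larger_column_sum(self):
        # column ED2 collects 6 while the largest row sum is 3
        z = labeled([[0, 3, 0], [0, 0, 0], [0, 3, 0]])
        assert normalize_direct_relation(z).scale_constant == 3.0
        assert (
            normalize_direct_relation(z, include_columns=True).scale_constant == 6.0
        )


class TestTotalRelation:
    def test_null_matrix_fixed_point(self):
        res = total_relation(labeled(np.zeros((3, 3))))
        assert (res.T.to_numpy() == 0).all()
        assert (res.R == 0).all() and (res.C == 0).all()

    def test_2x2_antidiagonal_closed_form(self):
        # for D = [[0,a],[b,0]]: T = 1/(1-ab) * [[ab, a], [b, ab]]
        a = b = 0.5
        res = total_relation(labeled([[0, a], [b, 0]]))
        expected = np.array([[a * b, a], [b, a * b]]) / (1 - a * b)
        np.testing.assert_allclose(res.T.to_numpy(), expected, atol=1e-12)
        np.testing.assert_allclose(res.T.to_numpy(), [[1 / 3, 2 / 3], [2 / 3, 1 / 3]])

    def test_matches_truncated_series_oracle(self, random_direct_relation):
        for seed, n in [(0, 3), (1, 8), (2, 20)]:
            z = random_direct_relation(n, seed=seed)
            d = normalize_direct_relation(z).matrix.to_numpy()
            rho = np.max(np.abs(np.linalg.eigvals(d)))
            if rho >= 0.95:
                d = d * (0.9 / rho)
            res = total_relation(labeled(d))
            oracle = series_oracle(d, 200)
            assert np.max(np.abs(res.T.to_numpy() - oracle)) < 1e-9

    def test_divergent_matrix_rejected(self):
        # row sums exactly 1 => spectral radius 1 for this doubly stochastic D
        d = labeled([[0, 1], [1, 0]])
        with pytest.raises(ConvergenceError, match="converge"):
            total_relation(d)

    def test_nonnegative_total_relation(self, random_direct_relation):
        z = random_direct_relation(10, seed=5)
        res = total_relation(normalize_direct_relation(z).matrix * 0.9)
        assert (res.T.to_numpy() >= -1e-12).all()


class TestMarginals:
    def test_conservation_of_relation(self, random_direct_relation):
        for seed in range(5):
            z = random_direct_relation(6 + seed, seed=seed)
            res, _ = run_dematel(z)
            assert abs(res.relation.sum()) < 1e-9

    def test_marginals_are_row_and_column_sums(self, random_direct_relation):
        res, _ = run_dematel(random_direct_relation(5, seed=7))
        np.testing.assert_allclose(res.R.to_numpy(), res.T.sum(axis=1).to_numpy())
        np.testing.assert_allclose(res.C.to_numpy(), res.T.sum(axis=0).to_numpy())
        assert res.R.sum() == pytest.approx(res.T.to_numpy().sum())

    def test_symmetric_input_gives_zero_relation(self):
        z = labeled([[0, 2, 1], [2, 0, 3], [1, 3, 0]])
        res, _ = run_dematel(z)
        np.testing.assert_allclose(res.relation.to_numpy(), 0, atol=1e-9)
        np.testing.assert_allclose(res.R.to_numpy(), res.C.to_numpy())

    def test_relation_scores_table(self, random_direct_relation):
        res, _ = run_dematel(random_direct_relation(4, seed=11))
        table = relation_scores(res)
        assert list(table.columns) == ["R", "C", "R+C", "R-C"]
        np.testing.assert_allclose(
            table["R+C"].to_numpy(), (res.R + res.C).to_numpy()
        )

    def test_printed_marginals_reproduce_relation(self):
        # published 4-decimal R and C entries for the imaging/physio block
        t2 = load_fixture("bahonar_table2")
        R, C, RC = t2.tables["R"], t2.tables["C"], t2.tables["R-C"]
        for dep in ["ED20", "ED19", "ED18", "ED17"]:
            assert round(R[dep] - C[dep], 3) == pytest.approx(RC[dep])

    def test_scale_invariance_full_chain(self, random_direct_relation):
        z = random_direct_relation(8, seed=3)
        base, base_prof = run_dematel(z)
        for c in (0.1, 3.0, 17.0):
            res, prof = run_dematel(z * c)
            np.testing.assert_allclose(res.T.to_numpy(), base.T.to_numpy(), atol=1e-9)
            np.testing.assert_allclose(
                res.relation.to_numpy(), base.relation.to_numpy(), atol=1e-9
            )
            assert prof.master_dispatcher == base_prof.master_dispatcher
            assert prof.master_receiver == base_prof.master_receiver
            assert (prof.group == base_prof.group).all()

    def test_monotonicity_in_single_entry(self, random_direct_relation):
        # raising one direct influence (with S held fixed) cannot lower
        # the dispatching of its source or the receiving of its target
        z = random_direct_relation(6, seed=9)
        d0 = normalize_direct_relation(z)
        s = d0.scale_constant
        res0 = total_relation(d0.matrix)
        z_up = z.copy()
        z_up.iloc[1, 4] += 0.5
        res1 = total_relation(z_up / s)
        assert res1.R.iloc[1] >= res0.R.iloc[1] - 1e-12
        assert res1.C.iloc[4] >= res0.C.iloc[4] - 1e-12


class TestClassification:
    def test_cause_effect_signs(self, random_direct_relation):
        res, prof = run_dematel(random_direct_relation(9, seed=13))
        for dep in res.department_ids:
            rel = res.relation[dep]
            expected = "cause" if rel > 1e-9 else ("effect" if rel < -1e-9 else "neutral")
            assert prof.group[dep] == expected

    def test_fixture_master_dispatcher_and_receiver(self):
        t2 = load_fixture("bahonar_table2")
        rc = t2.tables["R-C"]
        assert rc.idxmax() == "ED5"  # ICU2 dispatches the most net influence
        assert rc.idxmin() == "ED12"  # jaw and face surgery receives the most

    def test_laboratory_is_cause_in_fixture(self):
        t2 = load_fixture("bahonar_table2")
        assert t2.tables["R"]["ED16"] == pytest.approx(1.6005)
        assert t2.tables["R-C"]["ED16"] == pytest.approx(0.1158)
        assert t2.tables["R-C"]["ED16"] > 0  # laboratory sits in the cause group

    def test_symmetric_input_all_neutral_with_deterministic_tie(self):
        z = labeled([[0, 2, 1], [2, 0, 3], [1, 3, 0]])
        res, prof = run_dematel(z)
        assert (prof.group == "neutral").all()
        assert prof.master_dispatcher == "ED1"  # first label wins exact ties
        assert prof.master_receiver == "ED1"
        assert prof.is_master_dispatcher("ED1")
        assert not prof.is_master_receiver("ED2")
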