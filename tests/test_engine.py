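"""DEA Stage-1 LP, compromise-programming Stage-2 QP, and the grid oracle."""

import numpy as np
import pytest

from ldikit import (
    DeaConfig,
    NormalizedMatrix,
    brute_force_dea_oracle,
    common_scores,
    cp_common_weights,
    dea_ideal_score,
    dea_ideal_scores,
)
from conftest import random_block


def block(values):
    V = np.asarray(values, dtype=float)
    return NormalizedMatrix(
        unit_ids=[f"u{i}" for i in range(V.shape[0])],
        indicator_ids=[f"x{j}" for j in range(V.shape[1])],
        values=V,
    )


class TestStage1:
    def test_single_unit_single_indicator(self):
        assert dea_ideal_score(block([[100.0]]), 0) == pytest.approx(100.0)

    def test_two_units_one_indicator_closed_form(self):
        b = block([[100.0], [50.0]])
        assert dea_ideal_score(b, 0) == pytest.approx(100.0)
        assert dea_ideal_score(b, 1) == pytest.approx(50.0)

    def test_dominated_unit_scores_below_100(self):
        # (50, 50) lies strictly inside the hull of (100, 20) and (20, 100)
        b = block([[100, 20], [20, 100], [50, 50]])
        s = dea_ideal_scores(b)
        np.testing.assert_allclose(s.s_star[:2], 100.0, atol=1e-6)
        assert s.s_star[2] == pytest.approx(100 * 50 / 60, abs=1e-6)

    def test_identity_profile_all_score_100(self):
        s = dea_ideal_scores(block(np.eye(3) * 100))
        np.testing.assert_allclose(s.s_star, 100.0, atol=1e-6)

    def test_max_ideal_score_is_100(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            s = dea_ideal_scores(random_block(rng, int(rng.integers(2, 8)), int(rng.integers(1, 5))))
            assert s.s_star.max() == pytest.approx(100.0, abs=1e-6)
            assert np.all(s.s_star <= 100.0 + 1e-6)

    def test_dominance_monotonicity(self):
        """A unit weakly better in every indicator never scores lower."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            b = random_block(rng, 5, 3)
            V = b.values.copy()
            V[1] = np.minimum(V[0] * rng.uniform(0.3, 1.0), V[0])  # row 1 dominated by row 0
            b2 = block(V)
            s = dea_ideal_scores(b2)
            assert s.s_star[0] >= s.s_star[1] - 1e-6

    def test_too_large_epsilon_is_infeasible(self):
        with pytest.raises(RuntimeError, match="epsilon"):
            dea_ideal_score(block([[100.0, 100.0]]), 0, DeaConfig(epsilon=10.0))


class TestOracle:
    def test_single_direction_matches_lp(self):
        b = block([[100.0], [25.0]])
        assert brute_force_dea_oracle(b, 1, 1) == pytest.approx(dea_ideal_score(b, 1))

    def test_oracle_never_exceeds_lp(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n = int(rng.integers(1, 4))
            b = random_block(rng, int(rng.integers(2, 8)), n)
            k = int(rng.integers(0, len(b.unit_ids)))
            lp = dea_ideal_score(b, k)
            oracle = brute_force_dea_oracle(b, k, grid_n=500)
            assert oracle <= lp + 1e-9

    def test_two_indicator_agreement(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            b = random_block(rng, 6, 2)
            k = int(rng.integers(0, 6))
            lp = dea_ideal_score(b, k)
            oracle = brute_force_dea_oracle(b, k, grid_n=10_000)
            assert abs(lp - oracle) / 100.0 < 1e-3  # unit score scale

    def test_refuses_high_dimension(self):
        with pytest.raises(ValueError, match="at most 3"):
            brute_force_dea_oracle(block(np.full((2, 4), 100.0)), 0)


class TestStage2:
    def test_rank_one_block_reaches_every_ideal(self):
        """Proportional rows: one weighting is simultaneously optimal for all."""
        base = np.array([100.0, 80.0, 40.0])
        b = block(np.column_stack([base, base]))
        ideal = dea_ideal_scores(b)
        w = cp_common_weights(b, ideal)
        assert w.objective_value <= 1e-8
        np.testing.assert_allclose(common_scores(b, w), ideal.s_star, atol=1e-4)

    def test_single_indicator_closed_form(self):
        b = block([[100.0], [60.0]])
        w = cp_common_weights(b, dea_ideal_scores(b))
        assert w.w[0] == pytest.approx(1.0, abs=1e-8)  # 1 / column max on [0,1] scale
        assert w.objective_value <= 1e-12

    def test_qp_beats_grid_search(self):
        """No feasible weight vector on a dense grid improves on the QP objective."""
        b = block([[100, 20], [20, 100], [50, 50]])
        ideal = dea_ideal_scores(b)
        w = cp_common_weights(b, ideal)
        Y, s = b.internal, ideal.internal
        t = np.linspace(0, 1, 401)
        D = np.column_stack([t, 1 - t])
        caps = (Y @ D.T).max(axis=0)
        scales = np.linspace(0, 1, 201)
        best = np.inf
        for d, cap in zip(D, caps):
            if cap <= 0:
                continue
            for a in scales:  # scaled inside the feasible region
                ww = d * (a / cap)
                best = min(best, float(np.sum((s - Y @ ww) ** 2)))
        assert w.objective_value <= best + 1e-9

    def test_zero_weights_give_zero_scores(self):
        from ldikit import CommonWeightVector

        b = block([[100.0, 50.0], [50.0, 100.0]])
        w = CommonWeightVector(indicator_ids=b.indicator_ids, w=np.zeros(2), objective_value=np.nan)
        np.testing.assert_allclose(common_scores(b, w), 0.0)

    def test_common_scores_never_exceed_ideal(self):
        rng = np.random.default_rng(41)
        for _ in range(15):
            b = random_block(rng, int(rng.integers(3, 9)), int(rng.integers(1, 5)))
            ideal = dea_ideal_scores(b)
            w = cp_common_weights(b, ideal)
            assert np.max(b.internal @ w.w) <= 1.0 + 1e-6  # stage-1 feasibility
            assert np.all(common_scores(b, w) <= ideal.s_star + 1e-6)

    def test_backend_agreement(self):
        """SLSQP and trust-constr seeds converge to the same refined optimum."""
        rng = np.random.default_rng(53)
        for _ in range(8):
            b = random_block(rng, int(rng.integers(4, 9)), int(rng.integers(2, 4)))
            ideal = dea_ideal_scores(b)
            wa = cp_common_weights(b, ideal, DeaConfig(qp_solver="slsqp"))
            wb = cp_common_weights(b, ideal, DeaConfig(qp_solver="trust-constr"))
            np.testing.assert_allclose(wa.w, wb.w, atol=1e-6)

    def test_min_norm_tiebreak_on_identical_columns(self):
        """Rank deficiency resolves to the unique minimum-norm weighting."""
        base = np.array([100.0, 75.0, 50.0, 25.0])
        b = block(np.column_stack([base, base]))
        w = cp_common_weights(b, dea_ideal_scores(b))
        np.testing.assert_allclose(w.w, [0.5, 0.5], atol=1e-7)

    def test_degenerate_all_zero_block_rejected(self):
        b = block(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="all-zero"):
            cp_common_weights(b, dea_ideal_scores(block(np.zeros((2, 2)))))


def test_unit_invariance_of_pipeline_outputs():
    """Rescaling a raw column before normalization changes nothing downstream."""
    from ldikit import IndicatorNode, IndicatorScheme, UnitDataMatrix, normalize_matrix

    sch = IndicatorScheme(
        nodes=[
            IndicatorNode("a", "top", 1, weight=1.0),
            IndicatorNode("a.1", "mid", 2, parent_id="a"),
            IndicatorNode("x", "x", 3, parent_id="a.1", polarity=1),
            IndicatorNode("y", "y", 3, parent_id="a.1", polarity=-1),
        ]
    )
    rng = np.random.default_rng(61)
    vals = rng.uniform(1.0, 10.0, size=(5, 2))
    raw1 = UnitDataMatrix([f"u{i}" for i in range(5)], ["x", "y"], vals, np.zeros((5, 2), bool))
    scaled = vals.copy()
    scaled[:, 0] *= 1e3
    raw2 = UnitDataMatrix([f"u{i}" for i in range(5)], ["x", "y"], scaled, np.zeros((5, 2), bool))
    b1, b2 = normalize_matrix(raw1, sch), normalize_matrix(raw2, sch)
    np.testing.assert_allclose(b1.values, b2.values, rtol=1e-9)
    s1, s2 = dea_ideal_scores(b1), dea_ideal_scores(b2)
    np.testing.assert_allclose(s1.s_star, s2.s_star, atol=1e-9)
    w1 = cp_common_weights(b1, s1)
    w2 = cp_common_weights(b2, s2)
    np.testing.assert_allclose(w1.w, w2.w, atol=1e-8)
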