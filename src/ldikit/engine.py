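"""Two-stage DEA + compromise-programming weighting engine.

Stage 1 is a benefit-of-the-doubt DEA: each evaluation unit k picks the
nonnegative weight vector most favorable to itself,

    s*_k = max_w  sum_j w_j y_kj   s.t.  sum_j w_j y_ij <= 1 for every unit i,
                                          w_j >= epsilon,

with y on a [0, 1] scale (normalized values / 100). The optima form the
ideal score vector: what every unit could claim under its own best-case
weighting. Stage 2 (compromise programming, L2 norm) finds one common
weight vector minimizing the total squared shortfall of actual weighted
scores from those ideals over the same feasible domain,

    w* = argmin_w sum_k (s*_k - sum_j w_j y_kj)^2   s.t. same constraints.

The common weights resolve DEA's weight-dispersion problem: every unit is
scored with the same w*, and since w* lies in each unit's Stage-1 feasible
region, common scores never exceed ideal scores.

Stage 1 is solved exactly as a linear program (HiGHS); Stage 2 as a convex
quadratic program via SLSQP (default) or trust-constr. Under rank
deficiency the L2 fit does not pin w* down; a second pass then selects the
minimum-norm optimum, which is unique.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .normalization import NormalizedMatrix

__all__ = [
    "DeaConfig",
    "IdealScoreVector",
    "CommonWeightVector",
    "dea_ideal_score",
    "dea_ideal_scores",
    "cp_common_weights",
    "common_scores",
    "brute_force_dea_oracle",
]

logger = logging.getLogger(__name__)


@dataclass
class DeaConfig:
    """Solver configuration.

    epsilon: lower bound on every weight. Default 0; a tiny positive value
    forces every indicator to contribute (the published leaf weights of
    order 1e-8 are consistent with such a bound, though its value was never
    stated, so 0 remains the default).
    """

    epsilon: float = 0.0
    lp_tol: float = 1e-9
    qp_tol: float = 1e-12
    qp_solver: str = "slsqp"  # or "trust-constr"
    min_norm_tiebreak: bool = True

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.qp_solver not in ("slsqp", "trust-constr"):
            raise ValueError(f"unknown QP solver: {self.qp_solver}")


@dataclass
class IdealScoreVector:
    """Stage-1 optima on the 0-100 scale; at least one unit attains 100."""

    unit_ids: list[str]
    s_star: np.ndarray

    def __post_init__(self) -> None:
        self.s_star = np.asarray(self.s_star, dtype=float)

    @property
    def internal(self) -> np.ndarray:
        return self.s_star / 100.0


@dataclass
class CommonWeightVector:
    """Stage-2 unified weights (multipliers on [0,1]-scale normalized values)."""

    indicator_ids: list[str]
    w: np.ndarray
    objective_value: float
    solver: str = ""

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)


def _internal(block: NormalizedMatrix | np.ndarray) -> np.ndarray:
    if isinstance(block, NormalizedMatrix):
        return block.internal
    return np.asarray(block, dtype=float)


def dea_ideal_score(block: NormalizedMatrix, unit_index: int, cfg: DeaConfig | None = None) -> float:
    """Stage-1 optimum for one unit, on the 0-100 scale.

    Solved as an LP: maximize the unit's weighted score subject to no unit's
    weighted score exceeding 1 and weights >= epsilon.
    """
    cfg = cfg or DeaConfig()
    Y = _internal(block)
    m, n = Y.shape
    if not 0 <= unit_index < m:
        raise IndexError(f"unit index {unit_index} out of range for {m} units")
    res = optimize.linprog(
        c=-Y[unit_index],
        A_ub=Y,
        b_ub=np.ones(m),
        bounds=[(cfg.epsilon, None)] * n,
        method="highs",
        options={"primal_feasibility_tolerance": cfg.lp_tol, "dual_feasibility_tolerance": cfg.lp_tol},
    )
    if not res.success:
        raise RuntimeError(
            f"stage-1 LP failed for unit {block.unit_ids[unit_index]!r}: {res.message} "
            f"(epsilon={cfg.epsilon} may be too large)"
        )
    logger.debug("stage-1 LP unit %s: status=%s s*=%.9f", block.unit_ids[unit_index], res.status, -res.fun)
    return float(-res.fun) * 100.0


def dea_ideal_scores(block: NormalizedMatrix, cfg: DeaConfig | None = None) -> IdealScoreVector:
    """Stage-1 optima for every unit, order preserved."""
    cfg = cfg or DeaConfig()
    scores = [dea_ideal_score(block, k, cfg) for k in range(len(block.unit_ids))]
    return IdealScoreVector(unit_ids=list(block.unit_ids), s_star=np.asarray(scores))


def _qp_solve(Y, cfg, w0, target):
    """Seed solve of the L2-fit QP min ||target - Y w||^2 over {Y w <= 1, w >= epsilon}."""
    m, n = Y.shape

    def fun(w):
        r = Y @ w - target
        return float(r @ r)

    def jac(w):
        return 2.0 * Y.T @ (Y @ w - target)

    if cfg.qp_solver == "slsqp":
        cons = [{"type": "ineq", "fun": lambda w: 1.0 - Y @ w, "jac": lambda w: -Y}]
        res = optimize.minimize(
            fun, w0, jac=jac, method="SLSQP",
            bounds=[(cfg.epsilon, None)] * n,
            constraints=cons,
            options={"maxiter": 1000, "ftol": cfg.qp_tol},
        )
    else:
        res = optimize.minimize(
            fun, w0, jac=jac, method="trust-constr",
            bounds=optimize.Bounds(cfg.epsilon, np.inf),
            constraints=[optimize.LinearConstraint(Y, -np.inf, 1.0)],
            options={"maxiter": 5000, "gtol": 1e-12, "xtol": 1e-16},
        )
    return res


def _polish_fit(Y, s, w, eps, max_iter=200):
    """Primal active-set refinement of the L2-fit QP.

    Starting from a (near-)feasible solver solution, iterates exact
    equality-constrained KKT solves with multiplier checks and
    blocking-constraint steps until the KKT conditions hold. Removes
    solver-dependent convergence error so different seed solvers land on
    the same optimum. Falls back to the input on any numerical trouble.
    """
    m, n = Y.shape
    # constraints c.x <= d: unit rows (Y_i, 1) and bounds (-e_j, -eps)
    C = np.vstack([Y, -np.eye(n)])
    d = np.concatenate([np.ones(m), -np.full(n, eps)])
    H = 2.0 * Y.T @ Y

    x = np.maximum(np.asarray(w, dtype=float), eps)
    cap = np.max(Y @ x)
    if cap > 1.0:
        x = np.maximum(x / cap, eps)  # may still exceed 1 if eps binds; checked below
        if np.max(Y @ x) > 1.0 + 1e-9:
            return w
    x0 = x.copy()

    work = set(np.where(C @ x >= d - 1e-9)[0])
    for _ in range(max_iter):
        g = 2.0 * Y.T @ (Y @ x - s)
        W = sorted(work)
        Cw = C[W]
        k = len(W)
        K = np.zeros((n + k, n + k))
        K[:n, :n] = H
        if k:
            K[:n, n:] = Cw.T
            K[n:, :n] = Cw
        rhs = np.concatenate([-g, np.zeros(k)])
        sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
        p, lam = sol[:n], sol[n:]
        if np.linalg.norm(p) <= 1e-11 * max(1.0, np.linalg.norm(x)):
            if k == 0 or np.all(lam >= -1e-9):
                break  # KKT satisfied
            work.discard(W[int(np.argmin(lam))])
            continue
        # step to the nearest blocking constraint
        mask = np.ones(C.shape[0], dtype=bool)
        mask[W] = False
        cp = C[mask] @ p
        slack = d[mask] - C[mask] @ x
        blocking = cp > 1e-13
        alpha = 1.0
        idx_full = np.where(mask)[0]
        hit = None
        if blocking.any():
            ratios = slack[blocking] / cp[blocking]
            j = int(np.argmin(ratios))
            if ratios[j] < alpha:
                alpha = max(ratios[j], 0.0)
                hit = int(idx_full[np.where(blocking)[0][j]])
        x = x + alpha * p
        if hit is not None:
            work.add(hit)
    x = np.maximum(x, eps)
    old_obj = float(np.sum((s - Y @ w) ** 2))
    new_obj = float(np.sum((s - Y @ x) ** 2))
    if np.max(Y @ x) <= 1.0 + 1e-9 and new_obj <= old_obj + 1e-10:
        return x
    return np.maximum(np.asarray(w, dtype=float), eps) if new_obj > old_obj else x0


def _min_norm_projection(Y, w_star, eps, max_iter=200):
    """Deterministic tie-break: min ||w||^2 s.t. Y w = Y w*, w >= eps.

    Moving within the null space of Y leaves every fitted score (hence the
    L2 objective and feasibility) unchanged, so among optimal weight
    vectors this selects the unique minimum-norm one. Solved exactly by an
    active-set iteration over the bound constraints; returns ``w_star``
    unchanged when the fit already pins the weights down.
    """
    m, n = Y.shape
    z = Y @ w_star
    x = np.asarray(w_star, dtype=float).copy()
    bound = set(np.where(x <= eps + 1e-9)[0])
    for _ in range(max_iter):
        B = sorted(bound)
        free = np.setdiff1d(np.arange(n), B)
        if free.size == 0:
            break
        Yf = Y[:, free]
        b = z - Y[:, B] @ np.full(len(B), eps)
        nf = free.size
        K = np.zeros((nf + m, nf + m))
        K[:nf, :nf] = 2.0 * np.eye(nf)
        K[:nf, nf:] = Yf.T
        K[nf:, :nf] = Yf
        rhs = np.concatenate([np.zeros(nf), b])
        sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
        x_new = np.full(n, eps)
        x_new[free] = sol[:nf]
        lam = sol[nf:]
        if np.linalg.norm(Y @ x_new - z) > 1e-9:
            return w_star  # active bounds make the fitted scores unreachable
        p = x_new - x
        if np.linalg.norm(p) <= 1e-12 * max(1.0, np.linalg.norm(x)):
            if not B:
                break
            mu = (2.0 * x + Y.T @ lam)[B]
            if np.all(mu >= -1e-9):
                break
            bound.discard(B[int(np.argmin(mu))])
            continue
        # step toward x_new, stopping at the first bound it would violate
        alpha = 1.0
        hit = None
        for j in np.where(p < -1e-13)[0]:
            if j in bound:
                continue
            r = (eps - x[j]) / p[j]
            if r < alpha:
                alpha, hit = max(r, 0.0), int(j)
        x = x + alpha * p
        if hit is not None:
            bound.add(hit)
    x = np.maximum(x, eps)
    if np.linalg.norm(Y @ x - z) <= 1e-9 and x @ x <= w_star @ w_star + 1e-12:
        return x
    return w_star


def cp_common_weights(
    block: NormalizedMatrix,
    ideal: IdealScoreVector,
    cfg: DeaConfig | None = None,
) -> CommonWeightVector:
    """Stage-2 common weights: L2-closest feasible weighting to the ideal point.

    The objective is evaluated on the [0,1] score scale for conditioning;
    the reported ``objective_value`` is on that scale. With
    ``min_norm_tiebreak`` (default) a rank-deficient fit is resolved to the
    minimum-norm optimum, making the result unique and solver-independent.
    """
    cfg = cfg or DeaConfig()
    Y = _internal(block)
    m, n = Y.shape
    if not np.any(Y > 0):
        raise ValueError("degenerate all-zero block")
    if list(ideal.unit_ids) != list(block.unit_ids):
        raise ValueError("ideal score vector computed on a different block")
    s = ideal.internal

    # warm start: nonnegative LS fit pulled back into the feasible region
    w0, _ = optimize.nnls(Y, s)
    w0 = np.maximum(w0, cfg.epsilon)
    cap = np.max(Y @ w0)
    if cap > 1.0:
        w0 = np.maximum(w0 / cap, cfg.epsilon)

    res = _qp_solve(Y, cfg, w0, target=s)
    if not res.success and res.status not in (0,):
        raise RuntimeError(f"stage-2 QP did not converge: {res.message}")
    w = np.maximum(res.x, cfg.epsilon)
    w = _polish_fit(Y, s, w, cfg.epsilon)
    if cfg.min_norm_tiebreak:
        w = _min_norm_projection(Y, w, cfg.epsilon)
    obj = float(np.sum((s - Y @ w) ** 2))
    logger.debug("stage-2 QP: objective=%.3e, ||w||=%.6f", obj, float(np.linalg.norm(w)))
    return CommonWeightVector(
        indicator_ids=list(block.indicator_ids), w=w, objective_value=obj, solver=cfg.qp_solver
    )


def common_scores(block: NormalizedMatrix, weights: CommonWeightVector) -> np.ndarray:
    """Per-unit scores under the common weights, on the 0-100 scale."""
    if list(weights.indicator_ids) != list(block.indicator_ids):
        raise ValueError("weight vector indexed by different indicators than the block")
    return 100.0 * (_internal(block) @ weights.w)


def brute_force_dea_oracle(block: NormalizedMatrix, unit_index: int, grid_n: int = 200) -> float:
    """Desk-scale Stage-1 oracle: enumerate weight directions on a simplex grid.

    Each direction d >= 0 (sum 1) is scaled to the feasibility boundary
    t = 1 / max_i (Y_i . d); the candidate score is t * (Y_k . d). The
    maximum over the grid approaches the LP optimum from below and every
    grid point is feasible, so the oracle never exceeds the LP value.
    Refuses more than 3 indicators.
    """
    Y = _internal(block)
    m, n = Y.shape
    if n > 3:
        raise ValueError("oracle supports at most 3 indicators")
    if n == 1:
        directions = np.ones((1, 1))
    elif n == 2:
        t = np.linspace(0.0, 1.0, grid_n + 1)
        directions = np.column_stack([t, 1.0 - t])
    else:
        i, j = np.meshgrid(np.arange(grid_n + 1), np.arange(grid_n + 1), indexing="ij")
        keep = i + j <= grid_n
        i, j = i[keep], j[keep]
        directions = np.column_stack([i, j, grid_n - i - j]).astype(float) / grid_n
    proj = Y @ directions.T  # units x directions
    caps = proj.max(axis=0)
    ok = caps > 0
    if not ok.any():
        return 0.0
    return float(np.max(proj[unit_index, ok] / caps[ok])) * 100.0
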