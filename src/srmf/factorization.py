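"""The similarity-regularized weighted matrix factorization model.

The model approximates an incomplete drug x cell-line response matrix Y by
U Vᵀ, with U (m x K) and V (n x K) the latent coordinates of drugs and
cell lines. The objective minimized is

    || W ∘ (Y − U Vᵀ) ||²_F
      + λ_l (||U||²_F + ||V||²_F)
      + λ_d || S_d − U Uᵀ ||²_F
      + λ_c || S_c − V Vᵀ ||²_F

where W is the binary observed-entry mask and S_d / S_c are precomputed
drug and cell-line similarity matrices. Before fitting, Y is divided by
its maximum absolute observed value so responses lie in [−1, 1], matching
the [−1, 1] range of the similarity matrices; predictions are mapped back
to the original response scale.

Fitting is alternating minimization: each sweep solves regularized
per-row normal equations for U with V fixed (and the second occurrence of
U inside the quartic similarity term frozen at the previous sweep, so it
contributes a linear system), then symmetrically for V. Each proposed
sweep is accepted through a backtracking line search against the exact
objective, which guarantees a monotonically non-increasing objective
sequence regardless of the linearization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from srmf.datamodel import ResponseMatrix, SimilarityMatrix, SrmfConfig

__all__ = ["LatentFactors", "FitTrace", "scale_response", "objective", "fit", "predict"]


@dataclass
class LatentFactors:
    """Fitted factor pair plus the response-scaling constant.

    ``scale`` is the max-absolute-observed-value divisor applied to the
    responses before fitting; predictions are multiplied back by it.
    """

    U: np.ndarray
    V: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.U.ndim != 2 or self.V.ndim != 2 or self.U.shape[1] != self.V.shape[1]:
            raise ValueError("U and V must be 2-D with a common latent dimension K")
        if not (np.isfinite(self.U).all() and np.isfinite(self.V).all()):
            raise ValueError("latent factors must be finite")
        if not self.scale > 0:
            raise ValueError("scale must be positive")


@dataclass
class FitTrace:
    """Objective value per outer iteration (element 0 is the initial value)."""

    objective_values: list[float]
    iterations_run: int
    converged: bool


def scale_response(R: ResponseMatrix) -> tuple[ResponseMatrix, float]:
    """Divide observed responses by their maximum absolute value.

    Returns the rescaled matrix (observed entries in [−1, 1]) and the
    divisor; missing entries are untouched.
    """
    observed = R.mask.astype(bool)
    if not observed.any():
        raise ValueError("response matrix has no observed entries")
    scale = float(np.abs(R.values[observed]).max())
    if scale == 0:
        raise ValueError("all observed responses are zero; scale is undefined")
    scaled = ResponseMatrix(
        list(R.drug_ids), list(R.cell_ids), R.values / scale, R.mask.copy(), R.direction
    )
    return scaled, scale


def objective(
    Y: np.ndarray,
    W: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    Sd: np.ndarray | None,
    Sc: np.ndarray | None,
    lambda_l: float,
    lambda_d: float,
    lambda_c: float,
) -> float:
    """Evaluate the regularized weighted-factorization objective."""
    Y = np.asarray(Y, dtype=float)
    W = np.asarray(W, dtype=float)
    if Y.shape != W.shape:
        raise ValueError("Y and W must have the same shape")
    m, n = Y.shape
    if U.shape[0] != m or V.shape[0] != n or U.shape[1] != V.shape[1]:
        raise ValueError("factor dimensions do not conform with Y")
    if not np.isin(W, (0, 1)).all():
        raise ValueError("W must be binary")
    Yz = np.where(W > 0, Y, 0.0)
    resid = W * (Yz - U @ V.T)
    f = float(np.sum(resid * resid))
    f += lambda_l * (float(np.sum(U * U)) + float(np.sum(V * V)))
    if lambda_d != 0:
        if Sd is None:
            raise ValueError("lambda_d > 0 requires a drug similarity matrix")
        Dd = np.asarray(Sd, dtype=float) - U @ U.T
        f += lambda_d * float(np.sum(Dd * Dd))
    if lambda_c != 0:
        if Sc is None:
            raise ValueError("lambda_c > 0 requires a cell-line similarity matrix")
        Dc = np.asarray(Sc, dtype=float) - V @ V.T
        f += lambda_c * float(np.sum(Dc * Dc))
    return f


def _svd_init(Y: np.ndarray, W: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic init from the top-K SVD of the mean-imputed matrix."""
    obs = W > 0
    mean = Y[obs].mean()
    Yi = np.where(obs, Y, mean)
    Um, s, Vt = np.linalg.svd(Yi, full_matrices=False)
    Um, s, Vt = Um[:, :K], s[:K], Vt[:K]
    # sign convention, symmetric under problem transposition: the largest-
    # magnitude entry of each concatenated singular-vector pair is positive
    for k in range(len(s)):
        pair = np.concatenate([Um[:, k], Vt[k]])
        if pair[np.argmax(np.abs(pair))] < 0:
            Um[:, k] *= -1
            Vt[k] *= -1
    root = np.sqrt(s)
    return Um * root, Vt.T * root


def _solve_rows(
    Y: np.ndarray,
    W: np.ndarray,
    other: np.ndarray,
    frozen: np.ndarray,
    S: np.ndarray | None,
    lambda_l: float,
    lambda_s: float,
) -> np.ndarray:
    """Row-wise regularized normal equations for one factor.

    For each row i solves
        (Vᵀ diag(w_i) V + λ_l I + 2 λ_s FᵀF) uᵢᵀ = Vᵀ (w_i ∘ y_i) + 2 λ_s Fᵀ s_i
    with ``other`` = V, ``frozen`` = F the factor's previous value inside
    the similarity term, and s_i the i-th similarity row.
    """
    m = Y.shape[0]
    K = other.shape[1]
    base = lambda_l * np.eye(K)
    if lambda_s != 0 and S is not None:
        base = base + 2.0 * lambda_s * (frozen.T @ frozen)
    out = np.empty((m, K))
    Yz = np.where(W > 0, Y, 0.0)
    for i in range(m):
        w = W[i]
        Vw = other * w[:, None]
        A = base + Vw.T @ other
        b = other.T @ (w * Yz[i])
        if lambda_s != 0 and S is not None:
            b = b + 2.0 * lambda_s * (frozen.T @ S[i])
        out[i] = np.linalg.solve(A, b)
    return out


def _backtrack(
    current: np.ndarray,
    proposed: np.ndarray,
    f_current: float,
    evaluate,
    max_halvings: int = 30,
) -> tuple[np.ndarray, float]:
    """Accept the longest step along (proposed - current) that does not
    increase the objective; fall back to the current iterate."""
    t = 1.0
    for _ in range(max_halvings):
        trial = current + t * (proposed - current)
        f_trial = evaluate(trial)
        if f_trial <= f_current:
            return trial, f_trial
        t *= 0.5
    return current, f_current


def fit(
    R: ResponseMatrix,
    Sd: SimilarityMatrix | None,
    Sc: SimilarityMatrix | None,
    cfg: SrmfConfig,
) -> tuple[LatentFactors, FitTrace]:
    """Fit the factorization by alternating minimization.

    ``Sd`` may be None when ``cfg.lambda_d == 0`` and ``Sc`` when
    ``cfg.lambda_c == 0``; otherwise they must cover R's drug / cell ids.
    Deterministic given ``cfg.seed`` (the seed only matters for
    ``init="random"``).
    """
    m, n = R.shape
    cfg.validate_for_shape(m, n)
    if cfg.lambda_d != 0 and Sd is None:
        raise ValueError("lambda_d > 0 requires a drug similarity matrix")
    if cfg.lambda_c != 0 and Sc is None:
        raise ValueError("lambda_c > 0 requires a cell-line similarity matrix")
    Sd_arr = Sd.aligned_to(R.drug_ids) if cfg.lambda_d != 0 else None
    Sc_arr = Sc.aligned_to(R.cell_ids) if cfg.lambda_c != 0 else None

    scaled, scale = scale_response(R)
    Y = np.where(scaled.mask > 0, scaled.values, 0.0)
    W = scaled.mask.astype(float)

    if cfg.init == "svd":
        U, V = _svd_init(Y, W, cfg.K)
    else:
        rng = np.random.default_rng(cfg.seed)
        sd = 1.0 / np.sqrt(cfg.K)
        U = rng.normal(0.0, sd, size=(m, cfg.K))
        V = rng.normal(0.0, sd, size=(n, cfg.K))

    def f_of(U_, V_):
        return objective(Y, W, U_, V_, Sd_arr, Sc_arr, cfg.lambda_l, cfg.lambda_d, cfg.lambda_c)

    f = f_of(U, V)
    trace = [f]
    converged = False
    it = 0

    def sweep_u(f_cur):
        nonlocal U
        U_prop = _solve_rows(Y, W, V, U, Sd_arr, cfg.lambda_l, cfg.lambda_d)
        U, f_new = _backtrack(U, U_prop, f_cur, lambda U_: f_of(U_, V))
        return f_new

    def sweep_v(f_cur):
        nonlocal V
        V_prop = _solve_rows(Y.T, W.T, U, V, Sc_arr, cfg.lambda_l, cfg.lambda_c)
        V, f_new = _backtrack(V, V_prop, f_cur, lambda V_: f_of(U, V_))
        return f_new

    # the shorter side goes first so a transposed problem runs the mirrored
    # sweep order and yields exactly the transposed solution
    order = (sweep_u, sweep_v) if m <= n else (sweep_v, sweep_u)
    for it in range(1, cfg.max_iter + 1):
        for sweep in order:
            f = sweep(f)
        if not (np.isfinite(U).all() and np.isfinite(V).all()):
            raise FloatingPointError(f"non-finite factor entries at iteration {it}")
        trace.append(f)
        prev = trace[-2]
        denom = max(abs(prev), 1e-30)
        if abs(prev - f) / denom < cfg.tol:
            converged = True
            break
    factors = LatentFactors(U=U, V=V, scale=scale)
    return factors, FitTrace(objective_values=trace, iterations_run=it, converged=converged)


def predict(R: ResponseMatrix, factors: LatentFactors) -> np.ndarray:
    """Reconstruct the full response matrix on the original response scale."""
    m, n = R.shape
    if factors.U.shape[0] != m or factors.V.shape[0] != n:
        raise ValueError(
            f"factors of shape {factors.U.shape[0]}x{factors.V.shape[0]} do not "
            f"match a {m}x{n} response matrix"
        )
    return factors.scale * (factors.U @ factors.V.T)
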