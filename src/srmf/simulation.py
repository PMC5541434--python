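"""Synthetic drug-response problems with known low-rank ground truth.

The generator emulates the benchmark design used to stress matrix-
factorization response predictors: a target response matrix Y* = U* V*ᵀ
with Gaussian latent factors, additive Gaussian noise whose standard
deviation is a stated fraction of sd(Y*), similarity matrices derived by
Pearson correlation from the clean target (drug rows for Sd, cell columns
for Sc), and a uniformly random missing mask. Default dimensions are
m = 100 drugs by n = 150 cell lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from srmf.datamodel import Direction, ResponseMatrix, SimilarityMatrix, SrmfConfig
from srmf.factorization import fit, predict

__all__ = [
    "SimulationConfig",
    "SimulationInstance",
    "simulate_instance",
    "srmf_predictor",
    "drug_averaged_metrics",
    "run_noise_sweep",
]

Predictor = Callable[[ResponseMatrix, SimilarityMatrix, SimilarityMatrix, int], np.ndarray]


@dataclass
class SimulationConfig:
    """Study conditions of one synthetic benchmark.

    noise_level is the noise standard deviation relative to sd of the
    clean target entries; missing_fraction of entries are masked uniformly
    at random.
    """

    m: int = 100
    n: int = 150
    k_true: int = 10
    noise_level: float = 0.0
    missing_fraction: float = 0.1
    n_repeats: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m <= 0 or self.n <= 0:
            raise ValueError("m and n must be positive")
        if not 0 < self.k_true <= min(self.m, self.n):
            raise ValueError("k_true must satisfy 0 < k_true <= min(m, n)")
        if not 0.0 <= self.noise_level <= 1.0:
            raise ValueError("noise_level must lie in [0, 1]")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.n_repeats <= 0:
            raise ValueError("n_repeats must be positive")

    def replace(self, **kwargs) -> "SimulationConfig":
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}  # type: ignore[attr-defined]
        d.update(kwargs)
        return SimulationConfig(**d)


@dataclass
class SimulationInstance:
    """One synthetic problem: noisy observations plus the clean truth."""

    response: ResponseMatrix
    target: np.ndarray  # clean m x n target Y*
    Sd: SimilarityMatrix
    Sc: SimilarityMatrix
    U_true: np.ndarray
    V_true: np.ndarray


def _corr_similarity(X: np.ndarray, ids: list[str]) -> SimilarityMatrix:
    S = np.corrcoef(X)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(ids, S)


def simulate_instance(cfg: SimulationConfig) -> SimulationInstance:
    """Draw one reproducible synthetic instance from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    U = rng.standard_normal((cfg.m, cfg.k_true))
    V = rng.standard_normal((cfg.n, cfg.k_true))
    target = U @ V.T
    sd_target = target.std()
    noise = rng.normal(0.0, cfg.noise_level * sd_target, size=target.shape)
    observed = target + noise

    drug_ids = [f"drug_{i + 1:03d}" for i in range(cfg.m)]
    cell_ids = [f"cell_{j + 1:03d}" for j in range(cfg.n)]
    Sd = _corr_similarity(target, drug_ids)
    Sc = _corr_similarity(target.T, cell_ids)

    values = observed.copy()
    n_missing = int(round(cfg.missing_fraction * cfg.m * cfg.n))
    if n_missing:
        flat = rng.choice(cfg.m * cfg.n, size=n_missing, replace=False)
        values.flat[flat] = np.nan
    response = ResponseMatrix(
        drug_ids, cell_ids, values, direction=Direction.LOWER_IS_SENSITIVE
    )
    return SimulationInstance(
        response=response, target=target, Sd=Sd, Sc=Sc, U_true=U, V_true=V
    )


def srmf_predictor(cfg: SrmfConfig) -> Predictor:
    """Wrap the factorization as a sweep-compatible fit/predict callable."""

    def _predict(R: ResponseMatrix, Sd: SimilarityMatrix, Sc: SimilarityMatrix, seed: int):
        factors, _ = fit(R, Sd, Sc, cfg.replace(seed=seed))
        return predict(R, factors)

    return _predict


def drug_averaged_metrics(target: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    """Drug-averaged PCC and RMSE of a full prediction against the clean target."""
    target = np.asarray(target, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if target.shape != predicted.shape:
        raise ValueError("target and prediction shapes differ")
    tc = target - target.mean(axis=1, keepdims=True)
    pc = predicted - predicted.mean(axis=1, keepdims=True)
    num = (tc * pc).sum(axis=1)
    den = np.sqrt((tc**2).sum(axis=1) * (pc**2).sum(axis=1))
    valid = den > 0
    pcc = float(np.mean(num[valid] / den[valid]))
    rmse = float(np.mean(np.sqrt(np.mean((target - predicted) ** 2, axis=1))))
    return pcc, rmse


def _repeat_seed(base_seed: int, level: float, repeat: int) -> int:
    # order-free derivation: depends only on (base seed, level value, repeat),
    # never on sweep iteration order
    ss = np.random.SeedSequence([base_seed, int(round(level * 10**6)), repeat])
    return int(ss.generate_state(1)[0] % (2**31))


def run_noise_sweep(
    cfg_base: SimulationConfig,
    noise_levels: Sequence[float],
    methods: Mapping[str, Predictor],
) -> pd.DataFrame:
    """Benchmark predictors across noise levels against the clean target.

    For each noise level and repeat a fresh instance is drawn, every method
    is fitted on the observed (noisy, masked) responses, and its full
    prediction is scored against the noise-free target by drug-averaged
    PCC and RMSE. Returns one row per (noise level, method) with means and
    standard errors over repeats.
    """
    if not noise_levels:
        raise ValueError("need at least one noise level")
    if not methods:
        raise ValueError("need at least one method")
    rows = []
    for level in noise_levels:
        scores: dict[str, list[tuple[float, float]]] = {name: [] for name in methods}
        for r in range(cfg_base.n_repeats):
            seed = _repeat_seed(cfg_base.seed, level, r)
            inst = simulate_instance(cfg_base.replace(noise_level=level, seed=seed))
            for name, method in methods.items():
                pred = method(inst.response, inst.Sd, inst.Sc, seed)
                scores[name].append(drug_averaged_metrics(inst.target, pred))
        for name, vals in scores.items():
            pcc = np.array([v[0] for v in vals])
            rmse = np.array([v[1] for v in vals])
            nrep = len(vals)
            rows.append(
                {
                    "noise_level": level,
                    "method": name,
                    "n_repeats": nrep,
                    "pcc_mean": pcc.mean(),
                    "pcc_se": pcc.std(ddof=1) / np.sqrt(nrep) if nrep > 1 else 0.0,
                    "rmse_mean": rmse.mean(),
                    "rmse_se": rmse.std(ddof=1) / np.sqrt(nrep) if nrep > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)
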