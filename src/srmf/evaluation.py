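"""Per-drug prediction metrics, cross-validation and hyperparameter search.

Performance is always summarized per drug, then averaged over drugs:
Pearson correlation (PCC) and root-mean-squared error (RMSE) between
observed and predicted responses, plus the same metrics restricted to each
drug's sensitive and resistant cell lines (PCC_S/R, RMSE_S/R). Sensitive
and resistant cells are the first and fourth quartiles of that drug's
observed responses; which quartile means "sensitive" follows the response
direction (lower-is-sensitive for log-IC50, higher for activity area).

Cross-validation is entry-wise: the observed matrix cells — not drug rows
or cell-line columns — are partitioned into folds of near-equal size, each
fold is masked from training in turn, and the pooled held-out predictions
are scored.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from srmf.datamodel import Direction, ResponseMatrix, SimilarityMatrix, SrmfConfig
from srmf.factorization import fit, predict

__all__ = [
    "UndefinedMetricError",
    "MetricsReport",
    "FoldAssignment",
    "rmse_per_drug",
    "pcc_per_drug",
    "sensitive_resistant_split",
    "evaluate",
    "kfold_entries",
    "cross_validate",
    "grid_search",
    "default_lambda_grid",
    "relative_improvement",
]


def relative_improvement(score: float, baseline: float, higher_is_better: bool = True) -> float:
    """Percent improvement of ``score`` over ``baseline``.

    For higher-is-better metrics (PCC) this is 100·(score − baseline)/baseline;
    for lower-is-better metrics (RMSE), 100·(baseline − score)/baseline.
    """
    if baseline == 0:
        raise ValueError("baseline must be nonzero")
    delta = (score - baseline) if higher_is_better else (baseline - score)
    return 100.0 * delta / abs(baseline)

logger = logging.getLogger(__name__)

# printed hyperparameter grids: lambda_l in {2^-3..2^2},
# lambda_d and lambda_c in {2^-5..2^1, 0}
DEFAULT_LAMBDA_L_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-3, 3))
DEFAULT_LAMBDA_DC_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-5, 2)) + (0.0,)


class UndefinedMetricError(ValueError):
    """A metric is undefined for this drug (too few cells or zero variance)."""


def rmse_per_drug(observed: np.ndarray, predicted: np.ndarray) -> float:
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.size == 0 or observed.size != predicted.size:
        raise ValueError("observed and predicted must be non-empty vectors of equal length")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def pcc_per_drug(observed: np.ndarray, predicted: np.ndarray) -> float:
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.size != predicted.size:
        raise ValueError("observed and predicted must have equal length")
    if observed.size < 3:
        raise UndefinedMetricError(f"need >= 3 cells for a correlation, got {observed.size}")
    if np.std(observed) == 0 or np.std(predicted) == 0:
        raise UndefinedMetricError("zero-variance vector; correlation undefined")
    return float(stats.pearsonr(observed, predicted).statistic)


_MIN_CELLS_FOR_SPLIT = 8


def sensitive_resistant_split(R: ResponseMatrix, drug: str) -> tuple[list[str], list[str]]:
    """Split a drug's observed cells into sensitive and resistant quartile groups.

    Q1 and Q3 use the linear-interpolation quantile convention; cells with
    a value exactly at the quartile boundary are included in the extreme
    group. Returns (sensitive ids, resistant ids).
    """
    if drug not in R.drug_ids:
        raise ValueError(f"unknown drug {drug!r}")
    i = R.drug_ids.index(drug)
    obs = R.mask[i].astype(bool)
    if obs.sum() < _MIN_CELLS_FOR_SPLIT:
        raise UndefinedMetricError(
            f"drug {drug!r} has {int(obs.sum())} observed cells; "
            f"need >= {_MIN_CELLS_FOR_SPLIT} for a quartile split"
        )
    vals = R.values[i, obs]
    cells = [c for c, o in zip(R.cell_ids, obs) if o]
    q1, q3 = np.quantile(vals, [0.25, 0.75])
    if q1 == q3:
        raise UndefinedMetricError(f"drug {drug!r}: first and third quartiles coincide")
    low = [c for c, v in zip(cells, vals) if v <= q1]
    high = [c for c, v in zip(cells, vals) if v >= q3]
    if R.direction is Direction.LOWER_IS_SENSITIVE:
        return low, high
    return high, low


@dataclass
class MetricsReport:
    """Per-drug and drug-averaged prediction metrics.

    ``per_drug`` is indexed by drug id with columns pcc, rmse, pcc_sr,
    rmse_sr, n_cells_used (NaN where a metric is undefined);
    ``drug_averaged`` holds the arithmetic means over drugs with defined
    values; ``excluded`` counts drugs excluded per column, with reasons.
    """

    per_drug: pd.DataFrame
    drug_averaged: dict[str, float]
    excluded: dict[str, int] = field(default_factory=dict)

    _COLUMNS = ("pcc", "rmse", "pcc_sr", "rmse_sr")

    def to_csv(self, path) -> None:
        self.per_drug.to_csv(path, index_label="drug")


def _safe_metric(fn: Callable[..., float], *args) -> float:
    try:
        return fn(*args)
    except UndefinedMetricError:
        return float("nan")


def evaluate(
    R_true: ResponseMatrix,
    R_pred: np.ndarray,
    heldout: Iterable[tuple[int, int]] | np.ndarray,
) -> MetricsReport:
    """Score predictions on a set of held-out observed entries.

    Per-drug metrics use that drug's held-out entries only. S/R metrics are
    restricted to held-out entries whose cell line belongs to the drug's
    sensitive or resistant quartile group, with group membership determined
    from the observed values of the full matrix.
    """
    R_pred = np.asarray(R_pred, dtype=float)
    if R_pred.shape != R_true.shape:
        raise ValueError(
            f"prediction shape {R_pred.shape} does not match responses {R_true.shape}"
        )
    entries = np.asarray(list(map(tuple, np.asarray(heldout, dtype=int))), dtype=int).reshape(-1, 2)
    obs_mask = R_true.mask.astype(bool)
    for i, j in entries:
        if not obs_mask[i, j]:
            raise ValueError(f"held-out entry ({i}, {j}) is not an observed entry")

    by_drug: dict[int, list[int]] = {}
    for i, j in entries:
        by_drug.setdefault(int(i), []).append(int(j))

    rows = []
    excluded = {"no_heldout": 0, "pcc": 0, "pcc_sr": 0, "rmse_sr": 0}
    cell_pos = {c: j for j, c in enumerate(R_true.cell_ids)}
    for i, drug in enumerate(R_true.drug_ids):
        cols = by_drug.get(i)
        if not cols:
            excluded["no_heldout"] += 1
            continue
        cols_a = np.array(sorted(cols))
        obs = R_true.values[i, cols_a]
        pred = R_pred[i, cols_a]
        row = {
            "drug": drug,
            "pcc": _safe_metric(pcc_per_drug, obs, pred),
            "rmse": rmse_per_drug(obs, pred),
            "n_cells_used": len(cols_a),
        }
        try:
            sens, res = sensitive_resistant_split(R_true, drug)
            sr_cols = {cell_pos[c] for c in itertools.chain(sens, res)}
            keep = np.array([j in sr_cols for j in cols_a])
            if keep.any():
                row["pcc_sr"] = _safe_metric(pcc_per_drug, obs[keep], pred[keep])
                row["rmse_sr"] = rmse_per_drug(obs[keep], pred[keep])
            else:
                row["pcc_sr"] = row["rmse_sr"] = float("nan")
        except UndefinedMetricError:
            row["pcc_sr"] = row["rmse_sr"] = float("nan")
        if np.isnan(row["pcc"]):
            excluded["pcc"] += 1
        if np.isnan(row["pcc_sr"]):
            excluded["pcc_sr"] += 1
        if np.isnan(row["rmse_sr"]):
            excluded["rmse_sr"] += 1
        rows.append(row)

    per_drug = pd.DataFrame(
        rows, columns=["drug", "pcc", "rmse", "pcc_sr", "rmse_sr", "n_cells_used"]
    ).set_index("drug")
    with np.errstate(invalid="ignore"):
        drug_averaged = {
            col: float(np.nanmean(per_drug[col])) if per_drug[col].notna().any() else float("nan")
            for col in MetricsReport._COLUMNS
        }
    if excluded["no_heldout"]:
        logger.info("%d drugs had no held-out entries and were excluded", excluded["no_heldout"])
    return MetricsReport(per_drug=per_drug, drug_averaged=drug_averaged, excluded=excluded)


@dataclass
class FoldAssignment:
    """Entry-wise fold assignment over the observed cells of a response matrix."""

    entries: np.ndarray  # (n_observed, 2) row/col indices
    fold_ids: np.ndarray  # parallel array of fold labels in 1..k
    k: int
    seed: int

    def fold_entries(self, fold: int) -> np.ndarray:
        return self.entries[self.fold_ids == fold]


def kfold_entries(R: ResponseMatrix, k: int, seed: int = 0) -> FoldAssignment:
    """Randomly partition the observed entries into k folds of near-equal size."""
    if k < 2:
        raise ValueError("k must be >= 2")
    entries = R.observed_entries()
    if k > len(entries):
        raise ValueError(f"k={k} exceeds the {len(entries)} observed entries")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(entries))
    fold_ids = np.empty(len(entries), dtype=int)
    fold_ids[perm] = np.arange(len(entries)) % k + 1
    return FoldAssignment(entries=entries, fold_ids=fold_ids, k=k, seed=seed)


def _mask_entries(R: ResponseMatrix, entries: np.ndarray) -> ResponseMatrix:
    values = R.values.copy()
    mask = R.mask.copy()
    values[entries[:, 0], entries[:, 1]] = np.nan
    mask[entries[:, 0], entries[:, 1]] = 0
    return ResponseMatrix(list(R.drug_ids), list(R.cell_ids), values, mask, R.direction)


def cross_validate(
    R: ResponseMatrix,
    Sd: SimilarityMatrix | None,
    Sc: SimilarityMatrix | None,
    cfg: SrmfConfig,
    k: int = 10,
    seed: int = 0,
) -> MetricsReport:
    """Entry-wise k-fold cross-validation of the factorization.

    Each fold's entries are masked from training (response rescaling happens
    inside ``fit`` on the training entries only), the model is refitted, and
    the held-out predictions pooled across folds are scored with
    :func:`evaluate` against the observed values.
    """
    folds = kfold_entries(R, k, seed)
    pooled = np.full(R.shape, np.nan)
    for fold in range(1, k + 1):
        ent = folds.fold_entries(fold)
        R_train = _mask_entries(R, ent)
        factors, _ = fit(R_train, Sd, Sc, cfg)
        pred = predict(R_train, factors)
        pooled[ent[:, 0], ent[:, 1]] = pred[ent[:, 0], ent[:, 1]]
    return evaluate(R, pooled, folds.entries)


def default_lambda_grid() -> list[tuple[float, float, float]]:
    """The full printed hyperparameter grid, in lexicographic order (384 points)."""
    return [
        (ll, ld, lc)
        for ll in DEFAULT_LAMBDA_L_GRID
        for ld in DEFAULT_LAMBDA_DC_GRID
        for lc in DEFAULT_LAMBDA_DC_GRID
    ]


def grid_search(
    R: ResponseMatrix,
    Sd: SimilarityMatrix | None,
    Sc: SimilarityMatrix | None,
    grid: Sequence[tuple[float, float, float]],
    cfg_base: SrmfConfig,
    selection_metric: str = "pcc",
    k: int = 10,
    seed: int = 0,
) -> tuple[SrmfConfig, pd.DataFrame]:
    """Select (lambda_l, lambda_d, lambda_c) by cross-validation on ``R``.

    ``R`` should be training data only; each grid point is scored by
    internal k-fold cross-validation and the argbest of
    ``selection_metric`` (drug-averaged; pcc-like maximized, rmse-like
    minimized) wins, ties broken by first position in ``grid``.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if selection_metric not in MetricsReport._COLUMNS:
        raise ValueError(f"unknown selection metric {selection_metric!r}")
    maximize = selection_metric.startswith("pcc")
    rows = []
    best_score = -np.inf
    best_cfg = None
    for ll, ld, lc in grid:
        cfg = cfg_base.replace(lambda_l=ll, lambda_d=ld, lambda_c=lc)
        report = cross_validate(R, Sd, Sc, cfg, k=k, seed=seed)
        score = report.drug_averaged[selection_metric]
        rows.append({"lambda_l": ll, "lambda_d": ld, "lambda_c": lc, selection_metric: score})
        oriented = score if maximize else -score
        if np.isfinite(oriented) and oriented > best_score:
            best_score = oriented
            best_cfg = cfg
    if best_cfg is None:
        raise ValueError("selection metric undefined at every grid point")
    return best_cfg, pd.DataFrame(rows)
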