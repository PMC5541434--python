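"""Shared data model: response, fingerprint, expression, similarity and config types.

All matrix containers pair a numpy array with ordered id lists and validate
their invariants at construction time. The response matrix is oriented
drugs x cell lines throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np


class Direction(str, Enum):
    """Which end of the response scale means drug sensitivity.

    IC50-style measurements (GDSC, natural-log uM) are lower-is-sensitive;
    activity-area measurements (CCLE) are higher-is-sensitive.
    """

    LOWER_IS_SENSITIVE = "lower_is_sensitive"
    HIGHER_IS_SENSITIVE = "higher_is_sensitive"


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(x for x in ids if (x in seen) or seen.add(x))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what} id: {dup!r}")
    return ids


@dataclass
class ResponseMatrix:
    """Observed drug responses with a missing-entry mask.

    Parameters
    ----------
    drug_ids, cell_ids
        Row and column labels.
    values
        m x n float array; NaN exactly where the entry is unobserved.
    mask
        m x n binary array, 1 = observed. Derived from ``values`` when omitted.
    direction
        Sensitivity direction of the response units.
    """

    drug_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    direction: Direction = Direction.LOWER_IS_SENSITIVE

    def __post_init__(self) -> None:
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        self.cell_ids = _check_unique(self.cell_ids, "cell line")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.drug_ids), len(self.cell_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.cell_ids)} cell lines"
            )
        if self.mask is None:
            self.mask = (~np.isnan(self.values)).astype(np.uint8)
        else:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values shape")
            if not np.isin(self.mask, (0, 1)).all():
                raise ValueError("mask entries must be 0 or 1")
            self.mask = self.mask.astype(np.uint8)
        observed = self.mask.astype(bool)
        if not np.isfinite(self.values[observed]).all():
            raise ValueError("observed entries must be finite")
        if not np.isnan(self.values[~observed]).all():
            raise ValueError("mask marks an entry missing but values holds a number there")
        self.direction = Direction(self.direction)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())

    @property
    def n_missing(self) -> int:
        return int(self.mask.size - self.mask.sum())

    def observed_entries(self) -> np.ndarray:
        """Indices of observed cells as an (n_observed, 2) array of (row, col)."""
        return np.argwhere(self.mask.astype(bool))

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(
            list(self.drug_ids),
            list(self.cell_ids),
            self.values.copy(),
            self.mask.copy(),
            self.direction,
        )


@dataclass
class FingerprintMatrix:
    """Binary chemical-fingerprint bit table, drugs x fingerprint bits."""

    drug_ids: list[str]
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        self.bits = np.asarray(self.bits)
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.drug_ids):
            raise ValueError("bits must be a 2-D array with one row per drug")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("fingerprint entries must be 0 or 1")
        self.bits = self.bits.astype(np.uint8)


@dataclass
class ExpressionMatrix:
    """Gene x cell-line expression levels."""

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.cell_ids = _check_unique(self.cell_ids, "cell line")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("expression shape does not match id lists")
        if not np.isfinite(self.values).all():
            raise ValueError("expression entries must be finite")


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over drugs (Sd) or cell lines (Sc)."""

    ids: list[str]
    values: np.ndarray

    _SYM_TOL = 1e-12

    def __post_init__(self) -> None:
        self.ids = _check_unique(self.ids, "entity")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity matrix must be {n}x{n}")
        if not np.allclose(self.values, self.values.T, atol=self._SYM_TOL, rtol=0):
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-9, rtol=0):
            raise ValueError("similarity matrix diagonal must equal 1")

    def aligned_to(self, ids: Sequence[str]) -> np.ndarray:
        """Values reindexed to the given id order; error on unknown ids."""
        pos = {x: i for i, x in enumerate(self.ids)}
        try:
            idx = np.array([pos[str(x)] for x in ids])
        except KeyError as e:
            raise ValueError(f"id {e.args[0]!r} not present in similarity matrix") from None
        return self.values[np.ix_(idx, idx)]


@dataclass
class MutationProfile:
    """Binary mutation / amplification calls, cell lines x genes."""

    cell_ids: list[str]
    gene_ids: list[str]
    status: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = _check_unique(self.cell_ids, "cell line")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.status = np.asarray(self.status)
        if self.status.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("status shape does not match id lists")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("mutation status entries must be 0 or 1")
        self.status = self.status.astype(np.uint8)

    def gene_status(self, gene: str) -> dict[str, int]:
        if gene not in self.gene_ids:
            raise ValueError(f"gene {gene!r} absent from mutation profile")
        j = self.gene_ids.index(gene)
        return {c: int(s) for c, s in zip(self.cell_ids, self.status[:, j])}


@dataclass
class SrmfConfig:
    """Hyperparameters of the factorization.

    K is the latent dimensionality; lambda_l weights the L2 (Tikhonov) term,
    lambda_d / lambda_c the drug- and cell-similarity regularizers. tol is
    the relative objective-change stopping criterion.
    """

    K: int = 45
    lambda_l: float = 0.125
    lambda_d: float = 0.0
    lambda_c: float = 0.125
    tol: float = 1e-4
    max_iter: int = 500
    seed: int = 0
    init: str = "svd"  # "svd" (deterministic) or "random"

    def __post_init__(self) -> None:
        if int(self.K) != self.K or self.K <= 0:
            raise ValueError(f"K must be a positive integer, got {self.K}")
        self.K = int(self.K)
        for name in ("lambda_l", "lambda_d", "lambda_c"):
            v = float(getattr(self, name))
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
            setattr(self, name, v)
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if int(self.max_iter) != self.max_iter or self.max_iter <= 0:
            raise ValueError("max_iter must be a positive integer")
        self.max_iter = int(self.max_iter)
        self.seed = int(self.seed)
        if self.init not in ("svd", "random"):
            raise ValueError(f"init must be 'svd' or 'random', got {self.init!r}")

    def validate_for_shape(self, m: int, n: int) -> "SrmfConfig":
        if self.K > min(m, n):
            raise ValueError(f"K={self.K} exceeds min(m, n) = {min(m, n)} for a {m}x{n} problem")
        return self

    def replace(self, **kwargs) -> "SrmfConfig":
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}  # type: ignore[attr-defined]
        d.update(kwargs)
        return SrmfConfig(**d)
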