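"""Readers and writers for all matrix artifacts and the run configuration.

Every matrix travels as a delimited text table (comma or tab, auto-detected
from the header line) with a header row of column ids and a first column of
row ids. Responses are drugs x cell lines; missing entries carry the NA
token (default ``"NA"``).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from srmf.datamodel import (
    Direction,
    ExpressionMatrix,
    FingerprintMatrix,
    MutationProfile,
    ResponseMatrix,
    SimilarityMatrix,
    SrmfConfig,
)

__all__ = [
    "read_response_matrix",
    "write_response_matrix",
    "write_predictions",
    "read_fingerprint_matrix",
    "read_expression_matrix",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_mutation_profile",
    "load_config",
]


def _detect_sep(path: str | Path) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: file is empty")
    return "\t" if "\t" in header else ","


def _read_labelled_table(path: str | Path) -> pd.DataFrame:
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: table has no data rows or columns")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _to_float(df: pd.DataFrame, na_token: str | None, path: str | Path) -> np.ndarray:
    """Parse a string table to floats, NaN at the NA token, naming offenders."""
    out = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col].to_numpy()
        if na_token is not None:
            is_na = raw == na_token
        else:
            is_na = np.zeros(len(raw), dtype=bool)
        parsed = pd.to_numeric(pd.Series(np.where(is_na, "nan", raw)), errors="coerce").to_numpy()
        bad = np.isnan(parsed) & ~is_na
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"{path}: non-numeric value {raw[i]!r} at row {df.index[i]!r}, column {col!r}"
            )
        out[:, j] = parsed
    return out


def read_response_matrix(
    path: str | Path,
    direction: Direction | str = Direction.LOWER_IS_SENSITIVE,
    na_token: str = "NA",
    transpose: bool = False,
) -> ResponseMatrix:
    """Read a drugs x cell-lines response table.

    Parameters
    ----------
    direction
        Sensitivity direction of the response units (lower-is-sensitive for
        log-IC50, higher-is-sensitive for activity area).
    na_token
        Cell content marking a missing response.
    transpose
        Set when the file is oriented cell lines x drugs.
    """
    df = _read_labelled_table(path)
    if transpose:
        df = df.T
    values = _to_float(df, na_token, path)
    return ResponseMatrix(list(df.index), list(df.columns), values, direction=Direction(direction))


def write_response_matrix(
    R: ResponseMatrix, path: str | Path, na_token: str = "NA", sep: str = ","
) -> None:
    df = pd.DataFrame(R.values, index=R.drug_ids, columns=R.cell_ids)
    df.to_csv(path, sep=sep, na_rep=na_token)


def write_predictions(
    R: ResponseMatrix, predicted: np.ndarray, path: str | Path, sep: str = ","
) -> None:
    """Write the completed response matrix plus a companion observed-mask file.

    The prediction table round-trips through :func:`read_response_matrix`
    with zero missing entries; ``<path>.mask`` records which entries were
    observed in ``R`` so predicted-only cells stay distinguishable.
    """
    predicted = np.asarray(predicted, dtype=float)
    if predicted.shape != R.shape:
        raise ValueError(f"predicted shape {predicted.shape} does not match response {R.shape}")
    if not np.isfinite(predicted).all():
        raise ValueError("predicted matrix contains non-finite entries")
    pd.DataFrame(predicted, index=R.drug_ids, columns=R.cell_ids).to_csv(path, sep=sep)
    mask_path = f"{os.fspath(path)}.mask"
    pd.DataFrame(R.mask, index=R.drug_ids, columns=R.cell_ids).to_csv(mask_path, sep=sep)


def read_fingerprint_matrix(path: str | Path) -> FingerprintMatrix:
    df = _read_labelled_table(path)
    values = _to_float(df, None, path)
    return FingerprintMatrix(list(df.index), values)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    df = _read_labelled_table(path)
    values = _to_float(df, None, path)
    return ExpressionMatrix(list(df.index), list(df.columns), values)


def read_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    df = _read_labelled_table(path)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: similarity table row and column ids differ")
    values = _to_float(df, None, path)
    return SimilarityMatrix(list(df.index), values)


def write_similarity_matrix(S: SimilarityMatrix, path: str | Path, sep: str = ",") -> None:
    pd.DataFrame(S.values, index=S.ids, columns=S.ids).to_csv(path, sep=sep)


def read_mutation_profile(path: str | Path) -> MutationProfile:
    df = _read_labelled_table(path)
    values = _to_float(df, None, path)
    return MutationProfile(list(df.index), list(df.columns), values)


_CONFIG_KEYS = {
    "K",
    "lambda_l",
    "lambda_d",
    "lambda_c",
    "tol",
    "max_iter",
    "seed",
    "init",
}


def load_config(path: str | Path | None, shape: tuple[int, int] | None = None) -> SrmfConfig:
    """Load a flat key: value config file (YAML mapping); missing keys default.

    When ``shape`` is given the K <= min(m, n) invariant is enforced.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        unknown = set(loaded) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        data = loaded
    cfg = SrmfConfig(**data)
    if shape is not None:
        cfg.validate_for_shape(*shape)
    return cfg
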