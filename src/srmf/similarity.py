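"""Similarity construction and structure-based drug clustering.

Drug similarity Sd is the Jaccard (Tanimoto) coefficient between binary
chemical-fingerprint bit sets; cell-line similarity Sc is the Pearson
correlation between gene expression profiles. Drugs can additionally be
clustered hierarchically on the 1 - Jaccard distance, and within- versus
between-group correlation contrasts are tested with the one-sided
Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from srmf.datamodel import ExpressionMatrix, FingerprintMatrix, SimilarityMatrix
from srmf.stats import MannWhitneyResult, mann_whitney_one_sided

__all__ = [
    "jaccard_similarity",
    "pearson_similarity",
    "cluster_drugs",
    "group_correlation_comparison",
    "GroupComparison",
]


def jaccard_similarity(F: FingerprintMatrix) -> SimilarityMatrix:
    """Pairwise Jaccard coefficient |A ∩ B| / |A ∪ B| of fingerprint bit sets.

    Raises if any drug has an all-zero fingerprint (the coefficient is
    undefined for an empty bit set).
    """
    bits = F.bits.astype(float)
    set_sizes = bits.sum(axis=1)
    if (set_sizes == 0).any():
        drug = F.drug_ids[int(np.argmax(set_sizes == 0))]
        raise ValueError(f"drug {drug!r} has an all-zero fingerprint; Jaccard is undefined")
    inter = bits @ bits.T
    union = set_sizes[:, None] + set_sizes[None, :] - inter
    S = inter / union
    np.fill_diagonal(S, 1.0)
    S = (S + S.T) / 2.0
    return SimilarityMatrix(list(F.drug_ids), S)


def pearson_similarity(E: ExpressionMatrix, normalize: bool = False) -> SimilarityMatrix:
    """Pairwise Pearson correlation of cell-line expression profiles.

    With ``normalize=True`` each gene is z-scored across cell lines first
    (genes with zero variance are dropped), mirroring the normalisation used
    before profile-correlation analyses.
    """
    X = E.values
    if E.values.shape[0] < 2:
        raise ValueError("need at least 2 genes to correlate profiles")
    if normalize:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        keep = sd.ravel() > 0
        if not keep.any():
            raise ValueError("all genes have zero variance across cell lines")
        X = (X[keep] - mu[keep]) / sd[keep]
    var = X.var(axis=0)
    if (var == 0).any():
        cell = E.cell_ids[int(np.argmax(var == 0))]
        raise ValueError(f"cell line {cell!r} has a zero-variance profile")
    S = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(S, 1.0)
    S = (S + S.T) / 2.0
    return SimilarityMatrix(list(E.cell_ids), S)


def cluster_drugs(
    F: FingerprintMatrix, distance_threshold: float, method: str = "average"
) -> dict[str, int]:
    """Hierarchically cluster drugs on the 1 - Jaccard structural distance.

    The dendrogram is cut at ``distance_threshold`` (cophenetic distance),
    yielding one integer cluster label per drug. Linkage defaults to
    average; single and complete are also accepted.
    """
    if not 0.0 <= distance_threshold <= 1.0:
        raise ValueError(f"distance_threshold must lie in [0, 1], got {distance_threshold}")
    if method not in ("single", "complete", "average"):
        raise ValueError(f"unsupported linkage {method!r}")
    S = jaccard_similarity(F)
    D = 1.0 - S.values
    np.fill_diagonal(D, 0.0)
    if len(F.drug_ids) == 1:
        return {F.drug_ids[0]: 1}
    Z = linkage(squareform(D, checks=False), method=method)
    labels = fcluster(Z, t=distance_threshold, criterion="distance")
    return {drug: int(lab) for drug, lab in zip(F.drug_ids, labels)}


@dataclass
class GroupComparison:
    """Within- vs between-group similarity values and their rank test."""

    within: np.ndarray
    between: np.ndarray
    test: MannWhitneyResult

    @property
    def p(self) -> float:
        return self.test.p


def group_correlation_comparison(
    profile_corr: SimilarityMatrix, group_labels: Mapping[str, object]
) -> GroupComparison:
    """Compare profile correlations within groups against those between groups.

    Uses each unordered pair once (strict lower triangle, no self-pairs) and
    tests the one-sided alternative that within-group correlations exceed
    between-group correlations.
    """
    labels = {str(k): v for k, v in group_labels.items()}
    missing = [i for i in profile_corr.ids if i not in labels]
    if missing:
        raise ValueError(f"no group label for {missing[0]!r}")
    if len(set(labels[i] for i in profile_corr.ids)) < 2:
        raise ValueError("need at least two groups to compare within vs between")
    S = profile_corr.values
    within, between = [], []
    ids = profile_corr.ids
    for i in range(1, len(ids)):
        for j in range(i):
            (within if labels[ids[i]] == labels[ids[j]] else between).append(S[i, j])
    if not within:
        raise ValueError("no within-group pairs: every group has fewer than 2 members")
    if not between:
        raise ValueError("no between-group pairs")
    within_a, between_a = np.array(within), np.array(between)
    test = mann_whitney_one_sided(within_a, between_a, alternative="greater")
    return GroupComparison(within=within_a, between=between_a, test=test)
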