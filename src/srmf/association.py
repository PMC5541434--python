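"""Genotype-sensitivity association tests on observed and completed responses.

Cell lines are grouped by the mutation / amplification status of a single
gene and the one-sided Mann-Whitney U test asks whether mutated lines are
more sensitive (or, with the alternative flipped, more resistant) than
wild-type lines. The same test can be run twice — once on observed
responses alone and once after concatenating predicted responses for
unassayed lines — to inspect the gain of signal contributed by matrix
completion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from srmf.datamodel import Direction, MutationProfile
from srmf.stats import mann_whitney_one_sided
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationRecord",
    "genotype_response_test",
    "combined_vs_observed_test",
    "benjamini_hochberg",
]


@dataclass
class AssociationRecord:
    """Result of one genotype vs response comparison."""

    gene: str
    n_mut: int
    n_wt: int
    median_mut: float
    median_wt: float
    u: float
    p: float
    alternative: str


def _sensitivity_scores(values: np.ndarray, direction: Direction) -> np.ndarray:
    # orient so that larger score always means more sensitive
    if Direction(direction) is Direction.LOWER_IS_SENSITIVE:
        return -values
    return values


def genotype_response_test(
    responses: Mapping[str, float],
    mutation: MutationProfile,
    gene: str,
    direction: Direction | str,
    alternative: str,
) -> AssociationRecord:
    """Test whether mutated cell lines respond differently to a drug.

    Parameters
    ----------
    responses
        Response value per cell id (log-IC50 or activity area).
    alternative
        ``"sensitive"`` tests whether mutated lines are more sensitive than
        wild-type (lower IC50 when direction is lower-is-sensitive);
        ``"resistant"`` tests the opposite direction.
    """
    if alternative not in ("sensitive", "resistant"):
        raise ValueError(f"alternative must be 'sensitive' or 'resistant', got {alternative!r}")
    status = mutation.gene_status(gene)
    mut_vals, wt_vals = [], []
    for cell, value in responses.items():
        if cell not in status:
            raise ValueError(f"cell line {cell!r} absent from mutation profile")
        (mut_vals if status[cell] else wt_vals).append(float(value))
    if not mut_vals or not wt_vals:
        which = "mutated" if not mut_vals else "wild-type"
        raise ValueError(f"gene {gene!r}: {which} group is empty")
    mut_a, wt_a = np.array(mut_vals), np.array(wt_vals)
    mut_s = _sensitivity_scores(mut_a, Direction(direction))
    wt_s = _sensitivity_scores(wt_a, Direction(direction))
    side = "greater" if alternative == "sensitive" else "less"
    test = mann_whitney_one_sided(mut_s, wt_s, alternative=side)
    return AssociationRecord(
        gene=gene,
        n_mut=len(mut_a),
        n_wt=len(wt_a),
        median_mut=float(np.median(mut_a)),
        median_wt=float(np.median(wt_a)),
        u=test.u,
        p=test.p,
        alternative=alternative,
    )


def combined_vs_observed_test(
    observed: Mapping[str, float],
    predicted: Mapping[str, float],
    mutation: MutationProfile,
    gene: str,
    direction: Direction | str,
    alternative: str,
) -> tuple[AssociationRecord, AssociationRecord]:
    """Run the genotype test on observed responses alone and augmented with
    predicted responses for unassayed cell lines.

    Returns (observed-only record, observed+predicted record). The
    predicted set must be disjoint from the observed set.
    """
    overlap = set(observed) & set(predicted)
    if overlap:
        raise ValueError(f"predicted responses overlap observed cell lines: {sorted(overlap)[:3]}")
    obs_rec = genotype_response_test(observed, mutation, gene, direction, alternative)
    combined = dict(observed)
    combined.update(predicted)
    comb_rec = genotype_response_test(combined, mutation, gene, direction, alternative)
    return obs_rec, comb_rec


def benjamini_hochberg(pvalues: Mapping[str, float], alpha: float = 0.05) -> dict[str, float]:
    """BH-adjusted p-values for a panel of single-gene tests (opt-in)."""
    genes = list(pvalues)
    _, adj, _, _ = multipletests([pvalues[g] for g in genes], alpha=alpha, method="fdr_bh")
    return dict(zip(genes, adj))
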