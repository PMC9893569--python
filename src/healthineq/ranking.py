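"""Weighted fractional income ranks.

Every concentration-index statistic in this package is driven by the fractional
rank ``R_i`` of each person in the income ordering: with the sample sorted by
household income per capita (poorest to richest), the rank of person *i* is the
cumulative survey weight of everyone poorer plus half of person *i*'s own
weight, divided by the total weight.  Under equal weights and distinct incomes
this reduces to the textbook ``R_i = (i - 0.5) / n``.  Ranks live strictly
inside (0, 1) and their weighted mean is exactly 0.5 — a conservation property
the index formulas rely on.

Tied incomes share the weighted midpoint rank of their tie block, so no
statistic downstream depends on the arbitrary ordering of records within a
mass point of the income distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import AlignmentError

__all__ = ["RankedSample", "fractional_rank"]


@dataclass(frozen=True)
class RankedSample:
    """Fractional ranks aligned index-for-index with the input records.

    Attributes
    ----------
    ranks
        Fractional ranks ``R_i`` in (0, 1), in the original input order.
    order_permutation
        Indices that sort the input by income (stable sort).
    total_weight
        Sum of the survey weights.
    tie_groups
        Index sets (original order) of records sharing an income value;
        only groups with two or more members are listed.
    """

    ranks: np.ndarray
    order_permutation: np.ndarray
    total_weight: float
    tie_groups: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.ranks.shape[0]


def fractional_rank(income_pc, weights) -> RankedSample:
    """Compute weighted fractional ranks of persons ordered by income per capita.

    Parameters
    ----------
    income_pc
        Non-negative household income per capita, one value per person.
    weights
        Strictly positive survey weights, same length.

    Returns
    -------
    RankedSample
        Ranks satisfy ``R_i = (cum. weight before i + w_i / 2) / W`` with tied
        incomes receiving the weighted midpoint rank of their tie block.

    Raises
    ------
    AlignmentError
        If the two vectors differ in length.
    ValueError
        On empty input, non-positive weights, or NaN/negative incomes
        (missing income must be resolved by the caller, not here).
    """
    income = np.asarray(income_pc, dtype=float)
    w = np.asarray(weights, dtype=float)
    if income.ndim != 1 or w.ndim != 1:
        raise ValueError("income_pc and weights must be one-dimensional")
    if income.shape[0] != w.shape[0]:
        raise AlignmentError(
            f"income_pc has length {income.shape[0]} but weights has length {w.shape[0]}"
        )
    if income.shape[0] == 0:
        raise ValueError("cannot rank an empty sample")
    if np.isnan(income).any():
        raise ValueError("income_pc contains NaN; resolve missingness before ranking")
    if not np.isfinite(income).all():
        raise ValueError("income_pc contains non-finite values")
    if (income < 0).any():
        raise ValueError("income_pc must be non-negative")
    if not np.isfinite(w).all() or (w <= 0).any():
        raise ValueError("weights must be strictly positive and finite")

    order = np.argsort(income, kind="stable")
    inc_sorted = income[order]
    w_sorted = w[order]
    total = float(w_sorted.sum())

    # tie blocks over the sorted incomes
    new_block = np.empty(inc_sorted.shape[0], dtype=bool)
    new_block[0] = True
    np.not_equal(inc_sorted[1:], inc_sorted[:-1], out=new_block[1:])
    block_id = np.cumsum(new_block) - 1
    n_blocks = block_id[-1] + 1
    block_w = np.bincount(block_id, weights=w_sorted, minlength=n_blocks)
    cum_before = np.concatenate(([0.0], np.cumsum(block_w)))[:n_blocks]
    block_rank = (cum_before + block_w / 2.0) / total

    ranks = np.empty_like(income)
    ranks[order] = block_rank[block_id]

    tie_groups = []
    if n_blocks < inc_sorted.shape[0]:
        counts = np.bincount(block_id, minlength=n_blocks)
        starts = np.concatenate(([0], np.cumsum(counts)))[:n_blocks]
        for b in np.nonzero(counts > 1)[0]:
            tie_groups.append(np.sort(order[starts[b] : starts[b] + counts[b]]))

    return RankedSample(
        ranks=ranks,
        order_permutation=order,
        total_weight=total,
        tie_groups=tie_groups,
    )
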