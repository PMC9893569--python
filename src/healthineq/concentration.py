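"""Concentration curves and concentration indices for health variables.

The standard concentration index of a health variable ``h`` against the income
fractional rank ``R`` is

    C(h) = (1 / h_bar) * sum_i (w_i / W) * h_i * (2 R_i - 1)
         = 2 * cov_w(h, R) / h_bar,

twice the (weighted) covariance between the variable and the fractional rank,
scaled by the mean.  It equals twice the area between the concentration curve
and the 45-degree equality line: positive values mean the variable is
concentrated among the rich (pro-rich), negative among the poor (pro-poor).

For bounded — especially binary — variables the standard index suffers from
the "bounds issue": its attainable range shrinks with the mean, so two
populations with equal C but different utilisation rates reflect different
amounts of inequality.  The Erreygers correction

    E(h) = 4 h_bar C(h) / (h_max - h_min) = 8 cov_w(h, R) / (h_max - h_min)

restores mirror symmetry (E(1-h) = -E(h)), transfer sensitivity, and
invariance to level shifts and positive linear rescaling of ``h``.  The
Wagstaff normalisation is the multiplicative alternative,

    W(h) = (h_max - h_min) h_bar C(h) / ((h_max - h_bar)(h_bar - h_min)),

which for a 0/1 outcome simplifies to C(h) / (1 - h_bar) and relates to
Erreygers through E = 4 h_bar (1 - h_bar) W.

Standard errors come either from the "convenient regression" — a weighted
least-squares fit of a transformed outcome on the fractional rank whose slope
*is* the index, with heteroskedasticity-robust (optionally cluster-robust)
standard errors — or from a percentile bootstrap that re-ranks every resample
and resamples whole clusters when a cluster id is supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import stats

from .exceptions import AlignmentError, UndefinedIndexError
from .ranking import RankedSample, fractional_rank

__all__ = [
    "OutcomeBounds",
    "IndexEstimate",
    "ConcentrationCurve",
    "concentration_index",
    "erreygers_index",
    "wagstaff_index",
    "concentration_curve",
    "index_ci",
    "classify_inequality",
]

_VARIANTS = ("standard", "erreygers", "wagstaff")


@dataclass(frozen=True)
class OutcomeBounds:
    """Feasible range of the health variable; binary outcomes use (0, 1)."""

    h_min: float = 0.0
    h_max: float = 1.0

    def __post_init__(self):
        if not self.h_max > self.h_min:
            raise ValueError(f"h_max ({self.h_max}) must exceed h_min ({self.h_min})")

    @property
    def span(self) -> float:
        return self.h_max - self.h_min


@dataclass(frozen=True)
class IndexEstimate:
    """A concentration-index estimate with optional uncertainty.

    ``value`` follows the convention positive = pro-rich, negative = pro-poor.
    """

    variant: str
    value: float
    mean_outcome: float
    n_effective: float
    se: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    ci_method: str = "none"
    ci_level: float = 0.95
    p_value: Optional[float] = None

    def __post_init__(self):
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown index variant {self.variant!r}")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")

    @property
    def stars(self) -> str:
        """Significance stars: * p<0.1, ** p<0.05, *** p<0.01."""
        if self.p_value is None:
            return ""
        if self.p_value < 0.01:
            return "***"
        if self.p_value < 0.05:
            return "**"
        if self.p_value < 0.1:
            return "*"
        return ""


@dataclass(frozen=True)
class ConcentrationCurve:
    """Piecewise-linear concentration curve.

    ``points`` is an (m, 2) array of (cumulative population share, cumulative
    outcome share) pairs, starting at (0, 0) and ending at (1, 1), both
    coordinates non-decreasing.  Tied incomes are collapsed into a single
    segment so the curve is invariant to within-tie ordering.
    """

    points: np.ndarray

    def index_from_area(self) -> float:
        """Twice the signed area between the diagonal and the curve.

        Equals the standard concentration index (trapezoid rule is exact for
        the piecewise-linear curve built over income tie blocks).
        """
        x = self.points[:, 0]
        y = self.points[:, 1]
        # 2 * (1/2 - integral of curve) = 1 - sum of trapezoids
        return 1.0 - float(np.sum(np.diff(x) * (y[1:] + y[:-1])))

    def plot(self, ax=None, label=None):
        """Draw the curve and the equality line on a matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot([0, 1], [0, 1], linestyle="--", color="grey", linewidth=1)
        ax.plot(self.points[:, 0], self.points[:, 1], label=label)
        ax.set_xlabel("Cumulative population share (poorest to richest)")
        ax.set_ylabel("Cumulative outcome share")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        return ax


def _aligned(h, ranked: RankedSample, weights):
    h = np.asarray(h, dtype=float)
    w = np.asarray(weights, dtype=float)
    if h.shape[0] != ranked.n or w.shape[0] != ranked.n:
        raise AlignmentError(
            f"outcome ({h.shape[0]}), weights ({w.shape[0]}) and ranks "
            f"({ranked.n}) must be aligned"
        )
    if not np.isfinite(h).all():
        raise ValueError("outcome contains NaN or infinite values")
    if (w <= 0).any():
        raise ValueError("weights must be strictly positive")
    return h, w


def _weighted_mean(x, w):
    return float(np.sum(w * x) / np.sum(w))


def _cov_with_rank(h, ranks, w):
    """Weighted covariance of h with the fractional rank (whose mean is 0.5)."""
    wn = w / w.sum()
    hbar = np.sum(wn * h)
    return float(np.sum(wn * (h - hbar) * (ranks - 0.5)))


def _kish_n(w):
    return float(w.sum() ** 2 / np.sum(w**2))


def concentration_index(h, ranked: RankedSample, weights) -> IndexEstimate:
    """Standard concentration index ``C(h) = 2 cov_w(h, R) / h_bar``.

    Defined for non-negative outcomes with a positive weighted mean; with
    equal weights and distinct incomes it reproduces the textbook direct sum
    ``(1/n) sum_i (h_i / h_bar)(2 R_i - 1)`` exactly.
    """
    h, w = _aligned(h, ranked, weights)
    if (h < 0).any():
        raise ValueError("standard concentration index requires a non-negative outcome")
    hbar = _weighted_mean(h, w)
    if hbar <= 0:
        raise UndefinedIndexError("outcome has zero weighted mean; C(h) is undefined")
    value = 2.0 * _cov_with_rank(h, ranked.ranks, w) / hbar
    return IndexEstimate(
        variant="standard", value=value, mean_outcome=hbar, n_effective=_kish_n(w)
    )


def erreygers_index(
    h, ranked: RankedSample, weights, bounds: OutcomeBounds = OutcomeBounds()
) -> IndexEstimate:
    """Erreygers-corrected index ``E(h) = 8 cov_w(h, R) / (h_max - h_min)``.

    For a 0/1 outcome this is ``4 h_bar C(h)``.  The outcome must lie within
    the declared bounds.
    """
    h, w = _aligned(h, ranked, weights)
    if (h < bounds.h_min).any() or (h > bounds.h_max).any():
        raise ValueError(
            f"outcome values escape the declared bounds [{bounds.h_min}, {bounds.h_max}]"
        )
    value = 8.0 * _cov_with_rank(h, ranked.ranks, w) / bounds.span
    return IndexEstimate(
        variant="erreygers",
        value=value,
        mean_outcome=_weighted_mean(h, w),
        n_effective=_kish_n(w),
    )


def wagstaff_index(
    h, ranked: RankedSample, weights, bounds: OutcomeBounds = OutcomeBounds()
) -> IndexEstimate:
    """Wagstaff-normalised index; for binary outcomes ``W = C(h) / (1 - h_bar)``.

    Undefined when the mean sits at either bound (everyone or no one uses the
    service).  Related to Erreygers by ``E = 4 h_bar (1 - h_bar) W`` for 0/1
    outcomes.
    """
    h, w = _aligned(h, ranked, weights)
    if (h < bounds.h_min).any() or (h > bounds.h_max).any():
        raise ValueError(
            f"outcome values escape the declared bounds [{bounds.h_min}, {bounds.h_max}]"
        )
    hbar = _weighted_mean(h, w)
    if hbar <= bounds.h_min or hbar >= bounds.h_max:
        raise UndefinedIndexError(
            f"Wagstaff index undefined: mean outcome {hbar} sits at a bound"
        )
    cov = _cov_with_rank(h, ranked.ranks, w)
    value = (
        2.0 * cov * bounds.span / ((bounds.h_max - hbar) * (hbar - bounds.h_min))
    )
    return IndexEstimate(
        variant="wagstaff", value=value, mean_outcome=hbar, n_effective=_kish_n(w)
    )


def concentration_curve(h, ranked: RankedSample, weights) -> ConcentrationCurve:
    """Concentration curve: cumulative outcome share against cumulative
    population share, the population ranked from poorest to richest."""
    h, w = _aligned(h, ranked, weights)
    if (h < 0).any():
        raise ValueError("concentration curve requires a non-negative outcome")
    total_h = np.sum(w * h)
    if total_h <= 0:
        raise UndefinedIndexError("total weighted outcome is zero; curve undefined")

    order = ranked.order_permutation
    w_s = w[order]
    wh_s = (w * h)[order]
    r_s = ranked.ranks[order]
    # collapse income tie blocks (identical rank along the sorted order)
    new_block = np.empty(r_s.shape[0], dtype=bool)
    new_block[0] = True
    np.not_equal(r_s[1:], r_s[:-1], out=new_block[1:])
    block_id = np.cumsum(new_block) - 1
    n_blocks = block_id[-1] + 1
    bw = np.bincount(block_id, weights=w_s, minlength=n_blocks)
    bwh = np.bincount(block_id, weights=wh_s, minlength=n_blocks)

    x = np.concatenate(([0.0], np.cumsum(bw) / w.sum()))
    y = np.concatenate(([0.0], np.cumsum(bwh) / total_h))
    x[-1] = 1.0
    y[-1] = 1.0
    return ConcentrationCurve(points=np.column_stack([x, y]))


def _point_estimate(h, ranked, w, variant, bounds):
    if variant == "standard":
        return concentration_index(h, ranked, w)
    if variant == "erreygers":
        return erreygers_index(h, ranked, w, bounds)
    if variant == "wagstaff":
        return wagstaff_index(h, ranked, w, bounds)
    raise ValueError(f"unknown index variant {variant!r}")


def _convenient_lhs(h, ranked, w, variant, bounds):
    """Transformed outcome whose WLS slope on the rank equals the index."""
    wn = w / w.sum()
    var_r = float(np.sum(wn * (ranked.ranks - 0.5) ** 2))
    hbar = _weighted_mean(h, w)
    if variant == "standard":
        return 2.0 * var_r * h / hbar
    if variant == "erreygers":
        return 8.0 * var_r * h / bounds.span
    # wagstaff
    denom = (bounds.h_max - hbar) * (hbar - bounds.h_min)
    return 2.0 * var_r * h * bounds.span / denom


def index_ci(
    h,
    ranked: RankedSample,
    weights,
    variant: str = "erreygers",
    method: str = "robust_regression",
    ci_level: float = 0.95,
    n_boot: int = 1000,
    seed: Optional[int] = None,
    cluster_id=None,
    bounds: OutcomeBounds = OutcomeBounds(),
    income_pc=None,
) -> IndexEstimate:
    """Attach a standard error and confidence interval to an index estimate.

    Parameters
    ----------
    method
        ``"robust_regression"`` — convenient WLS regression of the transformed
        outcome on the fractional rank; the slope reproduces the direct
        formula to 1e-10 and its heteroskedasticity-robust (cluster-robust if
        ``cluster_id`` is given) standard error yields a normal-theory CI.
        ``"bootstrap"`` — percentile interval over ``n_boot`` resamples with
        ranks recomputed inside every resample; whole clusters are resampled
        when ``cluster_id`` is given.  Requires ``income_pc`` (needed to
        re-rank) and ``seed``.
    income_pc
        Raw incomes, required for the bootstrap (ranks must be recomputed per
        resample).

    Degenerate bootstrap resamples (undefined index, e.g. an all-zero
    outcome) are redrawn; exceeding ten redraws per requested resample is an
    error.
    """
    h, w = _aligned(h, ranked, weights)
    est = _point_estimate(h, ranked, w, variant, bounds)

    if method == "robust_regression":
        import statsmodels.api as sm

        lhs = _convenient_lhs(h, ranked, w, variant, bounds)
        X = sm.add_constant(ranked.ranks)
        model = sm.WLS(lhs, X, weights=w)
        if cluster_id is not None:
            groups = np.asarray(cluster_id)
            if groups.shape[0] != ranked.n:
                raise AlignmentError("cluster_id must align with the sample")
            res = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
        else:
            res = model.fit(cov_type="HC1")
        slope = float(res.params[1])
        if abs(slope - est.value) > 1e-8 * max(1.0, abs(est.value)):
            raise AssertionError(
                "convenient-regression slope disagrees with the direct formula"
            )
        se = float(res.bse[1])
        if se == 0.0:
            ci_lo, ci_hi, pval = est.value, est.value, 1.0
        else:
            z = stats.norm.ppf(0.5 + ci_level / 2.0)
            ci_lo = est.value - z * se
            ci_hi = est.value + z * se
            pval = 2.0 * stats.norm.sf(abs(est.value) / se)
        return replace(
            est,
            se=se,
            ci_low=ci_lo,
            ci_high=ci_hi,
            ci_method="robust_regression",
            ci_level=ci_level,
            p_value=pval,
        )

    if method == "bootstrap":
        if n_boot < 50:
            raise ValueError("bootstrap requires n_boot >= 50")
        if seed is None:
            raise ValueError("bootstrap requires an explicit seed")
        if income_pc is None:
            raise ValueError("bootstrap requires income_pc to recompute ranks")
        income = np.asarray(income_pc, dtype=float)
        if income.shape[0] != ranked.n:
            raise AlignmentError("income_pc must align with the sample")
        rng = np.random.default_rng(seed)

        if cluster_id is not None:
            groups = np.asarray(cluster_id)
            uniq, inv = np.unique(groups, return_inverse=True)
            members = [np.nonzero(inv == g)[0] for g in range(uniq.shape[0])]
            n_cl = len(members)

            def draw():
                picks = rng.integers(0, n_cl, size=n_cl)
                return np.concatenate([members[p] for p in picks])

        else:
            n = ranked.n

            def draw():
                return rng.integers(0, n, size=n)

        values = np.empty(n_boot)
        redraws = 0
        cap = 10 * n_boot
        b = 0
        while b < n_boot:
            idx = draw()
            try:
                rk = fractional_rank(income[idx], w[idx])
                values[b] = _point_estimate(h[idx], rk, w[idx], variant, bounds).value
            except UndefinedIndexError:
                redraws += 1
                if redraws > cap:
                    raise UndefinedIndexError(
                        f"exceeded {cap} redraws of degenerate bootstrap resamples"
                    )
                continue
            b += 1
        if redraws:
            warnings.warn(f"redrew {redraws} degenerate bootstrap resamples")

        alpha = 1.0 - ci_level
        ci_lo = float(np.quantile(values, alpha / 2.0))
        ci_hi = float(np.quantile(values, 1.0 - alpha / 2.0))
        se = float(np.std(values, ddof=1))
        pval = 1.0 if se == 0.0 else 2.0 * stats.norm.sf(abs(est.value) / se)
        return replace(
            est,
            se=se,
            ci_low=min(ci_lo, est.value),
            ci_high=max(ci_hi, est.value),
            ci_method="bootstrap",
            ci_level=ci_level,
            p_value=pval,
        )

    raise ValueError(f"unknown CI method {method!r}")


def classify_inequality(estimate: IndexEstimate) -> str:
    """Classify an estimate as ``pro-rich``, ``pro-poor`` or ``indeterminate``.

    Pro-rich iff the whole CI lies above zero, pro-poor iff below; an interval
    straddling zero is indeterminate.
    """
    if estimate.ci_low is None or estimate.ci_high is None:
        raise ValueError("classification requires a confidence interval")
    if estimate.ci_low > 0:
        return "pro-rich"
    if estimate.ci_high < 0:
        return "pro-poor"
    return "indeterminate"
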