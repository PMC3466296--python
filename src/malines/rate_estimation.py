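"""Mutation-rate point estimates, exact Poisson confidence intervals,
error-rate estimation, and generation counting.

The rate estimator is m/(n*g): m mutations over n scorable (unchanged +
mutated) sites and g cell generations.  Uncertainty comes almost entirely
from the Poisson noise in m, so the interval is an exact (Garwood)
chi-square interval on the count, scaled by 1/(n*g):

    lower(k) = chi2.ppf(alpha/2, 2k) / 2        (0 when k = 0)
    upper(k) = chi2.ppf(1 - alpha/2, 2k + 2) / 2

Garwood intervals are conservative — their coverage is at least the
nominal level for every true expectation.

The sequencing/alignment error rate is estimated empirically as the mean
fraction of reads at a site disagreeing with the site's majority base,
averaged per line and then across lines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .nuclear_calling import FilterParams


@dataclass(frozen=True)
class PoissonInterval:
    """Exact (Garwood) confidence interval for a Poisson expectation."""

    count: int
    level: float
    lower: float
    upper: float


def poisson_ci(k: int, level: float = 0.95) -> PoissonInterval:
    if k < 0:
        raise ValueError("count must be >= 0")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(chi2.ppf(alpha / 2, 2 * k)) / 2.0
    upper = float(chi2.ppf(1 - alpha / 2, 2 * k + 2)) / 2.0
    return PoissonInterval(count=k, level=level, lower=lower, upper=upper)


@dataclass(frozen=True)
class RateEstimate:
    """Point rate m/(n*g) with an exact Poisson interval on the count m."""

    mutations: int
    sites: int
    generations: int
    rate: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    level: float | None = None

    def to_dict(self) -> dict:
        return {
            "mutations": self.mutations,
            "sites": self.sites,
            "generations": self.generations,
            "rate": self.rate,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "level": self.level,
        }


def point_rate(m: int, n: int, g: int) -> RateEstimate:
    """Rate = m / (n * g) mutations per site per cell generation."""
    if n < 1 or g < 1:
        raise ValueError("sites and generations must be >= 1")
    if m < 0:
        raise ValueError("mutation count must be >= 0")
    return RateEstimate(mutations=m, sites=n, generations=g, rate=m / (n * g))


def rate_ci(m: int, n: int, g: int, level: float = 0.95) -> RateEstimate:
    """Point rate with the Garwood interval on m divided through by n*g."""
    est = point_rate(m, n, g)
    ci = poisson_ci(m, level)
    denom = n * g
    return RateEstimate(
        mutations=m,
        sites=n,
        generations=g,
        rate=est.rate,
        ci_lower=ci.lower / denom,
        ci_upper=ci.upper / denom,
        level=level,
    )


@dataclass(frozen=True)
class ErrorRateEstimate:
    """Mean disagreement-with-majority fraction, per line and overall."""

    per_line: dict[str, float]
    overall: float
    site_counts: dict[str, int]


def error_rate(
    counts_per_line: dict[str, np.ndarray],
    eligible_per_line: dict[str, np.ndarray] | None = None,
) -> ErrorRateEstimate:
    """Fraction of reads disagreeing with the site majority.

    Parameters
    ----------
    counts_per_line
        line id -> (n_sites, 4) count matrix.
    eligible_per_line
        Optional line id -> bool mask restricting which sites enter the
        mean (e.g. sites passing the focal filters, for the filtered
        variant of the estimate).  Sites with zero depth never count.

    Per-site fraction is (depth - majority count) / depth; the per-line
    value is its mean over included sites, and the overall value is the
    unweighted mean of the line means.
    """
    per_line: dict[str, float] = {}
    site_counts: dict[str, int] = {}
    for lid, counts in counts_per_line.items():
        counts = np.asarray(counts)
        depth = counts.sum(axis=1)
        keep = depth >= 1
        if eligible_per_line is not None:
            keep &= np.asarray(eligible_per_line[lid], dtype=bool)
        if not keep.any():
            raise ValueError(f"line {lid!r}: no eligible covered sites")
        frac = (depth[keep] - counts[keep].max(axis=1)) / depth[keep]
        per_line[lid] = float(frac.mean())
        site_counts[lid] = int(keep.sum())
    overall = float(np.mean(list(per_line.values())))
    return ErrorRateEstimate(
        per_line=per_line, overall=overall, site_counts=site_counts
    )


def focal_filter_mask(
    counts: np.ndarray,
    unique: np.ndarray,
    line_mean: float,
    params: FilterParams,
) -> np.ndarray:
    """Sites passing one line's focal filters (for the filtered error rate):
    uniquely mappable, depth within [min_cov_focal, max_cov_factor * mean],
    a majority call with agreement >= min_agree_focal."""
    from .consensus import consensus_matrix

    call, depth, agree = consensus_matrix(counts)
    mask = (
        np.asarray(unique, dtype=bool)
        & (depth >= params.min_cov_focal)
        & (depth <= params.max_cov_factor * line_mean)
        & (call >= 0)
        & (agree >= params.min_agree_focal)
    )
    return mask


@dataclass(frozen=True)
class GenerationEstimate:
    """Cell generations from plaque cell counts: divisions per transfer is
    the mean log2 cell count, and the total is that mean times the number
    of transfers, rounded half away from zero."""

    divisions_per_plaque: tuple[float, ...]
    mean_divisions: float
    transfers: int
    total_generations: int


def generations_from_counts(
    cell_counts: Sequence[int], transfers: int
) -> GenerationEstimate:
    counts = np.asarray(cell_counts, dtype=float)
    if len(counts) == 0 or (counts < 1).any():
        raise ValueError("cell counts must be positive")
    if transfers < 1:
        raise ValueError("transfers must be >= 1")
    divisions = np.log2(counts)
    mean = float(divisions.mean())
    total = mean * transfers
    total_rounded = int(np.floor(total + 0.5))  # half away from zero (total > 0)
    return GenerationEstimate(
        divisions_per_plaque=tuple(float(d) for d in divisions),
        mean_divisions=mean,
        transfers=transfers,
        total_generations=total_rounded,
    )
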