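"""Mitochondrial heteroplasmy calling and frequency-weighted rate estimation.

Each cell carries on the order of 200 mitochondrial genomes, so a new
mitochondrial mutation is observed not as a fixed base change but as an
alternate allele at intermediate frequency (heteroplasmy) at a very deep
site.  Under mutation-drift balance the probability that a segregating
mutation eventually fixes equals its current frequency, so each retained
mutation contributes its frequency f(m) to the rate:

    rate per line = sum of f(m) / (n_sites * g)

with n_sites the number of sites meeting the same eligibility criteria as
the mutations (uniquely mappable, depth >= min_cov) and g the number of
generations; the overall rate is the unweighted mean across lines.

Separating real low-frequency heteroplasmies from sequencing errors needs a
frequency cutoff.  Two selection procedures are provided:

* grid_minimum — run the whole rate pipeline at each candidate cutoff and
  take the argmin of the estimate: below the right cutoff the estimate is
  inflated by errors, above it real low-frequency mutations are lost.
* binomial_bound — given a per-read error rate e and a typical coverage c,
  choose the smallest cutoff f such that the binomial probability of more
  than c*f erroneous reads, P[Binomial(c, e) > c*f], is below a per-site
  significance threshold (default 1 / number of mitochondrial sites across
  lines, i.e. under one expected false call genome-wide).

The caller is responsible for inflating the empirical error rate before
passing it to the binomial method (the published analysis doubled it to
allow for systematically error-prone sites); the CLI exposes this as
``--error-inflation``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import binom

from .io_formats import BASES, PileupSite
from .rate_estimation import poisson_ci


@dataclass(frozen=True)
class MitoParams:
    """Heteroplasmy-calling parameters.

    ``min_cov`` may be given explicitly; when None it is resolved once per
    line at run start as a tenth of that line's mean mitochondrial
    coverage, floored (the published analysis used 400 reads, a tenth of
    the ~4000x mitochondrial mean).
    """

    cutoff: float = 0.03
    min_cov: int | None = None
    circular: bool = True
    generations: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.cutoff < 0.5:
            raise ValueError("cutoff must be in (0, 0.5)")
        if self.min_cov is not None and self.min_cov < 1:
            raise ValueError("min_cov must be >= 1")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")

    def resolve_min_cov(self, mean_coverage: float) -> int:
        if self.min_cov is not None:
            return self.min_cov
        return max(1, math.floor(mean_coverage / 10.0))


@dataclass(frozen=True)
class HeteroplasmyCall:
    contig: str
    position: int
    line_id: str
    ref_base: str
    alt_base: str
    frequency: float
    coverage: int


def allele_frequencies(site: PileupSite) -> dict[str, float]:
    """Frequency counts[b]/depth of each base b differing from the
    reference (zero for absent bases)."""
    depth = site.depth
    if depth < 1:
        raise ValueError("allele frequencies need depth >= 1")
    return {
        b: site.counts.get(b, 0) / depth for b in BASES if b != site.ref_base
    }


def call_heteroplasmies(
    counts_per_line: dict[str, np.ndarray],
    ref_idx: np.ndarray,
    unique: np.ndarray,
    params: MitoParams,
    contig: str = "mito",
    min_cov_per_line: dict[str, int] | None = None,
) -> tuple[list[HeteroplasmyCall], dict[str, int]]:
    """Call heteroplasmic mutations unique to one line.

    An alternate allele is a candidate in a line when its site is uniquely
    mappable, covered by at least min_cov reads in that line, and its
    frequency is >= the cutoff (the boundary counts: exactly the cutoff is
    retained).  Candidates at the same contig/position/alternate that pass
    the cutoff in two or more lines are excluded from ALL of them —
    recurrent signals are ancestral polymorphism or systematic error, not
    independent new mutations.

    Returns the retained calls and, per line, the number of eligible sites
    (the denominator n_sites for the rate).
    """
    ref_idx = np.asarray(ref_idx)
    unique = np.asarray(unique, dtype=bool)
    if min_cov_per_line is None:
        min_cov_per_line = {}
        for lid, counts in counts_per_line.items():
            depth = np.asarray(counts).sum(axis=1)
            covered = unique & (depth >= 1)
            mean = float(depth[covered].mean()) if covered.any() else 0.0
            min_cov_per_line[lid] = params.resolve_min_cov(mean)

    candidates: dict[tuple[int, int], list[HeteroplasmyCall]] = {}
    n_sites: dict[str, int] = {}
    for lid, counts in counts_per_line.items():
        counts = np.asarray(counts)
        depth = counts.sum(axis=1)
        eligible = unique & (depth >= min_cov_per_line[lid]) & (ref_idx >= 0)
        n_sites[lid] = int(eligible.sum())
        freqs = np.zeros_like(counts, dtype=float)
        d = depth[eligible][:, None]
        freqs[eligible] = counts[eligible] / d
        for pos in np.flatnonzero(eligible):
            for b in range(4):
                if b == ref_idx[pos]:
                    continue
                f = freqs[pos, b]
                if f >= params.cutoff:
                    call = HeteroplasmyCall(
                        contig=contig,
                        position=int(pos) + 1,
                        line_id=lid,
                        ref_base=BASES[ref_idx[pos]],
                        alt_base=BASES[b],
                        frequency=float(f),
                        coverage=int(depth[pos]),
                    )
                    candidates.setdefault((int(pos), b), []).append(call)

    retained = [
        calls[0] for calls in candidates.values() if len(calls) == 1
    ]
    retained.sort(key=lambda c: (c.position, c.alt_base, c.line_id))
    return retained, n_sites


@dataclass
class MitoRateEstimate:
    """Per-line frequency-sum rates, their mean, and the exact Poisson
    interval on the pooled retained-mutation count applied multiplicatively
    to the mean rate."""

    per_line: dict[str, dict]
    mean_rate: float
    n_mutations: int
    ci_lower: float | None = None
    ci_upper: float | None = None
    level: float = 0.95

    def to_dict(self) -> dict:
        return {
            "per_line": self.per_line,
            "mean_rate": self.mean_rate,
            "n_mutations": self.n_mutations,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "level": self.level,
        }


def mito_rate(
    calls: Sequence[HeteroplasmyCall],
    n_sites: dict[str, int],
    generations: int,
    level: float = 0.95,
) -> MitoRateEstimate:
    """Frequency-weighted rate per line and the mean across lines.

    Lines with zero eligible sites are excluded with a warning.  The
    confidence interval is the Garwood interval on the total retained
    count, scaled by (mean rate / count); with zero retained calls the
    interval on the count is still reported but the scaled bounds are 0.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    per_line: dict[str, dict] = {}
    rates = []
    for lid, n in n_sites.items():
        line_calls = [c for c in calls if c.line_id == lid]
        if n <= 0:
            warnings.warn(
                f"line {lid!r}: no eligible mitochondrial sites; excluded",
                stacklevel=2,
            )
            continue
        fsum = float(sum(c.frequency for c in line_calls))
        rate = fsum / (n * generations)
        per_line[lid] = {
            "frequency_sum": fsum,
            "n_sites": n,
            "n_calls": len(line_calls),
            "rate": rate,
        }
        rates.append(rate)
    if not rates:
        raise ValueError("no line with eligible mitochondrial sites")
    mean_rate = float(np.mean(rates))
    k = sum(d["n_calls"] for d in per_line.values())
    ci = poisson_ci(k, level)
    if k > 0:
        lo, hi = mean_rate * ci.lower / k, mean_rate * ci.upper / k
    else:
        lo, hi = 0.0, 0.0
    return MitoRateEstimate(
        per_line=per_line,
        mean_rate=mean_rate,
        n_mutations=k,
        ci_lower=lo,
        ci_upper=hi,
        level=level,
    )


@dataclass
class CutoffSelection:
    method: str  # grid_minimum | binomial_bound
    grid: list[float]
    chosen: float
    diagnostics: dict[float, float] = field(default_factory=dict)


def select_cutoff_grid(
    counts_per_line: dict[str, np.ndarray],
    ref_idx: np.ndarray,
    unique: np.ndarray,
    params: MitoParams,
    grid: Sequence[float],
) -> CutoffSelection:
    """Run the full call-and-rate pipeline at each candidate cutoff and
    choose the argmin of the mean rate (ties broken toward the smallest
    cutoff).  Below the right cutoff the estimate is error-inflated; the
    minimum marks where errors stop entering."""
    grid = [float(f) for f in grid]
    if not grid or sorted(grid) != grid:
        raise ValueError("grid must be non-empty and sorted ascending")
    import dataclasses

    diagnostics = {}
    for f in grid:
        p = dataclasses.replace(params, cutoff=f)
        calls, n_sites = call_heteroplasmies(
            counts_per_line, ref_idx, unique, p
        )
        est = mito_rate(calls, n_sites, params.generations)
        diagnostics[f] = est.mean_rate
    chosen = min(grid, key=lambda f: (diagnostics[f], f))
    return CutoffSelection(
        method="grid_minimum", grid=grid, chosen=chosen, diagnostics=diagnostics
    )


def binomial_tail(coverage: int, error_per_read: float, cutoff: float) -> float:
    """P[Binomial(coverage, e) > coverage * cutoff], strict inequality.

    For an integer-valued count X, X > t is X >= floor(t) + 1, so the tail
    is the survival function at floor(coverage * cutoff).
    """
    t = math.floor(coverage * cutoff)
    return float(binom.sf(t, coverage, error_per_read))


def select_cutoff_binomial(
    error_per_read: float,
    coverage: int,
    alpha_per_site: float,
    grid: Sequence[float],
) -> CutoffSelection:
    """Smallest grid cutoff keeping the per-site false-call probability
    below ``alpha_per_site``.

    ``error_per_read`` should already include any inflation factor the
    caller wants (the published analysis doubled the empirical 0.002).
    A natural ``alpha_per_site`` is 1 / (number of mitochondrial sites
    across lines), bounding the expected number of error-driven calls by
    one genome-wide.
    """
    if not 0 < error_per_read < 1:
        raise ValueError("error_per_read must be in (0, 1)")
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    grid = [float(f) for f in grid]
    if not grid or sorted(grid) != grid:
        raise ValueError("grid must be non-empty and sorted ascending")
    diagnostics = {
        f: binomial_tail(coverage, error_per_read, f) for f in grid
    }
    admissible = [f for f in grid if diagnostics[f] < alpha_per_site]
    if not admissible:
        raise ValueError("no admissible cutoff in grid")
    return CutoffSelection(
        method="binomial_bound",
        grid=grid,
        chosen=admissible[0],
        diagnostics=diagnostics,
    )
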