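"""Per-site majority consensus and per-line coverage statistics.

The consensus rule is the simple majority rule used throughout the
analysis: a base is called when it is the strictly most frequent base at
the site and at least 50% of the counted reads support it.  An exact
two-way tie at 50% (and any multi-way tie for the maximum) yields no call
and the position is treated as uncovered.  The organism is haploid, so no
heterozygote model is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import BASES, PileupSite
from .mappability import MappabilityMask


@dataclass(frozen=True)
class ConsensusCall:
    """Majority call at one site: base (or None for no-call), counted
    coverage, and the agreement fraction counts[base]/coverage."""

    base: str | None
    coverage: int
    agreement: float

    @property
    def is_call(self) -> bool:
        return self.base is not None


NO_CALL = ConsensusCall(base=None, coverage=0, agreement=0.0)


def majority_consensus(site: PileupSite) -> ConsensusCall:
    """Call the strictly most frequent base if it reaches 50% agreement.

    Zero depth, a tie for the maximum count, or a maximum below half the
    depth all yield a no-call (agreement reported as 0).
    """
    depth = site.depth
    if depth == 0:
        return NO_CALL
    items = [(b, c) for b, c in site.counts.items() if c > 0]
    top_base, top = max(items, key=lambda bc: bc[1])
    if sum(1 for _, c in items if c == top) > 1:
        return ConsensusCall(base=None, coverage=depth, agreement=0.0)
    if 2 * top < depth:
        return ConsensusCall(base=None, coverage=depth, agreement=0.0)
    return ConsensusCall(base=top_base, coverage=depth, agreement=top / depth)


def consensus_matrix(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised majority rule over a (n_sites, 4) count matrix.

    Returns ``(call_index, depth, agreement)`` where call_index is the
    column index of the called base in ``BASES`` or -1 for no-call.
    Agreement is 0 where no call is made.  Equivalent site-by-site to
    :func:`majority_consensus`; the scalar form is the readable reference,
    this is what the genome-scale paths use.
    """
    counts = np.asarray(counts)
    depth = counts.sum(axis=1)
    top = counts.max(axis=1)
    call = counts.argmax(axis=1)
    n_top = (counts == top[:, None]).sum(axis=1)
    ok = (depth > 0) & (n_top == 1) & (2 * top >= depth)
    call = np.where(ok, call, -1)
    agreement = np.zeros(len(counts), dtype=float)
    agreement[ok] = top[ok] / depth[ok]
    return call, depth, agreement


@dataclass(frozen=True)
class CoverageStats:
    """Mean read depth for one line over covered, uniquely mappable sites.

    Lines were sequenced to different depths, so the high-coverage cap in
    the site filters multiplies each line's own mean.
    """

    line_id: str
    mean_coverage: float
    site_count: int


def mean_coverage(
    depths: np.ndarray, mask: MappabilityMask, line_id: str = ""
) -> CoverageStats:
    """Arithmetic mean depth over uniquely mappable sites with depth >= 1."""
    depths = np.asarray(depths)
    if len(depths) != len(mask):
        raise ValueError("depth vector and mask length differ")
    eligible = mask.unique & (depths >= 1)
    n = int(eligible.sum())
    if n == 0:
        raise ValueError("no covered unique sites")
    return CoverageStats(
        line_id=line_id,
        mean_coverage=float(depths[eligible].mean()),
        site_count=n,
    )
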