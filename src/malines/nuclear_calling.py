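"""Classification of every site, per MA line, as a unique mutation, an
unchanged (reference-confirming) site, or excluded.

The rules are deliberately symmetric between changed and unchanged sites so
that the numerator (mutations m) and denominator (unchanged sites n) of the
rate m/(n*g) are counted under the same criteria:

* A site is eligible only if uniquely mappable and covered by at least one
  read in every line.
* The focal line must pass the strong filters: depth >= 5, depth <= 3x that
  line's own mean, a majority call, and >= 90% agreement (defaults).
* A focal call differing from the reference is a candidate mutation.  It is
  rejected as a shared candidate if the same alternate base is the weak
  majority (depth >= 1, agreement >= 50%) in ANY other line — shared
  candidates are reference errors or ancestor-vs-reference differences, not
  new mutations, because independent recurrence of the same substitution is
  vanishingly unlikely.
* A focal call equal to the reference is counted as unchanged only when
  every other line confirms the reference under the same weak criteria.

Two readings of the mutation rule are possible: the literal one (default),
where acceptance requires only the ABSENCE of the alternate base as a weak
majority elsewhere, and a strict one (``strict_confirmation``) where the
other lines must also positively confirm the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .consensus import ConsensusCall, consensus_matrix
from .io_formats import BASES

# Outcome / reason codes for the vectorised path.  0 is "unassigned".
MUTATION = 1
UNCHANGED = 2
NOT_UNIQUE = 3
NOT_COVERED_ALL_LINES = 4
LOW_COVERAGE = 5
HIGH_COVERAGE = 6
TIE_NO_CALL = 7
LOW_AGREEMENT = 8
SHARED_CANDIDATE = 9
CONFIRMATION_FAILED = 10

CODE_NAMES = {
    MUTATION: "MUTATION",
    UNCHANGED: "UNCHANGED",
    NOT_UNIQUE: "not_unique",
    NOT_COVERED_ALL_LINES: "not_covered_all_lines",
    LOW_COVERAGE: "low_coverage",
    HIGH_COVERAGE: "high_coverage",
    TIE_NO_CALL: "tie_no_call",
    LOW_AGREEMENT: "low_agreement",
    SHARED_CANDIDATE: "shared_candidate",
    CONFIRMATION_FAILED: "confirmation_failed",
}
EXCLUSION_REASONS = [
    CODE_NAMES[c] for c in range(NOT_UNIQUE, CONFIRMATION_FAILED + 1)
]


@dataclass(frozen=True)
class FilterParams:
    """Site-filter thresholds.

    The weak confirmation criteria (min_cov_confirm, min_agree_confirm) are
    the same two numbers for both the shared-candidate veto and the
    unchanged-site confirmation — the symmetry is the point.
    """

    min_cov_focal: int = 5
    min_agree_focal: float = 0.90
    min_cov_confirm: int = 1
    min_agree_confirm: float = 0.5
    max_cov_factor: float = 3.0
    require_unique: bool = True
    strict_confirmation: bool = False

    def __post_init__(self) -> None:
        if not (self.min_cov_focal >= self.min_cov_confirm >= 1):
            raise ValueError("need min_cov_focal >= min_cov_confirm >= 1")
        if not (0.5 <= self.min_agree_confirm <= self.min_agree_focal <= 1.0):
            raise ValueError(
                "need 0.5 <= min_agree_confirm <= min_agree_focal <= 1"
            )
        if self.max_cov_factor <= 0:
            raise ValueError("max_cov_factor must be positive")


@dataclass(frozen=True)
class SiteClassification:
    contig: str
    position: int
    line_id: str
    outcome: str  # MUTATION | UNCHANGED | EXCLUDED
    reason: str | None = None  # set when outcome == EXCLUDED


@dataclass(frozen=True)
class MutationCall:
    contig: str
    position: int
    line_id: str
    ref_base: str
    alt_base: str
    coverage: int
    agreement: float


def _weak_majority(call: ConsensusCall, params: FilterParams) -> str | None:
    if (
        call.is_call
        and call.coverage >= params.min_cov_confirm
        and call.agreement >= params.min_agree_confirm
    ):
        return call.base
    return None


def classify_site(
    contig: str,
    position: int,
    ref_base: str,
    calls: dict[str, ConsensusCall],
    unique: bool,
    line_means: dict[str, float],
    params: FilterParams,
) -> list[SiteClassification]:
    """Classify one site for every line (scalar reference implementation).

    The vectorised :func:`classify_genome` is what the genome-scale paths
    run; this form spells the rules out one condition at a time.
    """
    if len(calls) < 2:
        raise ValueError("need at least two MA lines")

    def excluded(reason: str) -> list[SiteClassification]:
        return [
            SiteClassification(contig, position, lid, "EXCLUDED", reason)
            for lid in calls
        ]

    if ref_base not in BASES or (params.require_unique and not unique):
        return excluded("not_unique")
    if any(c.coverage == 0 for c in calls.values()):
        return excluded("not_covered_all_lines")

    weak = {lid: _weak_majority(c, params) for lid, c in calls.items()}
    out = []
    for lid, c in calls.items():
        others = [weak[o] for o in calls if o != lid]
        if c.coverage < params.min_cov_focal:
            res = ("EXCLUDED", "low_coverage")
        elif c.coverage > params.max_cov_factor * line_means[lid]:
            res = ("EXCLUDED", "high_coverage")
        elif not c.is_call:
            res = ("EXCLUDED", "tie_no_call")
        elif c.agreement < params.min_agree_focal:
            res = ("EXCLUDED", "low_agreement")
        elif c.base != ref_base:
            if any(w == c.base for w in others):
                res = ("EXCLUDED", "shared_candidate")
            elif params.strict_confirmation and not all(
                w == ref_base for w in others
            ):
                res = ("EXCLUDED", "confirmation_failed")
            else:
                res = ("MUTATION", None)
        else:
            if all(w == ref_base for w in others):
                res = ("UNCHANGED", None)
            else:
                res = ("EXCLUDED", "confirmation_failed")
        out.append(SiteClassification(contig, position, lid, res[0], res[1]))
    return out


def classify_genome(
    counts: np.ndarray,
    ref_idx: np.ndarray,
    unique: np.ndarray,
    line_means: Sequence[float],
    params: FilterParams,
) -> np.ndarray:
    """Vectorised classification over a whole contig.

    Parameters
    ----------
    counts
        int array (n_lines, n_sites, 4), base order A, C, G, T.
    ref_idx
        int array (n_sites,); index of the reference base, -1 where the
        reference is N (such sites are excluded from all counting).
    unique
        bool array (n_sites,), the uniquely-mappable flag.
    line_means
        Per-line mean coverage (the high-coverage cap is 3x each line's own
        mean).

    Returns
    -------
    int8 array (n_lines, n_sites) of outcome codes (``CODE_NAMES``).
    """
    counts = np.asarray(counts)
    n_lines, n_sites, _ = counts.shape
    if n_lines < 2:
        raise ValueError("need at least two MA lines")
    ref_idx = np.asarray(ref_idx)
    unique = np.asarray(unique, dtype=bool)
    means = np.asarray(line_means, dtype=float)

    call = np.empty((n_lines, n_sites), dtype=np.int64)
    depth = np.empty((n_lines, n_sites), dtype=np.int64)
    agree = np.empty((n_lines, n_sites), dtype=float)
    for l in range(n_lines):
        call[l], depth[l], agree[l] = consensus_matrix(counts[l])

    weak = np.where(
        (call >= 0)
        & (depth >= params.min_cov_confirm)
        & (agree >= params.min_agree_confirm),
        call,
        -1,
    )

    out = np.zeros((n_lines, n_sites), dtype=np.int8)

    bad_site = ref_idx < 0
    if params.require_unique:
        bad_site |= ~unique
    out[:, bad_site] = NOT_UNIQUE
    uncovered = (depth == 0).any(axis=0) & ~bad_site
    out[:, uncovered] = NOT_COVERED_ALL_LINES

    def assign(mask: np.ndarray, code: int) -> None:
        np.putmask(out, (out == 0) & mask, code)

    assign(depth < params.min_cov_focal, LOW_COVERAGE)
    assign(depth > params.max_cov_factor * means[:, None], HIGH_COVERAGE)
    assign(call == -1, TIE_NO_CALL)
    assign(agree < params.min_agree_focal, LOW_AGREEMENT)

    # For each focal line: does any OTHER line's weak majority equal the
    # focal call / the reference?
    shared = np.zeros((n_lines, n_sites), dtype=bool)
    confirm = np.ones((n_lines, n_sites), dtype=bool)
    for l in range(n_lines):
        others = [o for o in range(n_lines) if o != l]
        shared[l] = (weak[others] == call[l][None, :]).any(axis=0)
        confirm[l] = (weak[others] == ref_idx[None, :]).all(axis=0)

    is_alt = call != ref_idx[None, :]
    assign(is_alt & shared, SHARED_CANDIDATE)
    if params.strict_confirmation:
        assign(is_alt & ~confirm, CONFIRMATION_FAILED)
    assign(is_alt, MUTATION)
    assign(~is_alt & confirm, UNCHANGED)
    assign(~is_alt, CONFIRMATION_FAILED)
    return out


def extract_mutations(
    outcomes: np.ndarray,
    counts: np.ndarray,
    ref_idx: np.ndarray,
    contig: str,
    line_ids: Sequence[str],
) -> list[MutationCall]:
    """Materialise MutationCall records from a classification matrix."""
    calls = []
    for l, pos in zip(*np.nonzero(outcomes == MUTATION)):
        c = counts[l, pos]
        alt = int(c.argmax())
        d = int(c.sum())
        calls.append(
            MutationCall(
                contig=contig,
                position=int(pos) + 1,
                line_id=line_ids[l],
                ref_base=BASES[ref_idx[pos]],
                alt_base=BASES[alt],
                coverage=d,
                agreement=int(c[alt]) / d,
            )
        )
    return calls


@dataclass
class Tally:
    """Per-line and pooled outcome counts.

    ``mutations`` (m) and ``unchanged`` (n) feed the rate m/(n*g);
    ``candidates`` counts focal alternate calls passing the strong filters
    before the shared-candidate veto, so candidates - mutations is the
    number ruled out as shared.
    """

    line_ids: list[str]
    per_line: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def mutations(self) -> int:
        return sum(d["MUTATION"] for d in self.per_line.values())

    @property
    def unchanged(self) -> int:
        return sum(d["UNCHANGED"] for d in self.per_line.values())

    @property
    def shared_candidates(self) -> int:
        return sum(d["shared_candidate"] for d in self.per_line.values())

    @property
    def candidates(self) -> int:
        return self.mutations + self.shared_candidates

    def to_dict(self) -> dict:
        return {
            "per_line": self.per_line,
            "pooled": {
                "mutations": self.mutations,
                "unchanged": self.unchanged,
                "candidates": self.candidates,
                "shared_candidates": self.shared_candidates,
            },
        }


def tally(outcomes: np.ndarray, line_ids: Sequence[str]) -> Tally:
    """Count outcomes per line; every classified line-site lands in exactly
    one bucket, so the buckets partition the line-site grid."""
    t = Tally(line_ids=list(line_ids))
    for l, lid in enumerate(line_ids):
        row = outcomes[l]
        d = {"MUTATION": int((row == MUTATION).sum())}
        d["UNCHANGED"] = int((row == UNCHANGED).sum())
        for code in range(NOT_UNIQUE, CONFIRMATION_FAILED + 1):
            d[CODE_NAMES[code]] = int((row == code).sum())
        t.per_line[lid] = d
    return t


def iter_classifications(
    outcomes: np.ndarray,
    contig: str,
    line_ids: Sequence[str],
):
    """Yield SiteClassification records (for the TSV writer)."""
    for pos in range(outcomes.shape[1]):
        for l, lid in enumerate(line_ids):
            code = int(outcomes[l, pos])
            if code in (MUTATION, UNCHANGED):
                yield SiteClassification(
                    contig, pos + 1, lid, CODE_NAMES[code], None
                )
            else:
                yield SiteClassification(
                    contig, pos + 1, lid, "EXCLUDED", CODE_NAMES[code]
                )


def sensitivity_sweep(
    counts: np.ndarray,
    ref_idx: np.ndarray,
    unique: np.ndarray,
    line_means: Sequence[float],
    grid: Sequence[FilterParams],
    generations: int,
    line_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Re-run the full classification for each parameter set in the grid.

    Returns one row per setting with the pooled tally and the implied rate
    m/(n*g) — the standard check that the published thresholds are not
    doing the heavy lifting.
    """
    if not len(grid):
        raise ValueError("empty parameter grid")
    if line_ids is None:
        line_ids = [f"line{i+1}" for i in range(counts.shape[0])]
    rows = []
    for p in grid:
        t = tally(
            classify_genome(counts, ref_idx, unique, line_means, p), line_ids
        )
        rows.append(
            {
                "min_cov_focal": p.min_cov_focal,
                "min_agree_focal": p.min_agree_focal,
                "min_cov_confirm": p.min_cov_confirm,
                "min_agree_confirm": p.min_agree_confirm,
                "max_cov_factor": p.max_cov_factor,
                "mutations": t.mutations,
                "unchanged": t.unchanged,
                "rate": t.mutations / (t.unchanged * generations)
                if t.unchanged
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)
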