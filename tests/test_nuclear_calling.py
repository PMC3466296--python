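"""Site classification rules: mutations unique to one line, unchanged
sites confirmed in all lines, symmetric weak criteria, and the tally."""

import dataclasses

import numpy as np
import pytest

from malines import FilterParams, classify_site, sensitivity_sweep
from malines.consensus import ConsensusCall
from malines.io_formats import BASES
from malines.nuclear_calling import (
    MUTATION,
    UNCHANGED,
    CODE_NAMES,
    classify_genome,
    extract_mutations,
    tally,
)


def call_from(counts):
    depth = sum(counts.values())
    if depth == 0:
        return ConsensusCall(None, 0, 0.0)
    top = max(counts, key=counts.get)
    if sum(1 for c in counts.values() if c == counts[top]) > 1 or (
        2 * counts[top] < depth
    ):
        return ConsensusCall(None, depth, 0.0)
    return ConsensusCall(top, depth, counts[top] / depth)


def classify(line_counts, ref="A", unique=True, means=None, params=None):
    calls = {f"L{i}": call_from(c) for i, c in enumerate(line_counts)}
    means = means or {lid: 10.0 for lid in calls}
    out = classify_site(
        "c", 1, ref, calls, unique, means, params or FilterParams()
    )
    return {r.line_id: (r.outcome, r.reason) for r in out}


class TestClassifySite:
    def test_unique_mutation_called(self):
        res = classify([{"T": 7}, {"A": 3}, {"A": 1}])
        assert res["L0"] == ("MUTATION", None)

    def test_candidate_shared_with_one_read_excluded(self):
        res = classify([{"T": 7}, {"T": 1}, {"A": 5}])
        assert res["L0"] == ("EXCLUDED", "shared_candidate")

    def test_unchanged_needs_confirmation_everywhere(self):
        res = classify([{"A": 6}, {"A": 1}, {"A": 2}])
        assert res["L0"] == ("UNCHANGED", None)
        assert res["L1"] == ("EXCLUDED", "low_coverage")
        assert res["L2"] == ("EXCLUDED", "low_coverage")

    def test_unconfirmed_reference_fails(self):
        res = classify([{"A": 6}, {"C": 2}, {"A": 3}])
        assert res["L0"] == ("EXCLUDED", "confirmation_failed")

    def test_not_covered_in_all_lines_excludes_site(self):
        res = classify([{"A": 6}, {}, {"A": 3}])
        assert all(v == ("EXCLUDED", "not_covered_all_lines") for v in res.values())

    def test_non_unique_site_excluded(self):
        res = classify([{"A": 6}, {"A": 2}, {"A": 3}], unique=False)
        assert all(v == ("EXCLUDED", "not_unique") for v in res.values())

    def test_high_coverage_cap_is_per_line_mean(self):
        means = {"L0": 2.0, "L1": 10.0, "L2": 10.0}
        res = classify([{"A": 7}, {"A": 7}, {"A": 7}], means=means)
        assert res["L0"] == ("EXCLUDED", "high_coverage")
        assert res["L1"] == ("UNCHANGED", None)

    def test_low_agreement_excluded(self):
        res = classify([{"T": 7, "A": 2}, {"A": 3}, {"A": 1}])
        assert res["L0"] == ("EXCLUDED", "low_agreement")

    def test_tie_is_no_call(self):
        res = classify([{"T": 4, "A": 4}, {"A": 3}, {"A": 1}])
        assert res["L0"] == ("EXCLUDED", "tie_no_call")

    def test_third_base_does_not_veto_mutation(self):
        # the veto is specifically the candidate alternate appearing
        # elsewhere; a G majority in another line does not block an A->T
        res = classify([{"T": 7}, {"G": 2}, {"A": 4}])
        assert res["L0"] == ("MUTATION", None)

    def test_strict_mode_requires_positive_confirmation(self):
        params = FilterParams(strict_confirmation=True)
        res = classify([{"T": 7}, {"G": 2}, {"A": 4}], params=params)
        assert res["L0"] == ("EXCLUDED", "confirmation_failed")
        res = classify([{"T": 7}, {"A": 2}, {"A": 4}], params=params)
        assert res["L0"] == ("MUTATION", None)

    def test_symmetry_of_weak_criteria(self):
        # raising min_cov_confirm to 2 shifts BOTH the shared-candidate
        # veto and the unchanged confirmation, with the same parameter
        params = FilterParams(min_cov_confirm=2)
        shared = classify([{"T": 7}, {"T": 1}, {"A": 5}], params=params)
        assert shared["L0"] == ("MUTATION", None)  # 1-read veto now inactive
        unchanged = classify([{"A": 6}, {"A": 1}, {"A": 5}], params=params)
        assert unchanged["L0"] == ("EXCLUDED", "confirmation_failed")

    def test_needs_two_lines(self):
        with pytest.raises(ValueError):
            classify_site(
                "c", 1, "A", {"L0": call_from({"A": 5})}, True, {"L0": 10.0},
                FilterParams(),
            )


def oracle_classify(counts, ref_idx, unique, means, p):
    """Independent per-site rule enumeration, written without reference to
    the package implementation (dict/loop style, no vectorisation)."""
    n_lines, n_sites, _ = counts.shape
    out = np.empty((n_lines, n_sites), dtype=object)
    for s in range(n_sites):
        cols = []
        for l in range(n_lines):
            c = counts[l, s]
            d = int(c.sum())
            best = int(c.argmax())
            ok = d > 0 and list(c).count(c[best]) == 1 and 2 * c[best] >= d
            cols.append((d, best if ok else None, (c[best] / d) if d else 0.0))
        if ref_idx[s] < 0 or not unique[s]:
            out[:, s] = "not_unique"
            continue
        if any(d == 0 for d, _, _ in cols):
            out[:, s] = "not_covered_all_lines"
            continue
        for l in range(n_lines):
            d, base, agr = cols[l]
            weak_others = [
                cols[o][1]
                for o in range(n_lines)
                if o != l and cols[o][1] is not None and cols[o][0] >= p.min_cov_confirm
                and cols[o][2] >= p.min_agree_confirm
            ]
            if d < p.min_cov_focal:
                out[l, s] = "low_coverage"
            elif d > p.max_cov_factor * means[l]:
                out[l, s] = "high_coverage"
            elif base is None:
                out[l, s] = "tie_no_call"
            elif agr < p.min_agree_focal:
                out[l, s] = "low_agreement"
            elif base != ref_idx[s]:
                out[l, s] = (
                    "shared_candidate" if base in weak_others else "MUTATION"
                )
            else:
                n_others = n_lines - 1
                confirmed = sum(1 for w in weak_others if w == ref_idx[s])
                non_ref_weak = any(w != ref_idx[s] for w in weak_others)
                out[l, s] = (
                    "UNCHANGED"
                    if confirmed == n_others and not non_ref_weak
                    else "confirmation_failed"
                )
    return out


class TestClassifyGenome:
    @pytest.fixture()
    def fixture_200(self, rng):
        n = 200
        counts = rng.poisson(3.0, size=(3, n, 4)).astype(np.int64)
        ref_idx = rng.integers(0, 4, n)
        ref_idx[rng.choice(n, 5, replace=False)] = -1
        unique = rng.random(n) > 0.2
        means = [counts[l].sum(1).mean() for l in range(3)]
        return counts, ref_idx, unique, means

    def test_matches_independent_oracle(self, fixture_200):
        counts, ref_idx, unique, means = fixture_200
        p = FilterParams()
        got = classify_genome(counts, ref_idx, unique, means, p)
        want = oracle_classify(counts, ref_idx, unique, means, p)
        names = np.vectorize(CODE_NAMES.get)(got)
        assert (names == want).all()

    def test_matches_oracle_with_perturbed_params(self, fixture_200):
        counts, ref_idx, unique, means = fixture_200
        p = FilterParams(min_cov_focal=3, min_agree_focal=0.8,
                        min_cov_confirm=2, min_agree_confirm=0.6)
        got = np.vectorize(CODE_NAMES.get)(
            classify_genome(counts, ref_idx, unique, means, p)
        )
        assert (got == oracle_classify(counts, ref_idx, unique, means, p)).all()

    def test_partition_every_line_site_has_one_outcome(self, fixture_200):
        counts, ref_idx, unique, means = fixture_200
        out = classify_genome(counts, ref_idx, unique, means, FilterParams())
        assert (out > 0).all()  # every line-site classified exactly once
        t = tally(out, ["a", "b", "c"])
        total = sum(sum(d.values()) for d in t.per_line.values())
        assert total == out.size


class TestTally:
    def test_zero_error_recovery_and_shared_exclusion(self, small_experiment, small_mask):
        from malines import SimulationConfig, simulate_experiment
        from malines.consensus import mean_coverage

        cfg = dataclasses.replace(
            small_experiment.config, per_read_error=0.0, seed=11,
            genome_length=8000, mean_coverage=(20.0,), shared_diff_count=5,
            true_nuclear_rate=3e-7,
        )
        exp = simulate_experiment(cfg)
        unique = np.ones(len(exp.genome), dtype=bool)
        lines = list(exp.counts)
        c3 = np.stack([exp.counts[l] for l in lines])
        means = [c3[i].sum(1)[c3[i].sum(1) > 0].mean() for i in range(3)]
        out = classify_genome(c3, exp.ref_idx, unique, means, FilterParams())
        t = tally(out, lines)
        muts = extract_mutations(out, c3, exp.ref_idx, "chr1", lines)
        called = {(m.line_id, m.position, m.alt_base) for m in muts}
        planted = {
            (lid, pos, alt)
            for lid, entries in exp.truth.mutations.items()
            for pos, _ref, alt in entries
        }
        assert called <= planted  # zero false positives at e=0
        # every planted mutation at an eligible site is recovered
        depth = c3.sum(axis=2)
        for lid, entries in exp.truth.mutations.items():
            l = lines.index(lid)
            for pos, _ref, alt in entries:
                i = pos - 1
                if (
                    (depth[:, i] >= 1).all()
                    and depth[l, i] >= 5
                    and depth[l, i] <= 3 * means[l]
                ):
                    assert (lid, pos, alt) in called
        # shared ancestral differences: all excluded as shared candidates
        assert t.shared_candidates == sum(
            1
            for pos, _r, _a in exp.truth.shared_diffs
            for l in range(3)
            if (depth[:, pos - 1] >= 1).all()
            and 5 <= depth[l, pos - 1] <= 3 * means[l]
        )
        assert all(
            out[l, pos - 1] != MUTATION
            for pos, _r, _a in exp.truth.shared_diffs
            for l in range(3)
        )


class TestSensitivitySweep:
    @pytest.fixture()
    def zero_error_data(self):
        from malines import SimulationConfig, simulate_experiment

        cfg = SimulationConfig(
            seed=21, genome_length=6000, per_read_error=0.0,
            mean_coverage=(20.0,), true_nuclear_rate=3e-7,
        )
        exp = simulate_experiment(cfg)
        lines = list(exp.counts)
        c3 = np.stack([exp.counts[l] for l in lines])
        unique = np.ones(len(exp.genome), dtype=bool)
        means = [c3[i].sum(1)[c3[i].sum(1) > 0].mean() for i in range(3)]
        return c3, exp.ref_idx, unique, means

    def test_full_agreement_keeps_m_shrinks_n(self, zero_error_data):
        c3, ref_idx, unique, means = zero_error_data
        grid = [FilterParams(), FilterParams(min_agree_focal=1.0)]
        df = sensitivity_sweep(c3, ref_idx, unique, means, grid, 1000)
        assert df.mutations[1] == df.mutations[0]  # zero error: m unchanged
        assert df.unchanged[1] <= df.unchanged[0]

    def test_inactive_coverage_filter_identical_tally(self, zero_error_data):
        c3, ref_idx, unique, means = zero_error_data
        deep = c3.sum(axis=2).min() >= 4  # may be False under Poisson; force
        c3 = c3 + 2  # lift every count so depth filters are inactive
        means = [c3[i].sum(1).mean() for i in range(3)]
        grid = [FilterParams(min_cov_focal=2), FilterParams(min_cov_focal=1)]
        df = sensitivity_sweep(c3, ref_idx, unique, means, grid, 1000)
        assert df.mutations[0] == df.mutations[1]
        assert df.unchanged[0] == df.unchanged[1]

    def test_rows_match_individual_runs(self, zero_error_data):
        c3, ref_idx, unique, means = zero_error_data
        grid = [
            FilterParams(),
            FilterParams(min_cov_focal=7),
            FilterParams(min_agree_focal=0.95),
            FilterParams(max_cov_factor=2.0),
        ]
        df = sensitivity_sweep(c3, ref_idx, unique, means, grid, 1000)
        assert len(df) == 4
        for row, p in zip(df.itertuples(), grid):
            t = tally(
                classify_genome(c3, ref_idx, unique, means, p), ["a", "b", "c"]
            )
            assert (row.mutations, row.unchanged) == (t.mutations, t.unchanged)

    def test_monotone_in_focal_filters(self, zero_error_data):
        c3, ref_idx, unique, means = zero_error_data
        for field, values in [
            ("min_cov_focal", [1, 3, 5, 8, 12]),
            ("min_agree_focal", [0.9, 0.95, 1.0]),
        ]:
            grid = [FilterParams(**{field: v}) for v in values]
            df = sensitivity_sweep(c3, ref_idx, unique, means, grid, 1000)
            assert (np.diff(df.mutations) <= 0).all()
            assert (np.diff(df.unchanged) <= 0).all()

    def test_empty_grid_rejected(self, zero_error_data):
        c3, ref_idx, unique, means = zero_error_data
        with pytest.raises(ValueError):
            sensitivity_sweep(c3, ref_idx, unique, means, [], 1000)
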