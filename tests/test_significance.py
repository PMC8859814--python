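"""Random-ligation binomial caller and per-bait local (elbow) filtering."""

import itertools
from math import comb

import numpy as np
import pytest
from scipy import stats

from chicbench import (
    CallSet,
    ContactCounts,
    bh_adjust,
    binomial_interaction_test,
    cumulative_significance_curve,
    fragment_visibility,
    lf_threshold,
    local_filter,
    read_contact_counts,
    write_contact_counts,
)

WORKED_Q = [0.04, 0.04, 0.03, 1e-3, 1e-6]


def exact_upper_tail(n: int, N: int, p: float) -> float:
    """Independent tail summation P(X >= n), X ~ Binomial(N, p)."""
    return sum(comb(N, k) * p**k * (1 - p) ** (N - k) for k in range(n, N + 1))


class TestVisibility:
    def test_hand_summed_marginals(self):
        cc = ContactCounts({(1, 2): 8, (1, 3): 1, (2, 3): 1})
        v = fragment_visibility(cc)
        assert v.end_counts == {1: 9, 2: 9, 3: 2}
        assert cc.total == 10
        assert v.relative == {1: 0.45, 2: 0.45, 3: 0.1}

    def test_single_pair_symmetry(self):
        v = fragment_visibility(ContactCounts({(1, 2): 1}))
        assert v.relative == {1: 0.5, 2: 0.5}

    def test_end_counts_sum_to_twice_total(self, rng):
        pairs = {}
        for _ in range(30):
            i, j = sorted(rng.integers(1, 20, size=2))
            if i != j:
                pairs[(int(i), int(j))] = int(rng.integers(1, 50))
        cc = ContactCounts(pairs)
        v = fragment_visibility(cc)
        assert sum(v.end_counts.values()) == 2 * cc.total
        assert abs(sum(v.relative.values()) - 1.0) < 1e-12

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ContactCounts({})
        with pytest.raises(ValueError):
            ContactCounts({(1, 1): 3})
        with pytest.raises(ValueError):
            ContactCounts({(1, 2): 0})


class TestBinomialTest:
    def test_worked_example_exact_tail(self):
        cc = ContactCounts({(1, 2): 8, (1, 3): 1, (2, 3): 1})
        out = binomial_interaction_test(cc)
        row = out[(out.frag_i == 1) & (out.frag_j == 2)].iloc[0]
        assert row["expected_p"] == pytest.approx(2 * 0.45 * 0.45)
        assert row["pvalue"] == pytest.approx(exact_upper_tail(8, 10, 0.405), rel=1e-12)

    def test_saturated_pair_tail_identity(self):
        # a pair holding all N reads: P(X >= N) = p^N <= p
        cc = ContactCounts({(1, 2): 5})
        out = binomial_interaction_test(cc)
        p_ij = out["expected_p"].iloc[0]
        assert out["pvalue"].iloc[0] == pytest.approx(p_ij**5)
        assert out["pvalue"].iloc[0] <= p_ij

    def test_enumeration_oracle_small_tables(self):
        # every contact table on 3 fragments with N <= 8 (exhaustive here;
        # the acceptance suite pushes to N <= 12)
        for a, b, c in itertools.product(range(9), repeat=3):
            if a + b + c == 0 or a + b + c > 8:
                continue
            raw = {(1, 2): a, (1, 3): b, (2, 3): c}
            table = {k: v for k, v in raw.items() if v > 0}
            cc = ContactCounts(table)
            v = fragment_visibility(cc).relative
            out = binomial_interaction_test(cc)
            assert set(zip(out.frag_i, out.frag_j)) == set(table)
            N = cc.total
            for row in out.itertuples():
                p_ij = 2 * v[row.frag_i] * v[row.frag_j]
                n_ij = table[(row.frag_i, row.frag_j)]
                assert row.pvalue == pytest.approx(
                    exact_upper_tail(n_ij, N, p_ij), rel=1e-9, abs=1e-12
                )

    def test_bait_restriction_tests_bait_other_only(self):
        from chicbench import BaitMap

        cc = ContactCounts({(1, 2): 3, (1, 3): 2, (2, 3): 1, (3, 4): 4})
        bm = BaitMap({1: "a", 2: "b"})
        out = binomial_interaction_test(cc, bm)
        tested = set(zip(out.frag_i, out.frag_j))
        assert tested == {(1, 3), (2, 3)}  # no bait-bait, no other-other

    def test_output_deterministically_sorted(self):
        cc = ContactCounts({(1, 2): 2, (1, 3): 2, (2, 3): 2})
        out = binomial_interaction_test(cc)
        assert list(out.columns) == [
            "frag_i", "frag_j", "observed", "expected_p", "pvalue", "qvalue",
        ]
        assert (out.qvalue.diff().fillna(0) >= 0).all()

    def test_null_pvalues_superuniform(self, rng):
        # draw pairs i.i.d. from the model's own null and check the
        # one-sided KS statistic does not flag sub-uniform p-values
        m = 40
        w = rng.lognormal(0, 0.4, size=m)
        iu, ju = np.triu_indices(m, k=1)
        probs = w[iu] * w[ju]
        probs /= probs.sum()
        draws = rng.multinomial(20_000, probs)
        nz = draws > 0
        cc = ContactCounts(
            {(int(iu[k] + 1), int(ju[k] + 1)): int(draws[k]) for k in np.nonzero(nz)[0]}
        )
        out = binomial_interaction_test(cc)
        res = stats.ks_1samp(out.pvalue, stats.uniform.cdf, alternative="greater")
        assert res.pvalue > 0.01


class TestBHAdjust:
    def test_hand_computed_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_ties(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert bh_adjust([0.1, 0.1, 0.1]) == pytest.approx([0.1, 0.1, 0.1])

    def test_monotone_and_dominates_p(self, rng):
        p = rng.random(200)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_permutation_invariance(self, rng):
        p = rng.random(50)
        perm = rng.permutation(50)
        q = bh_adjust(p)
        q_perm = bh_adjust(p[perm])
        assert q_perm == pytest.approx(q[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestLFCurve:
    def test_worked_example(self):
        curve = cumulative_significance_curve(WORKED_Q)
        assert list(curve.levels) == [1, 2, 3, 6]
        assert list(curve.cumulative) == [5, 3, 2, 1]
        assert curve.slopes == pytest.approx([-2.0, -1.0, -1.0 / 3.0])

    def test_all_equal_single_level(self):
        curve = cumulative_significance_curve([0.04, 0.04])
        assert len(curve.levels) == 1
        assert curve.slopes.size == 0
        assert curve.cumulative[0] == 2

    def test_q_one_maps_to_level_zero(self):
        curve = cumulative_significance_curve([1.0, 0.5])
        assert curve.levels[0] == 0.0

    def test_zero_q_floored(self):
        curve = cumulative_significance_curve([0.0, 0.01])
        assert curve.levels[-1] == 300  # default floor 1e-300

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cumulative_significance_curve([])

    def test_cumulative_starts_at_count_and_decreases(self, rng):
        for _ in range(20):
            q = 10 ** -rng.uniform(0.1, 9, size=rng.integers(1, 40))
            curve = cumulative_significance_curve(q)
            assert curve.cumulative[0] == len(q)
            assert np.all(np.diff(curve.cumulative) < 0)
            assert np.all(curve.slopes <= 0)


class TestLFThreshold:
    def test_worked_example_threshold(self):
        curve = cumulative_significance_curve(WORKED_Q)
        # |s| = {2, 1, 1/3}: only the first slope is above 1
        assert lf_threshold(curve) == 2.0
        assert lf_threshold(curve, "first-shallow") == 2.0

    def test_all_shallow_keeps_lowest_level(self):
        curve = cumulative_significance_curve([0.04, 0.01, 0.001])
        # one call per level: every slope magnitude <= 1
        assert np.all(np.abs(curve.slopes) <= 1)
        assert lf_threshold(curve) == curve.levels[0]

    def test_steep_throughout_keeps_top_level(self):
        q2 = [0.1] * 11 + [0.01] * 6 + [1e-3] * 4 + [1e-4] * 2
        curve2 = cumulative_significance_curve(q2)
        assert np.all(np.abs(curve2.slopes) > 1)
        assert lf_threshold(curve2) == curve2.levels[-1]
        assert lf_threshold(curve2, "first-shallow") == curve2.levels[-1]

    def test_unknown_rule_rejected(self):
        curve = cumulative_significance_curve(WORKED_Q)
        with pytest.raises(ValueError):
            lf_threshold(curve, "median")


class TestLocalFilter:
    def test_worked_example_retains_three(self):
        cs = CallSet.from_records(
            [(1, 10 + k, q) for k, q in enumerate(WORKED_Q)]
        )
        out, thresholds = local_filter(cs)
        assert thresholds == {1: 2.0}
        assert len(out) == 3
        kept_q = sorted(out.df["metric_value"])
        assert kept_q == [1e-6, 1e-3, 0.03]

    def test_single_interaction_bait_retained(self):
        cs = CallSet.from_records([(1, 5, 0.04)])
        out, thresholds = local_filter(cs)
        assert len(out) == 1 and thresholds == {1: 1.0}

    def test_baits_processed_independently(self):
        recs = [(1, 10 + k, q) for k, q in enumerate(WORKED_Q)]
        recs += [(2, 30 + k, q) for k, q in enumerate([0.04, 0.02])]
        a, _ = local_filter(CallSet.from_records(recs))
        b, _ = local_filter(CallSet.from_records(recs[::-1]))
        assert a.pairs() == b.pairs()

    def test_output_subset_and_level_separation(self, rng):
        recs = []
        for bait in range(1, 6):
            n = int(rng.integers(2, 30))
            q = 10 ** -rng.uniform(1.31, 8, size=n)
            recs += [(bait, 100 * bait + k, float(v)) for k, v in enumerate(q)]
        cs = CallSet.from_records(recs)
        out, thresholds = local_filter(cs)
        assert out.pairs() <= cs.pairs()
        for bait, t in thresholds.items():
            kept = out.df[out.df.bait_id == bait]["metric_value"]
            dropped = cs.df[
                (cs.df.bait_id == bait)
                & ~cs.df.set_index(["bait_id", "oe_id"]).index.isin(
                    out.df.set_index(["bait_id", "oe_id"]).index
                )
            ]["metric_value"]
            if len(kept) and len(dropped):
                lv = lambda q: np.floor(-np.log10(np.asarray(q)) + 0.5)
                assert lv(kept).min() >= lv(dropped).max()

    def test_score_metric_rejected(self):
        cs = CallSet.from_records([(1, 2, 7.0)], metric_kind="score")
        with pytest.raises(ValueError, match="q-value"):
            local_filter(cs)


class TestContactCountsIO:
    def test_round_trip(self, tmp_path, rng):
        cc = ContactCounts({(1, 2): 3, (2, 5): 7, (1, 9): 1})
        p = tmp_path / "c.tsv"
        write_contact_counts(p, cc)
        assert read_contact_counts(p).counts == cc.counts
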