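"""Kaplan-Meier estimator, k-group log-rank / Cox p-values, and the Rand /
adjusted Rand partition indices."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from lifelines import KaplanMeierFitter

from omifuse.evaluate import (
    adjusted_rand_index,
    compare_partitions,
    cox_test,
    kaplan_meier,
    logrank_test,
    rand_index,
)
from omifuse.omics_io import ClinicalTable
from omifuse.spectral import ClusterAssignment


def _assignment(ids, labels):
    labels = np.asarray(labels, dtype=int)
    return ClusterAssignment(
        list(ids), labels, int(labels.max()), np.zeros((len(ids), 1))
    )


class TestKaplanMeier:
    def test_no_events_curve_is_identically_one(self):
        clin = ClinicalTable(["a", "b"], [5.0, 9.0], [0, 0])
        curve = kaplan_meier(clin)
        assert curve.times.size == 0
        assert curve.survival_at(0.0) == 1.0 and curve.survival_at(100.0) == 1.0

    def test_single_death_halves_survival(self):
        clin = ClinicalTable(["a", "b"], [5.0, 10.0], [1, 0])
        curve = kaplan_meier(clin)
        np.testing.assert_allclose(curve.times, [5.0])
        np.testing.assert_allclose(curve.survival, [0.5])
        assert curve.survival_at(7.0) == 0.5 and curve.survival_at(4.9) == 1.0

    def test_matches_independent_product_limit_oracle(self, six_subject_clinical):
        """Ties (death + censoring at t=5) against lifelines' estimator."""
        curve = kaplan_meier(six_subject_clinical)
        kmf = KaplanMeierFitter().fit(
            six_subject_clinical.time, six_subject_clinical.event
        )
        for t in [0.0, 2.0, 5.0, 7.9, 8.0, 10.0, 11.0, 12.0]:
            assert curve.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-12
            )

    def test_oracle_agreement_on_random_censored_data(self, rng):
        time = np.round(rng.exponential(50.0, 40), 0) + 1.0  # forced ties
        event = (rng.uniform(size=40) < 0.7).astype(int)
        clin = ClinicalTable([f"s{i}" for i in range(40)], time, event)
        curve = kaplan_meier(clin)
        kmf = KaplanMeierFitter().fit(time, event)
        for t in np.unique(time):
            assert curve.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-12
            )

    def test_no_censoring_equals_empirical_survival(self, rng):
        time = rng.exponential(10.0, 25)
        clin = ClinicalTable([f"s{i}" for i in range(25)], time, np.ones(25, int))
        curve = kaplan_meier(clin)
        for t in curve.times:
            assert curve.survival_at(t) == pytest.approx(
                np.mean(time > t), abs=1e-12
            )

    def test_mask_subsets_and_empty_subset_rejected(self, six_subject_clinical):
        curve = kaplan_meier(six_subject_clinical, mask=np.arange(6) < 2)
        np.testing.assert_allclose(curve.times, [2.0, 5.0])
        with pytest.raises(ValueError, match="empty"):
            kaplan_meier(six_subject_clinical, mask=np.zeros(6, dtype=bool))


def _two_group_logrank_oracle(time, event, group):
    """Closed-form (O1 - E1)^2 / V1 two-group log-rank statistic."""
    o1 = e1 = v1 = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v1 += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o1 - e1) ** 2 / v1


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        ids = [f"s{i}" for i in range(8)]
        time = np.array([3.0, 6.0, 9.0, 12.0] * 2)
        event = np.array([1, 0, 1, 1] * 2)
        clin = ClinicalTable(ids, time, event)
        a = _assignment(ids, [1, 1, 1, 1, 2, 2, 2, 2])
        res = logrank_test(clin, a)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0, abs=1e-10)

    def test_two_group_closed_form_oracle(self, rng):
        time = np.round(rng.exponential(30.0, 10), 0) + 1
        event = (rng.uniform(size=10) < 0.8).astype(int)
        event[0] = 1
        group = np.array([1, 2] * 5)
        ids = [f"s{i}" for i in range(10)]
        res = logrank_test(ClinicalTable(ids, time, event), _assignment(ids, group))
        assert res.statistic == pytest.approx(
            _two_group_logrank_oracle(time, event, group), abs=1e-10
        )
        assert res.df == 1

    def test_power_under_strong_hazard_separation(self, rng):
        hits = 0
        n = 200
        ids = [f"s{i}" for i in range(n)]
        group = np.repeat([1, 2], n // 2)
        for _ in range(100):
            lam = np.where(group == 1, 0.01, 0.03)
            t = rng.exponential(1.0 / lam)
            c = rng.uniform(0, 5.0 / 0.01, size=n)
            time = np.minimum(t, c)
            event = (t <= c).astype(int)
            res = logrank_test(ClinicalTable(ids, time, event), _assignment(ids, group))
            hits += res.p_value < 0.01
        assert hits >= 95

    def test_degenerate_inputs_rejected(self):
        ids = ["a", "b", "c"]
        clin = ClinicalTable(ids, [1.0, 2.0, 3.0], [1, 1, 1])
        with pytest.raises(ValueError, match="2 non-empty groups"):
            logrank_test(clin, _assignment(ids, [1, 1, 1]))
        clin0 = ClinicalTable(ids, [1.0, 2.0, 3.0], [0, 0, 0])
        with pytest.raises(ValueError, match="event"):
            logrank_test(clin0, _assignment(ids, [1, 1, 2]))

    def test_cox_lrt_agrees_with_logrank_asymptotically(self, rng):
        n = 120
        ids = [f"s{i}" for i in range(n)]
        group = np.repeat([1, 2], n // 2)
        lam = np.where(group == 1, 0.01, 0.025)
        t = rng.exponential(1.0 / lam)
        clin = ClinicalTable(ids, t, np.ones(n, int))
        a = _assignment(ids, group)
        p_lr = logrank_test(clin, a).p_value
        res_cox = cox_test(clin, a)
        assert res_cox.method == "cox_lrt"
        # same asymptotics: log-p within ~20% on a clear signal
        assert np.log(res_cox.p_value) == pytest.approx(np.log(p_lr), rel=0.25)


class TestPartitionIndices:
    def test_identical_partitions(self):
        a = [1, 1, 2, 3, 3]
        assert rand_index(a, a) == 1.0
        assert adjusted_rand_index(a, a) == 1.0

    def test_all_same_vs_singletons_has_no_agreeing_pairs(self):
        assert rand_index([1, 1, 1], [1, 2, 3]) == 0.0

    def test_hand_worked_two_by_two(self):
        a, b = [1, 1, 2, 2], [1, 2, 1, 2]
        assert rand_index(a, b) == pytest.approx(1 / 3, abs=1e-12)
        assert adjusted_rand_index(a, b) == pytest.approx(-0.5, abs=1e-12)

    def test_matches_brute_force_pair_counting(self, rng):
        a = rng.integers(1, 4, size=25)
        b = rng.integers(1, 5, size=25)
        agree = total = 0
        for i in range(25):
            for j in range(i + 1, 25):
                total += 1
                agree += (a[i] == a[j]) == (b[i] == b[j])
        assert rand_index(a, b) == pytest.approx(agree / total, abs=1e-10)

    def test_ari_matches_hubert_arabie_formula(self, rng):
        from scipy.special import comb

        a = rng.integers(1, 4, size=30)
        b = rng.integers(1, 4, size=30)
        cmp_ = compare_partitions(a, b)
        nij = cmp_.contingency
        sum_ij = comb(nij, 2).sum()
        sum_a = comb(nij.sum(axis=1), 2).sum()
        sum_b = comb(nij.sum(axis=0), 2).sum()
        expected_idx = sum_a * sum_b / comb(30, 2)
        max_idx = (sum_a + sum_b) / 2
        ari = (sum_ij - expected_idx) / (max_idx - expected_idx)
        assert cmp_.adjusted_rand_index == pytest.approx(ari, abs=1e-10)
        assert nij.sum() == 30

    @given(st.lists(st.integers(1, 4), min_size=2, max_size=20))
    def test_symmetric_and_renaming_invariant(self, labels):
        a = np.asarray(labels)
        b = np.roll(a, 1)
        assert rand_index(a, b) == pytest.approx(rand_index(b, a), abs=1e-12)
        assert adjusted_rand_index(a, b) == pytest.approx(
            adjusted_rand_index(b, a), abs=1e-12
        )
        renamed = np.asarray([{1: 4, 2: 3, 3: 2, 4: 1}[x] for x in a])
        assert adjusted_rand_index(a, b) == pytest.approx(
            adjusted_rand_index(renamed, b), abs=1e-12
        )

    def test_ari_is_one_iff_identical_up_to_renaming(self, rng):
        a = rng.integers(1, 4, size=20)
        renamed = (a % 3) + 1  # bijective relabeling of {1,2,3}
        assert adjusted_rand_index(a, renamed) == 1.0
        b = a.copy()
        b[0] = b[0] % 3 + 1  # break one sample
        if len(set(a.tolist())) > 1:
            assert adjusted_rand_index(a, b) < 1.0

    def test_degenerate_single_cluster_pair(self):
        assert adjusted_rand_index([1, 1, 1], [2, 2, 2]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            rand_index([1, 2], [1, 2, 3])
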