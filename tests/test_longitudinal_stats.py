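"""Screening statistics against hand-computed values and closed-form
distribution tails, plus the intersection rule's set properties."""

import numpy as np
import pytest
from scipy import special

from corrtf.longitudinal_stats import (DegenerateTestError,
                                       GroupConnectionSample,
                                       classify_sign_pattern,
                                       find_significant_connections,
                                       normalize_subject_profiles,
                                       normalize_sum_squares, oneway_anova,
                                       paired_ttest)


def t_sf_two_sided(t, df):
    """Two-sided t tail via the regularized incomplete beta function."""
    return float(special.betainc(df / 2, 0.5, df / (df + t * t)))


def f_sf(f, d1, d2):
    """F distribution upper tail via the regularized incomplete beta."""
    return float(special.betainc(d2 / 2, d1 / 2, d2 / (d2 + d1 * f)))


class TestNormalize:
    def test_three_four_five(self):
        np.testing.assert_allclose(normalize_sum_squares([3.0, 4.0]), [0.6, 0.8])

    def test_unit_vector_unchanged(self):
        np.testing.assert_allclose(normalize_sum_squares([1.0, 0.0, 0.0]),
                                   [1.0, 0.0, 0.0])

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateTestError):
            normalize_sum_squares([0.0, 0.0])

    def test_output_has_unit_sum_of_squares(self, rng):
        v = rng.normal(size=37)
        assert np.sum(normalize_sum_squares(v) ** 2) == pytest.approx(1.0, abs=1e-12)

    def test_per_subject_profile_normalization(self, rng):
        stack = rng.normal(size=(4, 3, 5, 5))
        for s in range(4):
            for v in range(3):
                stack[s, v][np.eye(5, dtype=bool)] = np.nan
        out = normalize_subject_profiles(stack)
        ss = np.nansum(out.reshape(4, 3, -1) ** 2, axis=-1)
        np.testing.assert_allclose(ss, 1.0, atol=1e-12)


class TestPairedT:
    def test_hand_computed_example(self):
        """Differences (1, 2, 1): mean 4/3, sd 1/sqrt(3), t = 4 on df 2."""
        t, p = paired_ttest([1.0, 2.0, 4.0], [2.0, 4.0, 5.0])
        assert t == pytest.approx(4.0, abs=1e-12)
        assert p == pytest.approx(t_sf_two_sided(4.0, 2), abs=1e-10)

    def test_zero_mean_difference(self):
        t, p = paired_ttest([0.0, 0.0], [1.0, -1.0])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_constant_differences_degenerate(self):
        with pytest.raises(DegenerateTestError):
            paired_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0, 2.0], [1.0, 2.0, 3.0])


class TestAnova:
    def test_hand_computed_example(self):
        """Groups (1,2), (3,4), (5,6): SSB = 16, SSW = 1.5, F = 16 on (2, 3)."""
        f, p = oneway_anova([1.0, 2.0], [3.0, 4.0], [5.0, 6.0])
        assert f == pytest.approx(16.0, abs=1e-12)
        assert p == pytest.approx(f_sf(16.0, 2, 3), abs=1e-10)

    def test_identical_groups_give_zero_f(self):
        f, p = oneway_anova([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_all_constant_degenerate(self):
        with pytest.raises(DegenerateTestError):
            oneway_anova([1.0, 1.0], [1.0, 1.0], [1.0, 1.0])


class TestSignPattern:
    @pytest.mark.parametrize("t1, t2, want", [
        (2.5, -3.1, "positive_to_negative"),
        (-2.0, 2.0, "negative_to_positive"),
        (1.0, 2.0, "same_sign_positive"),
        (-1.0, -0.5, "same_sign_negative"),
        (0.0, 1.5, "same_sign_positive"),
        (0.0, -1.5, "same_sign_negative"),
        (0.0, 0.0, "same_sign_positive"),
    ])
    def test_patterns(self, t1, t2, want):
        assert classify_sign_pattern(t1, t2) == want

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_sign_pattern(np.nan, 1.0)


class TestFindSignificant:
    def _samples(self, rng, n_conn=40, n_subj=12, shift=0.0):
        out = []
        for c in range(n_conn):
            vals = rng.normal(size=(n_subj, 3))
            if shift:
                vals[:, 1] += shift
                vals[:, 2] += 2 * shift
            out.append(GroupConnectionSample("G", (c + 1, c + 2), vals))
        return out

    def test_significance_is_exactly_all_three_p_below_alpha(self, rng):
        results = find_significant_connections(self._samples(rng, shift=0.6))
        for r in results:
            want = (r.p_baseline_v1 < 0.05 and r.p_v1_v2 < 0.05
                    and r.p_anova < 0.05 and not r.degenerate)
            assert r.significant == want

    def test_p_values_match_independent_recomputation(self, rng):
        samples = self._samples(rng, n_conn=20, shift=0.4)
        results = find_significant_connections(samples)
        for s, r in zip(samples, results):
            v = s.per_visit_values
            n = v.shape[0]
            d = v[:, 1] - v[:, 0]
            t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            assert r.t_baseline_v1 == pytest.approx(t, abs=1e-10)
            assert r.p_baseline_v1 == pytest.approx(t_sf_two_sided(t, n - 1),
                                                    abs=1e-10)
            groups = [v[:, k] for k in range(3)]
            gm = np.mean(v)
            ssb = sum(len(g) * (g.mean() - gm) ** 2 for g in groups)
            ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
            f = (ssb / 2) / (ssw / (3 * n - 3))
            assert r.f_anova == pytest.approx(f, abs=1e-10)
            assert r.p_anova == pytest.approx(f_sf(f, 2, 3 * n - 3), abs=1e-10)

    def test_alpha_nestedness(self, rng):
        samples = self._samples(rng, n_conn=120, shift=0.45)
        sets = {}
        for alpha in (0.05, 0.01, 0.001):
            res = find_significant_connections(samples, alpha=alpha)
            sets[alpha] = {r.connection for r in res if r.significant}
        assert sets[0.001] <= sets[0.01] <= sets[0.05]

    def test_degenerate_connection_flagged_not_dropped(self, rng):
        samples = self._samples(rng, n_conn=3)
        samples[1] = GroupConnectionSample(
            "G", (9, 10), np.tile([1.0, 2.0, 3.0], (5, 1)))  # constant diffs
        results = find_significant_connections(samples)
        assert len(results) == 3
        flagged = {r.connection: r for r in results}[(9, 10)]
        assert flagged.degenerate and not flagged.significant

    def test_cross_subject_normalization_mode(self, rng):
        samples = self._samples(rng, n_conn=5)
        results = find_significant_connections(samples, normalize=True)
        assert len(results) == 5  # runs; statistics finite
        assert all(np.isfinite(r.t_baseline_v1) for r in results)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="at least 2 subjects"):
            GroupConnectionSample("G", (1, 2), np.zeros((1, 3)))

    def test_empty_sample_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            find_significant_connections([])

    def test_bh_correction_never_grows_the_set(self, rng):
        samples = self._samples(rng, n_conn=80, shift=0.4)
        plain = {r.connection for r in find_significant_connections(samples)
                 if r.significant}
        bh = {r.connection
              for r in find_significant_connections(samples, correction="bh")
              if r.significant}
        assert bh <= plain

    def test_deterministic_results(self, rng):
        samples = self._samples(rng, n_conn=10, shift=0.5)
        a = find_significant_connections(samples)
        b = find_significant_connections(samples)
        assert [(r.connection, r.t_baseline_v1, r.p_anova, r.significant)
                for r in a] == \
               [(r.connection, r.t_baseline_v1, r.p_anova, r.significant)
                for r in b]
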