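import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from triomr.transforms import (qc_filter, rank_inverse_normal, score_scale,
                               sex_stratified_z)


def pheno_frame(rows):
    return pd.DataFrame(rows, columns=["gestational_age_weeks", "birth_weight_kg",
                                       "congenital_anomaly", "multiple_birth"])


class TestQcFilter:
    def test_boundary_semantics(self):
        df = pheno_frame([
            (36.9, 3.5, False, False),   # preterm: excluded
            (37.0, 3.5, False, False),   # boundary gestation: retained
            (40.0, 2.5, False, False),   # boundary low weight: excluded
            (40.0, 2.51, False, False),  # just above: retained
            (40.0, 5.0, False, False),   # boundary high weight: excluded
            (40.0, 4.99, False, False),  # just below: retained
        ])
        kept, report = qc_filter(df)
        assert list(kept.index) == [1, 3, 5]
        assert report.n_excluded_gestation == 1
        assert report.n_excluded_birthweight == 2

    def test_precedence_flags_then_gestation_then_weight(self):
        df = pheno_frame([
            (35.0, 2.0, True, False),   # flagged wins over both
            (35.0, 2.0, False, False),  # gestation wins over weight
            (40.0, 2.0, False, False),  # weight
        ])
        _, report = qc_filter(df)
        assert (report.n_excluded_other, report.n_excluded_gestation,
                report.n_excluded_birthweight) == (1, 1, 1)
        assert report.n_retained == 0

    def test_empty_table(self):
        kept, report = qc_filter(pheno_frame([]))
        assert len(kept) == 0 and report.n_input == 0 and report.n_retained == 0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pheno_frame(list(zip(rng.normal(39, 2, 200), rng.normal(3.5, 0.6, 200),
                                  rng.random(200) < 0.05, rng.random(200) < 0.05)))
        once, r1 = qc_filter(df)
        twice, r2 = qc_filter(once)
        assert once.equals(twice)
        assert r2.n_retained == r2.n_input == r1.n_retained

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="required"):
            qc_filter(pd.DataFrame({"birth_weight_kg": [3.0]}))


class TestScoreScale:
    def test_fifty_percent_rule(self):
        row_ok = [1.0] * 5 + [np.nan] * 5    # 5/10 observed: scored
        row_bad = [1.0] * 4 + [np.nan] * 6   # 4/10 observed: missing
        out = score_scale(np.array([row_ok, row_bad]))
        assert out[0] == pytest.approx(10.0)  # mean 1.0 x 10 items
        assert np.isnan(out[1])

    @given(st.integers(2, 30), st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_complete_data_equals_row_sum(self, n_items, seed):
        rng = np.random.default_rng(seed)
        items = rng.normal(size=(7, n_items))
        assert np.allclose(score_scale(items), items.sum(axis=1))

    def test_zero_width_matrix_rejected(self):
        with pytest.raises(ValueError):
            score_scale(np.empty((3, 0)))


class TestRankInverseNormal:
    def test_matches_blom_closed_form_n5(self):
        x = np.array([10.0, -3.0, 0.5, 7.0, 2.0])
        out = rank_inverse_normal(x)
        ranks = stats.rankdata(x)
        expected = stats.norm.ppf((ranks - 0.375) / (5 + 0.25))
        assert np.allclose(out, expected, atol=1e-12)

    def test_symmetric_input_maps_to_symmetric_output(self):
        out = rank_inverse_normal(np.array([-1.0, 0.0, 1.0]))
        assert out[1] == pytest.approx(0.0, abs=1e-12)
        assert out[0] == pytest.approx(-out[2], abs=1e-12)

    @given(st.lists(st.floats(1.0, 1e4), min_size=3, max_size=40, unique=True))
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_monotone_transforms(self, xs):
        # cubing is strictly increasing and injective on distinct doubles >= 1
        x = np.array(xs)
        assert np.allclose(rank_inverse_normal(x),
                           rank_inverse_normal(x ** 3), atol=1e-12)

    def test_missing_stays_missing_and_rest_shift(self):
        x = np.array([3.0, np.nan, 1.0, 2.0])
        out = rank_inverse_normal(x)
        assert np.isnan(out[1])
        assert np.argsort(out[[0, 2, 3]]).tolist() == np.argsort(x[[0, 2, 3]]).tolist()

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            rank_inverse_normal(np.array([np.nan, np.nan]))

    def test_ties_share_average_rank(self):
        out = rank_inverse_normal(np.array([1.0, 1.0, 5.0]))
        assert out[0] == out[1] < out[2]


class TestSexStratifiedZ:
    def test_per_stratum_moments(self, rng):
        bw = rng.normal(3.5, 0.5, 500)
        sex = rng.choice(["M", "F"], 500)
        z = sex_stratified_z(bw, sex)
        for s in ("M", "F"):
            assert np.mean(z[sex == s]) == pytest.approx(0.0, abs=1e-12)
            assert np.std(z[sex == s], ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_removes_between_sex_mean_difference(self, rng):
        bw = np.concatenate([rng.normal(3.6, 0.4, 100), rng.normal(3.2, 0.4, 100)])
        sex = np.array(["M"] * 100 + ["F"] * 100)
        z = sex_stratified_z(bw, sex)
        assert abs(z[:100].mean() - z[100:].mean()) < 1e-12

    def test_hand_computed_small_strata(self):
        z = sex_stratified_z(np.array([3.0, 4.0, 2.0, 6.0]),
                             np.array(["M", "M", "F", "F"]))
        root_half = np.sqrt(0.5)
        assert np.allclose(z, [-root_half, root_half, -root_half, root_half])

    def test_tiny_stratum_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            sex_stratified_z(np.array([3.0, 4.0, 2.0]), np.array(["M", "M", "F"]))
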