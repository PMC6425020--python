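"""Behavioral RDMs, noise ceiling, commonality analysis, task performance."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, rankdata, spearmanr

from megrsa.core import GroupTimecourse, ModelRDM, RDMSeries, square_from_lower_triangle
from megrsa.behavior import (
    behavioral_performance,
    behavioral_rdm,
    commonality_analysis,
    meg_behavior_correlation,
    noise_ceiling,
)
from megrsa.rsa import partial_spearman
from megrsa.synthetic_data import classical_scaling


def series_from_vectors(vectors, n):
    vals = square_from_lower_triangle(np.atleast_2d(vectors), n)
    T = vals.shape[0]
    times = 5.0 * np.arange(T) if T > 1 else np.array([0.0])
    return RDMSeries(vals, times, np.arange(n))


class TestBehavioralRDM:
    def test_reference_distances(self):
        pos = np.array([[0.0, 0.0], [3.0, 4.0], [0.0, 0.0]])
        rdm = behavioral_rdm(pos)
        assert rdm.values[1, 0] == pytest.approx(25.0)
        assert rdm.values[2, 0] == pytest.approx(0.0)
        assert np.isnan(rdm.values[0, 0])

    def test_embedding_roundtrip_rank_correlation(self, rng):
        target = rng.random((10, 10))
        target = target + target.T
        np.fill_diagonal(target, 0.0)
        # distances of a genuinely 2-D configuration are exactly recoverable
        pos0 = rng.standard_normal((10, 2))
        d2 = ((pos0[:, None] - pos0[None, :]) ** 2).sum(axis=2)
        pos = classical_scaling(d2)
        rdm = behavioral_rdm(pos)
        i, j = np.tril_indices(10, k=-1)
        assert spearmanr(rdm.values[i, j], d2[i, j]).statistic == pytest.approx(1.0)

    def test_degenerate_arrangement_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            behavioral_rdm(np.ones((5, 2)))
        with pytest.raises(ValueError):
            behavioral_rdm(np.array([[0.0, np.inf], [1.0, 1.0]]))


class TestMEGBehaviorCorrelation:
    def test_behavior_equal_to_data_gives_one(self, rng):
        n = 8
        v = rng.random(28)
        rdms = series_from_vectors(v, n)
        behavior = ModelRDM(square_from_lower_triangle(v.copy(), n), "behavior")
        low = ModelRDM(square_from_lower_triangle(rng.random(28), n), "low")
        rho = meg_behavior_correlation(rdms, behavior, low)
        assert rho[0] == pytest.approx(1.0, abs=1e-10)

    def test_behavior_equal_to_low_level_gives_zero(self, rng):
        n = 8
        low_vec = rng.random(28)
        rdms = series_from_vectors(rng.random((3, 28)), n)
        behavior = ModelRDM(square_from_lower_triangle(low_vec.copy(), n), "behavior")
        low = ModelRDM(square_from_lower_triangle(low_vec.copy(), n), "low")
        with pytest.warns(UserWarning, match="zero residual"):
            rho = meg_behavior_correlation(rdms, behavior, low)
        assert np.allclose(rho, 0.0, atol=1e-10)

    def test_scaling_positions_leaves_correlation_unchanged(self, rng):
        n = 8
        pos = rng.standard_normal((n, 2))
        rdms = series_from_vectors(rng.random((2, 28)), n)
        r1 = meg_behavior_correlation(rdms, behavioral_rdm(pos))
        r2 = meg_behavior_correlation(rdms, behavioral_rdm(3.7 * pos))
        assert np.allclose(r1, r2, atol=1e-12)


class TestNoiseCeiling:
    def test_identical_subjects_hit_one(self, rng):
        v = rng.random(20)
        lower, upper = noise_ceiling([v.copy() for _ in range(5)])
        assert lower == pytest.approx(1.0)
        assert upper == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        vectors = [rng.standard_normal(300) for _ in range(8)]
        lower, upper = noise_ceiling(vectors)
        assert abs(lower) < 0.2 and abs(upper) < 0.35
        assert lower <= upper

    def test_matches_hand_computed_oracle(self):
        vectors = [
            np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
            np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0]),
            np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0]),
            np.array([6.0, 5.0, 4.0, 3.0, 2.0, 1.0]),
        ]
        # independent computation: rank (already ranks), correlate against
        # means including/excluding self
        R = np.vstack([rankdata(v) for v in vectors])
        grand = R.mean(0)

        def corr(a, b):
            return np.corrcoef(a, b)[0, 1]

        exp_upper = np.mean([corr(R[i], grand) for i in range(4)])
        exp_lower = np.mean(
            [corr(R[i], (grand * 4 - R[i]) / 3) for i in range(4)]
        )
        lower, upper = noise_ceiling(vectors)
        assert upper == pytest.approx(exp_upper, abs=1e-12)
        assert lower == pytest.approx(exp_lower, abs=1e-12)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            noise_ceiling([rng.random(10), rng.random(10)])


def oracle_commonality(meg, beh, models, low, name):
    """Independent route: partial correlations from nested OLS R^2 on ranks."""

    def partial_r(x, y, covs):
        rx, ry = rankdata(x), rankdata(y)
        if covs:
            Z = np.column_stack([np.ones(len(rx))] + [rankdata(c) for c in covs])
            rx = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
            ry = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
        else:
            rx, ry = rx - rx.mean(), ry - ry.mean()
        return rx @ ry / np.sqrt((rx @ rx) * (ry @ ry))

    all_vecs = list(models.values())
    rest = [v for k, v in models.items() if k != name]
    r_full = partial_r(meg, beh, all_vecs + low)
    r_drop = partial_r(meg, beh, rest + low)
    return r_drop**2 - r_full**2


class TestCommonality:
    def make_orthogonal_toy(self):
        # 6 conditions, 15 pairs; orthogonal binary models
        g = np.array([1, 1, 1, 0, 0, 0, 1, 1, 0, 1, 0, 1, 0, 1, 0], dtype=float)
        a = np.array([0, 1, 0, 1, 0, 1, 1, 0, 1, 0, 1, 0, 1, 0, 1], dtype=float)
        return g, a

    def test_shared_gender_structure_attributed_to_gender(self):
        # data and behavior both exactly the gender model: all shared
        # variance is the gender commonality, none is the age commonality
        n = 6
        g, a = self.make_orthogonal_toy()
        rdms = series_from_vectors(g, n)
        behavior = ModelRDM(square_from_lower_triangle(g.copy(), n), "behavior")
        models = {
            "gender": ModelRDM(square_from_lower_triangle(g.copy(), n), "gender"),
            "age": ModelRDM(square_from_lower_triangle(a, n), "age"),
        }
        with pytest.warns(UserWarning, match="zero residual"):
            out = commonality_analysis(rdms, behavior, models)
        total = out.reference[0]
        assert total == pytest.approx(1.0, abs=1e-10)
        assert out.coefficients["gender"][0] == pytest.approx(total, abs=1e-10)
        assert out.coefficients["age"][0] == pytest.approx(0.0, abs=1e-10)

    def test_matches_bruteforce_oracle(self, rng):
        n = 6
        for trial in range(8):
            r = np.random.default_rng(trial)
            meg = r.random(15)
            beh_vec = r.random(15)
            models = {
                "m1": ModelRDM(square_from_lower_triangle(r.random(15), n), "m1"),
                "m2": ModelRDM(square_from_lower_triangle(r.integers(0, 2, 15) * 1.0, n), "m2"),
            }
            low = ModelRDM(square_from_lower_triangle(r.random(15), n), "low")
            rdms = series_from_vectors(meg, n)
            behavior = ModelRDM(square_from_lower_triangle(beh_vec, n), "behavior")
            out = commonality_analysis(rdms, behavior, models, low_level=low)
            for name in models:
                expected = oracle_commonality(
                    meg, beh_vec, {k: v.vector() for k, v in models.items()},
                    [low.vector()], name,
                )
                assert out.coefficients[name][0] == pytest.approx(expected, abs=1e-10)

    def test_orthogonal_model_contributes_nothing(self, rng):
        n = 6
        g, a = self.make_orthogonal_toy()
        meg = g + 0.01 * rng.standard_normal(15)
        rdms = series_from_vectors(meg, n)
        behavior = ModelRDM(square_from_lower_triangle(g + 0.01 * rng.standard_normal(15), n), "b")
        models = {
            "gender": ModelRDM(square_from_lower_triangle(g, n), "gender"),
            "age": ModelRDM(square_from_lower_triangle(a, n), "age"),
        }
        out = commonality_analysis(rdms, behavior, models)
        assert abs(out.coefficients["age"][0]) < 0.05

    def test_r_scale_flag(self, rng):
        n = 6
        meg, beh_vec = rng.random(15), rng.random(15)
        models = {"m": ModelRDM(square_from_lower_triangle(rng.random(15), n), "m")}
        rdms = series_from_vectors(meg, n)
        behavior = ModelRDM(square_from_lower_triangle(beh_vec, n), "b")
        r2 = commonality_analysis(rdms, behavior, models, scale="r2")
        r1 = commonality_analysis(rdms, behavior, models, scale="r")
        assert not np.allclose(r2.coefficients["m"], r1.coefficients["m"])
        with pytest.raises(ValueError):
            commonality_analysis(rdms, behavior, models, scale="bogus")

    def test_window_outside_times_rejected(self, rng):
        n = 6
        rdms = series_from_vectors(rng.random((2, 15)), n)
        behavior = ModelRDM(square_from_lower_triangle(rng.random(15), n), "b")
        models = {"m": ModelRDM(square_from_lower_triangle(rng.random(15), n), "m")}
        with pytest.raises(ValueError):
            commonality_analysis(rdms, behavior, models, window=(500.0, 600.0))


def make_trial_log(rows):
    return pd.DataFrame(
        rows, columns=["subject", "is_target", "responded", "rt_ms", "familiarity"]
    )


class TestBehavioralPerformance:
    def synth_log(self, hit, fa, n_targets=100, n_nontargets=400, subjects=(0,)):
        rows = []
        for s in subjects:
            for fam in ("familiar", "unfamiliar"):
                for i in range(n_targets):
                    rows.append([s, True, i < round(hit * n_targets), 450.0, fam])
                for i in range(n_nontargets):
                    rows.append([s, False, i < round(fa * n_nontargets), np.nan, fam])
        return make_trial_log(rows)

    def test_equal_hit_and_false_alarm_rates_give_zero(self):
        out = behavioral_performance(self.synth_log(hit=0.5, fa=0.5))
        assert out.dprime[0] == pytest.approx(0.0, abs=1e-12)

    def test_reference_dprime_value(self):
        # hit 0.99, fa 0.01 -> d' = 2 * z(0.99) = 4.6527
        out = behavioral_performance(
            self.synth_log(hit=0.99, fa=0.01, n_targets=100, n_nontargets=100)
        )
        assert out.dprime[0] == pytest.approx(2 * norm.ppf(0.99), abs=1e-3)
        assert out.dprime[0] == pytest.approx(4.653, abs=1e-3)

    def test_perfect_rates_clipped_not_infinite(self):
        out = behavioral_performance(self.synth_log(hit=1.0, fa=0.0))
        assert np.isfinite(out.dprime[0])
        expected = norm.ppf(1 - 1 / 400) - norm.ppf(1 / 1600)
        assert out.dprime[0] == pytest.approx(expected, abs=1e-9)

    def test_identical_familiarity_conditions_p_one(self):
        log = self.synth_log(hit=0.9, fa=0.02, subjects=range(6))
        out = behavioral_performance(log)
        assert out.p_rt_familiarity == 1.0
        assert out.p_dprime_familiarity == 1.0

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            behavioral_performance(pd.DataFrame({"subject": [0]}))

    def test_no_targets_rejected(self):
        log = make_trial_log([[0, False, False, np.nan, "familiar"]])
        with pytest.raises(ValueError, match="target"):
            behavioral_performance(log)
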