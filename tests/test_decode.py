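"""Decoding: sub-averaging, pairwise CV accuracy, RDM construction,
temporal generalization and cross-category decoding.

The straightforward-loop oracle re-implements the fold bookkeeping with an
off-the-shelf SVM (sklearn's libsvm binding) and must reproduce the batched
solver's accuracies exactly.
"""

import numpy as np
import pytest
from sklearn.svm import SVC

from megrsa import DesignSpec, EffectComponent, EffectSpec
from megrsa.core import Epochs, ComponentEpochs, lower_triangle
from megrsa.decode import (
    DecodingConfig,
    build_rdm_series,
    cross_category_decode,
    image_decoding_timecourse,
    pairwise_decode_timepoint,
    subaverage_trials,
    temporal_generalization,
)
from megrsa.decode import _pseudotrials, _trials_by_condition
from megrsa.synthetic_data import (
    condition_table,
    generate_null_epochs,
    generate_subject_epochs,
)


def component_epochs_from_array(data, tmin=-50.0, step=10.0, condition_id=None):
    """Wrap a [trials, features, timepoints] array as ComponentEpochs."""
    data = np.asarray(data, dtype=float)
    n_trials, n_feat, n_tp = data.shape
    return ComponentEpochs(
        data=data,
        loadings=np.eye(n_feat),
        explained_variance_fraction=np.full(n_feat, 1.0 / n_feat),
        times=tmin + step * np.arange(n_tp),
        condition_id=np.asarray(condition_id)
        if condition_id is not None
        else np.zeros(n_trials, dtype=int),
        valid=np.ones(n_trials, dtype=bool),
    )


class TestSubaverage:
    def test_identical_trials_reproduced(self, rng):
        X = np.tile(np.array([1.0, 2.0, 3.0]), (5, 1))
        out = subaverage_trials(X, 5, rng)
        assert np.allclose(out, X)

    def test_group_sizes_near_equal(self):
        # 12 trials into 5 splits must give group sizes {3,3,2,2,2}; verify
        # against the partition the seeded rng produces
        X = np.arange(12, dtype=float)[:, None]
        perm = np.random.default_rng(0).permutation(12)
        groups = [perm[s::5] for s in range(5)]
        assert sorted(len(g) for g in groups) == [2, 2, 2, 3, 3]
        out = subaverage_trials(X, 5, np.random.default_rng(0))
        for s, g in enumerate(groups):
            assert out[s, 0] == pytest.approx(X[g, 0].mean())

    def test_k_equal_splits_is_permutation(self, rng):
        X = rng.standard_normal((5, 4))
        out = subaverage_trials(X, 5, rng)
        assert sorted(map(tuple, np.round(out, 12))) == sorted(map(tuple, np.round(X, 12)))

    def test_grand_mean_preserved_equal_groups(self, rng):
        X = rng.standard_normal((15, 3))
        out = subaverage_trials(X, 5, rng)
        assert np.allclose(out.mean(0), X.mean(0), atol=1e-12)

    def test_undersampled_rejected(self, rng):
        with pytest.raises(ValueError, match="under-sampled"):
            subaverage_trials(np.zeros((3, 2)), 5, rng)


class TestPairwiseDecode:
    def test_identical_pseudotrials_score_chance(self, rng):
        pseudo = rng.standard_normal((5, 8))
        assert pairwise_decode_timepoint(pseudo, pseudo.copy()) == 0.5

    def test_all_constant_features_warn_and_score_chance(self):
        pseudo = np.ones((5, 4))
        with pytest.warns(UserWarning, match="all-constant"):
            assert pairwise_decode_timepoint(pseudo, np.ones((5, 4))) == 0.5

    def test_wide_separation_perfect(self, rng):
        noise = rng.standard_normal((5, 6))
        a = noise + 100.0
        b = rng.standard_normal((5, 6)) - 100.0
        assert pairwise_decode_timepoint(a, b) == 1.0

    def test_matches_monte_carlo_oracle_1d(self, rng):
        # 1-D Gaussian classes, means +/-0.5, trial sd 1, 5 splits of 6 trials
        n_rounds = 800

        def draw_pseudo(r):
            trials_a = 0.5 + r.standard_normal((30, 1))
            trials_b = -0.5 + r.standard_normal((30, 1))
            return (
                subaverage_trials(trials_a, 5, r),
                subaverage_trials(trials_b, 5, r),
            )

        mine = np.mean(
            [pairwise_decode_timepoint(*draw_pseudo(rng)) for _ in range(n_rounds)]
        )
        oracle_rng = np.random.default_rng(999)
        oracle_acc = []
        for _ in range(n_rounds):
            a, b = draw_pseudo(oracle_rng)
            correct = 0
            for fold in range(5):
                keep = np.arange(5) != fold
                X = np.r_[a[keep], b[keep]]
                y = np.r_[np.ones(4), -np.ones(4)]
                clf = SVC(kernel="linear", C=1.0).fit(X, y)
                correct += int(clf.decision_function(a[fold : fold + 1])[0] > 0)
                correct += int(clf.decision_function(b[fold : fold + 1])[0] <= 0)
            oracle_acc.append(correct / 10.0)
        assert mine == pytest.approx(np.mean(oracle_acc), abs=0.05)


class TestBuildRDMSeries:
    def make_cep(self, rng, n_cond=4, k=8, d=6, n_tp=3, signal=None, labels=None):
        if labels is None:
            labels = np.repeat(np.arange(n_cond), k)
        data = rng.standard_normal((len(labels), d, n_tp))
        if signal is not None:
            data += signal[labels][:, :, None]
        return component_epochs_from_array(data, condition_id=labels)

    def make_table(self, n_cond):
        design = DesignSpec(
            n_identities=8, images_per_identity=max(1, n_cond // 8),
            n_trials_per_condition=4, n_channels=4,
        )
        return condition_table(design)

    def test_pair_count_symmetry_nan_diagonal(self, rng):
        cep = self.make_cep(rng, n_cond=4)
        design = DesignSpec(n_identities=8, images_per_identity=1)
        table = condition_table(design).subset(np.arange(8) < 4)
        rdms = build_rdm_series(cep, table, DecodingConfig(n_repetitions=2, seed=0))
        vals = rdms.values
        assert vals.shape == (3, 4, 4)
        assert np.isnan(vals[:, range(4), range(4)]).all()
        off = lower_triangle(vals)
        assert off.shape == (3, 6)
        assert np.all((off >= 0) & (off <= 1))
        assert np.allclose(np.nan_to_num(vals), np.nan_to_num(vals.transpose(0, 2, 1)))

    def test_null_epochs_near_chance(self):
        design = DesignSpec(
            n_identities=8, images_per_identity=2, n_trials_per_condition=15,
            n_channels=10, tmin_ms=0.0, tmax_ms=100.0, tstep_ms=10.0,
        )
        epochs = generate_null_epochs(design, noise_sd=1.0, seed=4)
        cep = component_epochs_from_array(
            epochs.data, tmin=0.0, step=10.0, condition_id=epochs.condition_id
        )
        table = condition_table(design)
        rdms = build_rdm_series(cep, table, DecodingConfig(n_repetitions=5, seed=1))
        grand = rdms.vectors().mean()
        n = rdms.vectors().size
        assert abs(grand - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_injected_gender_signal_separates_between_pairs(self, rng):
        design = DesignSpec(
            n_identities=8, images_per_identity=2, n_trials_per_condition=12,
            n_channels=8, tmin_ms=0.0, tmax_ms=20.0, tstep_ms=10.0,
        )
        table = condition_table(design)
        gender = table.factor("gender")
        signal = np.where(gender == "F", 1.0, -1.0)[:, None] * np.ones(8) * 0.8
        labels = np.repeat(np.arange(16), 12)
        data = rng.standard_normal((len(labels), 8, 3)) + signal[labels][:, :, None]
        cep = component_epochs_from_array(data, tmin=0.0, step=10.0, condition_id=labels)
        rdms = build_rdm_series(cep, table, DecodingConfig(n_repetitions=3, seed=0))
        between = (gender[:, None] != gender[None, :])
        vals = rdms.values[1]
        tri = np.tril_indices(16, k=-1)
        assert vals[tri][between[tri]].mean() > vals[tri][~between[tri]].mean()

    def test_undersampled_condition_reported(self, rng):
        labels = np.r_[np.repeat(np.arange(3), 8), np.repeat(3, 2)]
        cep = self.make_cep(rng, labels=labels)
        design = DesignSpec(n_identities=8, images_per_identity=1)
        table = condition_table(design).subset(np.arange(8) < 4)
        with pytest.raises(ValueError, match=r"\[3\]"):
            build_rdm_series(cep, table, DecodingConfig(n_repetitions=1, seed=0))

    def test_equivalence_with_straightforward_fold_loop(self, rng):
        """Batched SMO path == plain loop over folds with sklearn's SVM."""
        n_cond, k, d, n_tp, S = 5, 11, 7, 3, 5
        labels = np.repeat(np.arange(n_cond), k)
        data = rng.standard_normal((len(labels), d, n_tp)) * 0.7
        data += rng.standard_normal((n_cond, d))[labels][:, :, None] * 0.4
        cep = component_epochs_from_array(data, condition_id=labels)
        design = DesignSpec(n_identities=8, images_per_identity=1)
        table = condition_table(design).subset(np.arange(8) < n_cond)
        seed = 31
        cfg = DecodingConfig(n_repetitions=1, seed=seed)
        rdms = build_rdm_series(cep, table, cfg)

        # oracle: same sub-averaging stream, naive fold loop, sklearn SVM
        groups = _trials_by_condition(cep, table, S)
        P = _pseudotrials(cep.data, groups, S, np.random.default_rng(seed))
        tri_i, tri_j = np.tril_indices(n_cond, k=-1)
        expected = np.full((n_tp, n_cond, n_cond), np.nan)
        for t in range(n_tp):
            for a, b in zip(tri_i, tri_j):
                correct = 0
                for fold in range(S):
                    rows_a = [a * S + s for s in range(S) if s != fold]
                    rows_b = [b * S + s for s in range(S) if s != fold]
                    X = P[t][rows_a + rows_b]
                    y = np.r_[np.ones(S - 1), -np.ones(S - 1)]
                    clf = SVC(kernel="linear", C=1.0, tol=1e-8).fit(X, y)
                    dec_a = clf.decision_function(P[t][[a * S + fold]])[0]
                    dec_b = clf.decision_function(P[t][[b * S + fold]])[0]
                    correct += int(dec_a > 0) + int(dec_b <= 0)
                expected[t, a, b] = expected[t, b, a] = correct / (2.0 * S)
        tri = np.tril_indices(n_cond, k=-1)
        assert np.array_equal(rdms.values[:, tri[0], tri[1]], expected[:, tri[0], tri[1]])

    def test_more_repetitions_reduce_seed_variance(self, rng):
        n_cond, k, d = 3, 10, 5
        labels = np.repeat(np.arange(n_cond), k)
        data = rng.standard_normal((len(labels), d, 1)) * 1.2
        data += rng.standard_normal((n_cond, d))[labels][:, :, None] * 0.35
        cep = component_epochs_from_array(data, condition_id=labels)
        design = DesignSpec(n_identities=8, images_per_identity=1)
        table = condition_table(design).subset(np.arange(8) < n_cond)

        def entry_variance(reps):
            vals = [
                build_rdm_series(
                    cep, table, DecodingConfig(n_repetitions=reps, seed=s)
                ).values[0, 1, 0]
                for s in range(10)
            ]
            return np.var(vals)

        assert entry_variance(4) < entry_variance(1)


class TestImageDecoding:
    def test_constant_rdm(self):
        vals = np.full((2, 4, 4), 0.73)
        from megrsa.core import RDMSeries

        rdms = RDMSeries(vals, np.array([0.0, 5.0]), np.arange(4))
        assert np.allclose(image_decoding_timecourse(rdms), 0.73)

    def test_balanced_checkerboard_averages_to_chance(self):
        vals = np.full((1, 5, 5), np.nan)
        tri = np.tril_indices(5, k=-1)
        entries = np.array([0.4, 0.6] * 5)
        vals[0][tri] = entries
        vals[0][tri[1], tri[0]] = entries
        from megrsa.core import RDMSeries

        rdms = RDMSeries(vals, np.array([0.0, 5.0])[:1], np.arange(5))
        assert image_decoding_timecourse(rdms)[0] == pytest.approx(0.5)


class TestTemporalGeneralization:
    def test_stationary_signal_generalizes_and_prestim_chance(self, rng):
        n_cond, k, d = 4, 10, 6
        labels = np.repeat(np.arange(n_cond), k)
        patterns = rng.standard_normal((n_cond, d)) * 1.5
        n_tp = 8
        times = -40.0 + 10.0 * np.arange(n_tp)   # 4 pre, 4 post
        data = rng.standard_normal((len(labels), d, n_tp))
        data[:, :, times > 0] += patterns[labels][:, :, None]
        cep = component_epochs_from_array(data, tmin=-40.0, step=10.0, condition_id=labels)
        design = DesignSpec(n_identities=8, images_per_identity=1)
        table = condition_table(design).subset(np.arange(8) < n_cond)
        mat, train_t, test_t = temporal_generalization(
            cep, table, DecodingConfig(n_repetitions=2, seed=0), train_stride=2
        )
        post_train = train_t > 0
        post_test = test_t > 0
        assert mat[np.ix_(post_train, post_test)].mean() > 0.9
        assert abs(mat[np.ix_(~post_train, ~post_test)].mean() - 0.5) < 0.1

    def test_orthogonal_windows_give_block_structure(self, rng):
        n_cond, k, d = 4, 10, 8
        labels = np.repeat(np.arange(n_cond), k)
        # patterns confined to disjoint feature subspaces: no generalization
        p1 = np.zeros((n_cond, d))
        p2 = np.zeros((n_cond, d))
        p1[:, : d // 2] = rng.standard_normal((n_cond, d // 2)) * 1.5
        p2[:, d // 2 :] = rng.standard_normal((n_cond, d // 2)) * 1.5
        n_tp = 6
        data = rng.standard_normal((len(labels), d, n_tp))
        data[:, :, :3] += p1[labels][:, :, None]
        data[:, :, 3:] += p2[labels][:, :, None]
        cep = component_epochs_from_array(data, tmin=10.0, step=10.0, condition_id=labels)
        design = DesignSpec(n_identities=8, images_per_identity=1)
        table = condition_table(design).subset(np.arange(8) < n_cond)
        mat, train_t, test_t = temporal_generalization(
            cep, table, DecodingConfig(n_repetitions=2, seed=0), train_stride=1
        )
        within = np.r_[mat[:3, :3].ravel(), mat[3:, 3:].ravel()]
        across = np.r_[mat[:3, 3:].ravel(), mat[3:, :3].ravel()]
        assert within.mean() > 0.9
        assert across.mean() < 0.65


class TestCrossCategoryDecode:
    def build(self, rng, gender_amp=0.0, identity_amp=0.0):
        design = DesignSpec(
            n_identities=8, images_per_identity=2, n_trials_per_condition=12,
            n_channels=10, tmin_ms=0.0, tmax_ms=20.0, tstep_ms=10.0,
        )
        table = condition_table(design)
        gender = table.factor("gender")
        identity = table.factor("identity")
        d = 10
        g_pat = rng.standard_normal(d)
        id_pats = rng.standard_normal((8, d))
        signal = (
            gender_amp * np.where(gender == "F", 1.0, -1.0)[:, None] * g_pat
            + identity_amp * id_pats[identity]
        )
        labels = np.repeat(np.arange(16), 12)
        data = rng.standard_normal((len(labels), d, 3)) + signal[labels][:, :, None]
        cep = component_epochs_from_array(data, tmin=0.0, step=10.0, condition_id=labels)
        return cep, table

    def test_shared_gender_axis_generalizes(self, rng):
        cep, table = self.build(rng, gender_amp=0.9)
        acc, _ = cross_category_decode(
            cep, table, "gender", "identity", DecodingConfig(n_repetitions=2, seed=0)
        )
        assert acc.mean() > 0.8

    def test_identity_specific_patterns_do_not_generalize(self, rng):
        cep, table = self.build(rng, identity_amp=0.9)
        acc, _ = cross_category_decode(
            cep, table, "gender", "identity", DecodingConfig(n_repetitions=2, seed=0)
        )
        assert abs(acc.mean() - 0.5) < 0.12

    def test_null_data_chance(self, rng):
        cep, table = self.build(rng)
        acc, _ = cross_category_decode(
            cep, table, "gender", "identity", DecodingConfig(n_repetitions=2, seed=0)
        )
        assert abs(acc.mean() - 0.5) < 0.12


class TestConfig:
    def test_fold_split_coupling_enforced(self):
        with pytest.raises(ValueError):
            DecodingConfig(n_splits_subaverage=5, n_folds=4)

    @pytest.mark.parametrize("kwargs", [dict(n_repetitions=0), dict(C=0.0)])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DecodingConfig(**kwargs)
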