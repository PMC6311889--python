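import dataclasses
import warnings

import numpy as np
import pytest

from dmnfuse import (
    JointFeatureBuilder,
    JointICA,
    build_joint_features,
    generate_cohort,
    map_cohort,
    project_subjects,
    rank_sources,
    split_joint_source,
)
from dmnfuse.infomax import amari_index, infomax

from conftest import laplace_mixture, small_config


def whiten(X):
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n = X.shape[1]
    return np.sqrt(n) * Vt, np.sqrt(n) * (U / s).T


class TestJointFeatures:
    def test_shape_is_subjects_by_nv(self, small_cohort, small_maps):
        cfg, scans, _ = small_cohort
        feats = build_joint_features(small_maps, small_maps.subjects, small_maps.seed_names)
        v = small_maps.data.shape[2]
        assert feats.X.shape == (len(scans), 4 * v)
        assert feats.seed_order == small_maps.seed_names

    def test_single_seed_degenerate_concatenation(self, small_maps):
        feats = build_joint_features(small_maps, small_maps.subjects, ["PCC"])
        v = small_maps.data.shape[2]
        assert feats.X.shape == (len(small_maps.subjects), v)

    def test_blocks_with_100x_scale_equalize(self, small_maps):
        # force a 100-fold raw scale difference between two seed blocks and
        # check the normalized mean sums-of-squares agree to 1e-9
        maps = dataclasses.replace(small_maps, data=small_maps.data.copy())
        maps.data[:, 1, :] *= 10.0  # x100 in sum-of-squares
        feats = build_joint_features(maps, maps.subjects, maps.seed_names)
        v = maps.data.shape[2]
        blocks = feats.X.reshape(len(maps.subjects), 4, v)
        ss = np.mean(blocks**2, axis=(0, 2))
        assert np.abs(ss - ss[0]).max() < 1e-9

    def test_missing_subject_named_in_error(self, small_maps):
        with pytest.raises(KeyError, match="ghost"):
            build_joint_features(small_maps, ["ghost"], small_maps.seed_names)

    def test_missing_seed_named_in_error(self, small_maps):
        with pytest.raises(KeyError, match="XYZ"):
            build_joint_features(small_maps, small_maps.subjects, ["XYZ"])

    def test_voxel_index_mismatch_rejected(self, small_maps):
        builder = JointFeatureBuilder(seed_subset=small_maps.seed_names).fit(small_maps)
        other = dataclasses.replace(small_maps, voxel_index=small_maps.voxel_index[:, ::-1])
        with pytest.raises(ValueError, match="voxel index"):
            builder.transform(other)


class TestInfomaxRecovery:
    def test_recovers_laplace_sources(self):
        X, A, _ = laplace_mixture(seed=1)
        Z, wh = whiten(X)
        W, converged, _ = infomax(Z, np.random.default_rng(2))
        assert converged
        assert amari_index(W @ wh, A) < 0.05

    def test_agrees_with_reference_infomax(self):
        # independent oracle: MNE's Infomax on the same whitened data should
        # recover the same sources up to permutation and sign
        mne_infomax = pytest.importorskip("mne.preprocessing").infomax
        X, A, _ = laplace_mixture(seed=5)
        Z, wh = whiten(X)
        W_ours, _, _ = infomax(Z, np.random.default_rng(0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W_ref = mne_infomax(Z.T, extended=False, random_state=0)
        assert amari_index(W_ours @ wh, A) < 0.05
        assert amari_index(W_ref @ wh, A) < 0.1
        # cross-check: both unmixings agree up to permutation/scale
        P = np.abs(W_ours @ np.linalg.pinv(W_ref))
        P = P / P.max(axis=1, keepdims=True)
        assert ((P > 0.9).sum(axis=1) == 1).all()


class TestJointICA:
    def test_full_order_reconstruction_is_lossless(self, rng):
        # centering across subjects leaves rank M-1; at that order the
        # decomposition reconstructs the centered data exactly
        X = rng.standard_normal((6, 40))
        ica = JointICA(n_components=5, random_state=0).fit(X)
        Xc = X - X.mean(axis=0)
        rec = ica.mixing_ @ ica.components_
        assert np.linalg.norm(Xc - rec) / np.linalg.norm(Xc) <= 1e-6

    def test_truncated_reconstruction_error_equals_discarded_energy(self, rng):
        X = rng.standard_normal((8, 50))
        k = 4
        ica = JointICA(n_components=k, random_state=0).fit(X)
        Xc = X - X.mean(axis=0)
        resid = np.linalg.norm(Xc - ica.mixing_ @ ica.components_) ** 2
        discarded = (np.linalg.svd(Xc, compute_uv=False)[k:] ** 2).sum()
        assert resid == pytest.approx(discarded, rel=1e-8)

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((6, 30))
        a = JointICA(n_components=4, random_state=7).fit(X)
        b = JointICA(n_components=4, random_state=7).fit(X)
        assert np.array_equal(a.mixing_, b.mixing_)
        assert np.array_equal(a.components_, b.components_)

    def test_sign_and_order_conventions_idempotent(self, rng):
        X = rng.standard_normal((6, 30))
        ica = JointICA(n_components=4, random_state=0).fit(X)
        S, A = ica.components_, ica.mixing_
        signs = np.sign(S[np.arange(4), np.argmax(np.abs(S), axis=1)])
        np.testing.assert_array_equal(signs, 1.0)
        var = A.var(axis=0)
        assert (np.diff(var) <= 1e-12).all()

    def test_k_exceeding_rank_rejected(self, rng):
        X = rng.standard_normal((4, 30))
        with pytest.raises(ValueError, match="exceeds"):
            JointICA(n_components=5, random_state=0).fit(X)
        X_lowrank = np.outer(rng.standard_normal(4), rng.standard_normal(30))
        with pytest.raises(ValueError, match="rank"):
            JointICA(n_components=3, random_state=0).fit(X_lowrank)

    def test_projection_reproduces_training_coefficients(self, rng):
        X = rng.standard_normal((6, 40))
        ica = JointICA(n_components=5, random_state=0).fit(X)
        back = ica.transform(X)
        err = np.linalg.norm(back - ica.mixing_) / np.linalg.norm(ica.mixing_)
        assert err <= 1e-6

    def test_projecting_a_pure_source_isolates_it(self, rng):
        X = rng.standard_normal((6, 40))
        ica = JointICA(n_components=4, random_state=0).fit(X)
        coef = ica.transform(ica.components_[0] + ica.mean_)[0]
        assert abs(coef[0]) > 1e-3
        assert np.abs(coef[1:]).max() < 1e-8 * abs(coef[0])

    def test_zero_feature_projects_to_zero(self, rng):
        X = rng.standard_normal((6, 40))
        ica = JointICA(n_components=4, random_state=0).fit(X)
        coef = ica.transform(ica.mean_)[0]
        np.testing.assert_allclose(coef, 0.0, atol=1e-10)

    def test_project_subjects_consistency_on_maps(self, small_cohort, small_maps):
        builder = JointFeatureBuilder(seed_subset=small_maps.seed_names).fit(small_maps)
        feats = builder.transform(small_maps)
        ica = JointICA(
            n_components=len(small_maps.subjects) - 1, random_state=0
        ).fit(feats.X)
        back = project_subjects(small_maps, ica, builder)
        err = np.linalg.norm(back - ica.mixing_) / np.linalg.norm(ica.mixing_)
        assert err <= 1e-6


class TestSourceRanking:
    def test_equal_group_means_give_zero_t(self):
        A = np.array([[0.0], [1.0], [-1.0], [0.0], [1.0], [-1.0]])
        stats = rank_sources(A, ["g1"] * 3 + ["g2"] * 3)
        assert stats.t_values[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_pooled_t(self):
        A = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        stats = rank_sources(A, ["g1"] * 3 + ["g2"] * 3)
        assert stats.t_values[0] == pytest.approx(-3.6742346, abs=1e-6)

    def test_most_different_maximizes_abs_t_ties_to_lower_index(self):
        col = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        A = np.column_stack([col, col])
        stats = rank_sources(A, ["g1"] * 3 + ["g2"] * 3)
        assert stats.most_different == 0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            rank_sources(np.zeros((3, 2)), ["g1", "g1", "g2"])

    def test_planted_effect_found_as_most_different_source(self):
        cfg = small_config(n_per_group=9, t_len=60, effect_size=3.0, rng_seed=1)
        scans, truth = generate_cohort(cfg)
        maps = map_cohort(scans, cfg.resolved_seeds())
        feats = build_joint_features(maps, maps.subjects, maps.seed_names)
        ica = JointICA(n_components=5, random_state=0).fit(feats.X)
        stats = rank_sources(ica.mixing_, maps.groups)
        # the winning source's per-seed maps should resemble the planted
        # effect-carrying component more than any other planted component
        blocks = np.array_split(ica.components_[stats.most_different], 4)
        sims = [
            max(abs(np.corrcoef(b, comp)[0, 1]) for b in blocks)
            for comp in truth.spatial_components
        ]
        assert int(np.argmax(sims)) == 0  # component 0 carries the effect


class TestSplitJointSource:
    def test_four_seed_split_partitions_the_row(self, small_maps):
        feats = build_joint_features(small_maps, small_maps.subjects, small_maps.seed_names)
        ica = JointICA(n_components=4, random_state=0).fit(feats.X)
        parts = split_joint_source(ica, 2, small_maps.seed_names)
        assert list(parts) == small_maps.seed_names
        np.testing.assert_array_equal(
            np.concatenate([parts[s] for s in small_maps.seed_names]),
            ica.components_[2],
        )

    def test_single_seed_returns_the_row(self, small_maps):
        feats = build_joint_features(small_maps, small_maps.subjects, ["PCC"])
        ica = JointICA(n_components=3, random_state=0).fit(feats.X)
        np.testing.assert_array_equal(
            split_joint_source(ica, 0, ["PCC"])["PCC"], ica.components_[0]
        )

    def test_out_of_range_index_rejected(self, small_maps):
        feats = build_joint_features(small_maps, small_maps.subjects, ["PCC"])
        ica = JointICA(n_components=3, random_state=0).fit(feats.X)
        with pytest.raises(IndexError):
            split_joint_source(ica, 3, ["PCC"])


def test_top_source_stable_across_model_orders():
    """Refitting at nearby K keeps the most-different source's map.

    The effect sits on one compact satellite network; a multi-lobe network
    would legitimately be split into sub-networks at high model order, which
    is a property of spatial ICA, not an instability of the pipeline.
    """
    from dmnfuse import k_sweep

    cfg = small_config(
        n_per_group=18, grid=(14, 16, 14), t_len=130, effect_size=3.0,
        effect_weights={2: 1.0}, rng_seed=1,
    )
    scans, _ = generate_cohort(cfg)
    maps = map_cohort(scans, cfg.resolved_seeds())
    table = k_sweep(maps, maps.seed_names, k_values=(6, 8, 10, 12), k_ref=8, rng_seed=0)
    assert (table["abs_corr_with_reference"] > 0.8).all()
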