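import itertools

import numpy as np
import pandas as pd
import pytest

from neuroplsc.inference import (
    InferenceConfig,
    permutation_test,
    bootstrap_stability,
    threshold_saliences,
    normal_tail_probability,
    significant_components,
)
from neuroplsc.preprocess import prepare_blocks
from neuroplsc.synthetic import generate_two_block, generate_null, make_truth


@pytest.fixture(scope="module")
def strong_blocks():
    """High-SNR planted one-component dataset, prepared."""
    truth = make_truth(p=12, q=8, target_r=0.9, seed=21)
    ds, truth = generate_two_block(n=200, p=12, q=8, truth=truth)
    return prepare_blocks(ds), truth


class TestPermutationTest:
    def test_p_floor_for_overwhelming_signal(self, strong_blocks):
        blocks, _ = strong_blocks
        cfg = InferenceConfig(n_perm=199, seed=0)
        perm = permutation_test(blocks.Xz, blocks.Yz, 1, cfg)
        assert perm.p[0] == pytest.approx(1 / 200)

    def test_matches_exhaustive_enumeration_oracle(self):
        # n=5: run over all 120 row permutations and compare against an
        # independent brute-force p-value computed directly from numpy SVDs
        rng = np.random.default_rng(17)
        n, p, q = 5, 3, 3
        X = rng.normal(size=(n, p))
        Y = rng.normal(size=(n, q))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        Y = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        perms = [np.array(pm) for pm in itertools.permutations(range(n))]

        s_obs = np.linalg.svd(Y.T @ X / (n - 1), compute_uv=False)
        null = np.array([np.linalg.svd(Y[pm].T @ X / (n - 1), compute_uv=False)
                         for pm in perms])
        expected_p = (1 + (null >= s_obs[None, :]).sum(0)) / (len(perms) + 1)

        cfg = InferenceConfig(n_perm=1, perm_alignment="naive", seed=0)
        result = permutation_test(pd.DataFrame(X), pd.DataFrame(Y), 3, cfg,
                                  permutations=perms)
        assert np.array_equal(result.p, expected_p)
        assert np.allclose(result.null_s, null)

    def test_p_values_within_add_one_bounds(self, strong_blocks):
        blocks, _ = strong_blocks
        cfg = InferenceConfig(n_perm=50, seed=3)
        perm = permutation_test(blocks.Xz, blocks.Yz, 4, cfg)
        assert np.all(perm.p >= 1 / 51) and np.all(perm.p <= 1.0)

    def test_reproducible_under_seed(self, strong_blocks):
        blocks, _ = strong_blocks
        cfg = InferenceConfig(n_perm=60, seed=8)
        p1 = permutation_test(blocks.Xz, blocks.Yz, 2, cfg)
        p2 = permutation_test(blocks.Xz, blocks.Yz, 2, cfg)
        assert np.array_equal(p1.null_s, p2.null_s)

    def test_k_too_large_raises(self, strong_blocks):
        blocks, _ = strong_blocks
        with pytest.raises(ValueError, match="exceeds"):
            permutation_test(blocks.Xz, blocks.Yz, 99, InferenceConfig())

    def test_null_rejection_rate_is_conservative_or_calibrated(self):
        # exchangeable null: rejection rate at alpha must not exceed
        # alpha + 3 * Monte-Carlo standard error
        alpha, n_datasets = 0.05, 120
        cfg = InferenceConfig(n_perm=99, seed=0)
        rejections = 0
        for i in range(n_datasets):
            ds = generate_null(n=40, p=5, q=4, seed=1000 + i)
            blocks = prepare_blocks(ds)
            perm = permutation_test(blocks.Xz, blocks.Yz, 1,
                                    InferenceConfig(n_perm=99, seed=i))
            rejections += perm.p[0] < alpha
        se = np.sqrt(alpha * (1 - alpha) / n_datasets)
        assert rejections / n_datasets <= alpha + 3 * se

    def test_power_monotone_in_latent_strength(self):
        # median exceedance margin of the first component never decreases
        # as the planted latent correlation grows
        margins = []
        for target_r in (0.2, 0.5, 0.8):
            reps = []
            for rep in range(10):
                truth = make_truth(p=10, q=8, target_r=target_r, seed=rep)
                ds, _ = generate_two_block(n=120, p=10, q=8, truth=truth,
                                           seed=500 + rep)
                blocks = prepare_blocks(ds)
                perm = permutation_test(blocks.Xz, blocks.Yz, 1,
                                        InferenceConfig(n_perm=60, seed=rep))
                reps.append(perm.observed_s[0] - np.percentile(perm.null_s[:, 0], 95))
            margins.append(np.median(reps))
        assert margins[0] <= margins[1] <= margins[2]


class TestBootstrap:
    def test_reproducible_under_seed(self, strong_blocks):
        blocks, _ = strong_blocks
        cfg = InferenceConfig(n_boot=40, seed=5)
        b1 = bootstrap_stability(blocks.Xz, blocks.Yz, 2, cfg)
        b2 = bootstrap_stability(blocks.Xz, blocks.Yz, 2, cfg)
        pd.testing.assert_frame_equal(b1.behavior, b2.behavior)
        pd.testing.assert_frame_equal(b1.brain, b2.brain)

    def test_noiseless_saliences_have_zero_spread(self):
        truth = make_truth(p=10, q=8, K_true=1, noise_sd=0.0,
                           confound_strength=0.0, support_frac=1.0,
                           n_shifted_columns=0, seed=2)
        ds, truth = generate_two_block(n=60, p=10, q=8, truth=truth)
        blocks = prepare_blocks(ds)
        boot = bootstrap_stability(blocks.Xz, blocks.Yz, 1,
                                   InferenceConfig(n_boot=50, seed=1))
        sds = boot.behavior[("comp1", "sd")].astype(float)
        assert sds.max() < 1e-8
        assert boot.behavior[("comp1", "significant")].all()

    def test_strong_signal_mask_recovers_planted_support(self, strong_blocks):
        blocks, truth = strong_blocks
        boot = bootstrap_stability(blocks.Xz, blocks.Yz, 1,
                                   InferenceConfig(n_boot=200, seed=7))
        support = truth.support("behavior", 0)
        mask = boot.behavior[("comp1", "significant")].to_numpy(dtype=bool)
        # every planted variable detected; false positives rare
        assert mask[support].all()
        assert (~mask[~support]).mean() >= 0.75

    def test_sign_flip_symmetry_of_z(self, strong_blocks):
        blocks, _ = strong_blocks
        cfg = InferenceConfig(n_boot=60, seed=9)
        b1 = bootstrap_stability(blocks.Xz, blocks.Yz, 1, cfg)
        b2 = bootstrap_stability(blocks.Xz, -blocks.Yz, 1, cfg)
        z1 = b1.behavior[("comp1", "z")].astype(float).to_numpy()
        z2 = b2.behavior[("comp1", "z")].astype(float).to_numpy()
        assert np.allclose(np.abs(z1), np.abs(z2), atol=1e-8)

    def test_procrustes_alignment_also_supported(self, strong_blocks):
        blocks, truth = strong_blocks
        boot = bootstrap_stability(
            blocks.Xz, blocks.Yz, 2,
            InferenceConfig(n_boot=60, seed=11, boot_alignment="procrustes"))
        support = truth.support("behavior", 0)
        z = boot.behavior[("comp1", "z")].astype(float).to_numpy()
        assert np.abs(z[support]).min() > 3


class TestThresholding:
    def test_threshold_rules(self):
        cfg = InferenceConfig()
        rng = np.random.default_rng(0)
        ds, _ = generate_two_block(n=40, p=6, q=5,
                                   truth=make_truth(p=6, q=5, seed=0))
        blocks = prepare_blocks(ds)
        boot = bootstrap_stability(blocks.Xz, blocks.Yz, 1,
                                   InferenceConfig(n_boot=30, seed=0))
        masks3 = threshold_saliences(boot, 3.0)
        z = boot.behavior.xs("z", axis=1, level=1).astype(float)
        assert (masks3["behavior"].to_numpy() == (np.abs(z) >= 3.0).to_numpy()).all()
        masks0 = threshold_saliences(boot, 0.0)
        assert masks0["behavior"].to_numpy().all()
        assert masks0["brain"].to_numpy().all()

    @pytest.mark.parametrize("z,expected", [(2.9, False), (-3.1, True), (3.0, True)])
    def test_boundary_cases(self, z, expected):
        assert (abs(z) >= 3.0) is expected  # documents the inclusive cutoff


class TestNormalTail:
    @pytest.mark.parametrize("z,tails,expected,places", [
        (3.0, "one", 0.0013, 4),
        (2.57, "two", 0.01, 2),
        (0.0, "one", 0.5, 10),
        (3.0, "two", 0.0027, 4),
    ])
    def test_printed_values(self, z, tails, expected, places):
        assert round(normal_tail_probability(z, tails), places) == expected

    def test_negative_z_rejected(self):
        with pytest.raises(ValueError):
            normal_tail_probability(-1.0)


def test_significant_components_uses_alpha(strong_blocks):
    blocks, _ = strong_blocks
    perm = permutation_test(blocks.Xz, blocks.Yz, 3,
                            InferenceConfig(n_perm=99, seed=2))
    sig = significant_components(perm, alpha=0.05)
    assert 0 in sig  # the planted component is detected
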