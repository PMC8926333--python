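"""Synthetic data generator: determinism, ground truth, structure."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from fairconn.qc import compute_rsfc, vectorize_rsfc
from fairconn.synthetic import (
    SyntheticConfig,
    assigned_fc_correlation,
    generate_dataset,
    generate_suite,
    generate_timeseries,
    ground_truth_association,
)

QUIET_MOTION = {
    "spike_rate": 0.0, "fd_base": 0.0, "fd_spike": 0.5,
    "dvars_base": 0.0, "dvars_spike": 60.0, "jitter": 0.0,
}


class TestGenerateDataset:
    def test_bit_identical_given_seed(self, tiny_config, tiny_dataset):
        other = generate_dataset(tiny_config)
        assert np.array_equal(tiny_dataset.fc, other.fc)
        assert np.array_equal(tiny_dataset.y, other.y)
        assert np.array_equal(tiny_dataset.families, other.families)

    def test_noiseless_limit_is_exact(self):
        cfg = SyntheticConfig(
            n_majority=30, n_minority=10, n_roi=10, noise_sd=0.0,
            confound_loadings=(), group_mean_shift=0.0, seed=3,
        )
        ds = generate_dataset(cfg)
        truth = ds.truth["behaviors"]["y"]
        for group, w in (
            ("majority", truth["w_majority"]), ("minority", truth["w_minority"])
        ):
            m = ds.groups == group
            assert np.allclose(ds.y[m], ds.fc[m] @ w, atol=1e-12)

    def test_mean_shift_applies_to_minority_only(self):
        base = SyntheticConfig(
            n_majority=30, n_minority=10, n_roi=10, noise_sd=0.0,
            confound_loadings=(), seed=3,
        )
        shifted = generate_dataset(dataclasses.replace(base, group_mean_shift=2.5))
        plain = generate_dataset(base)
        m = plain.groups == "minority"
        assert np.allclose(shifted.y[m] - plain.y[m], 2.5)
        assert np.allclose(shifted.y[~m], plain.y[~m])

    def test_default_noise_gives_signal_correlation_near_root_half(self):
        # auto noise targets population R^2 = 0.5, i.e. corr ~ 0.707
        cfg = SyntheticConfig(
            n_majority=400, n_minority=100, n_roi=40, confound_loadings=(), seed=7
        )
        ds = generate_dataset(cfg)
        m = ds.groups == "majority"
        w = ds.truth["behaviors"]["y"]["w_majority"]
        r = np.corrcoef(ds.y[m], ds.fc[m] @ w)[0, 1]
        assert 0.6 < r < 0.8

    def test_variance_ratio_targeting(self):
        cfg = SyntheticConfig(
            n_majority=20000, n_minority=20000, n_roi=10,
            confound_loadings=(), group_variance_ratio=2.0, seed=5,
        )
        ds = generate_dataset(cfg)
        v_min = ds.y[ds.groups == "minority"].var()
        v_maj = ds.y[ds.groups == "majority"].var()
        assert v_min / v_maj == pytest.approx(2.0, rel=0.1)

    def test_group_counts_and_structure(self, tiny_dataset, tiny_config):
        ds, cfg = tiny_dataset, tiny_config
        assert (ds.groups == "majority").sum() == cfg.n_majority
        assert (ds.groups == "minority").sum() == cfg.n_minority
        assert (ds.groups == "other").sum() == cfg.n_other
        # family blocks never straddle sites
        for fam in np.unique(ds.families):
            assert len(set(ds.sites[ds.families == fam])) == 1

    @pytest.mark.parametrize("rho", [-1.0, -0.3, 0.0, 0.3, 0.8, 1.0])
    def test_weight_correlation_matches_pattern_similarity(self, rho):
        cfg = SyntheticConfig(
            n_majority=4, n_minority=4, n_roi=20, pattern_similarity=rho, seed=1
        )
        ds = generate_dataset(cfg)
        t = ds.truth["behaviors"]["y"]
        got = np.corrcoef(t["w_majority"], t["w_minority"])[0, 1]
        assert got == pytest.approx(rho, abs=1e-6)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(pattern_similarity=1.5).validate()
        with pytest.raises(ValueError):
            SyntheticConfig(noise_sd=-0.1).validate()
        with pytest.raises(ValueError):
            SyntheticConfig(group_variance_ratio=0.0).validate()
        with pytest.raises(ValueError, match="edges"):
            SyntheticConfig(n_roi=10, w_majority=np.ones(5),
                            w_minority=np.ones(5)).validate()

    def test_suite_shares_fc_across_behaviors(self, tiny_config):
        suite = generate_suite(tiny_config, {"a": 0.2, "b": 0.9})
        single = generate_dataset(tiny_config)
        assert np.array_equal(suite.fc, single.fc)
        assert set(suite.behaviors) == {"a", "b"}

    def test_levene_null_calibration(self):
        # equal group variances: rejection rate at alpha=0.05 stays near nominal
        from fairconn.metrics import levene_test

        cfg = SyntheticConfig(
            n_majority=100, n_minority=100, n_roi=8, confound_loadings=()
        )
        rejections = 0
        for rep in range(500):
            ds = generate_dataset(dataclasses.replace(cfg, seed=rep))
            _, p = levene_test(
                ds.y[ds.groups == "minority"], ds.y[ds.groups == "majority"]
            )
            rejections += p < 0.05
        assert rejections / 500 <= 0.07


class TestGroundTruthAssociation:
    def test_identity_covariance_returns_weights(self):
        cfg = SyntheticConfig(
            n_majority=4, n_minority=4, n_roi=10, confound_loadings=(),
            latent_loading_sd=0.0, latent_diag_var=1.0, seed=2,
        )
        ds = generate_dataset(cfg)
        w = ds.truth["behaviors"]["y"]["w_majority"]
        assert np.allclose(ground_truth_association(cfg, "majority"), w, atol=1e-12)

    def test_equal_for_identical_patterns(self):
        cfg = SyntheticConfig(n_majority=4, n_minority=4, n_roi=10,
                              pattern_similarity=1.0, seed=2)
        assert np.allclose(
            ground_truth_association(cfg, "majority"),
            ground_truth_association(cfg, "minority"),
        )

    def test_monte_carlo_oracle(self):
        # empirical edge-score covariance at n = 1e5 approaches Sigma w
        cfg = SyntheticConfig(n_majority=100_000, n_minority=1, n_roi=10, seed=5)
        ds = generate_dataset(cfg)
        m = ds.groups == "majority"
        fc, y = ds.fc[m], ds.y[m]
        emp = (fc - fc.mean(0)).T @ (y - y.mean()) / y.size
        assert np.abs(emp - ground_truth_association(cfg, "majority")).max() < 0.02

    def test_unknown_group_rejected(self, tiny_config):
        with pytest.raises(ValueError, match="unknown group"):
            ground_truth_association(tiny_config, "martian")


class TestGenerateTimeseries:
    def test_no_spikes_means_no_motion(self):
        cfg = SyntheticConfig(
            n_majority=2, n_minority=1, n_roi=6, frames_per_run=20,
            motion_params=QUIET_MOTION, seed=4,
        )
        ds = generate_dataset(cfg)
        runs = generate_timeseries(cfg, ds.subjects[0])
        assert all(r.fd.max() == 0.0 for r in runs)
        assert all(r.dvars.max() == 0.0 for r in runs)

    def test_seeded_determinism(self, tiny_config, tiny_dataset):
        sub = tiny_dataset.subjects[3]
        a = generate_timeseries(tiny_config, sub)
        b = generate_timeseries(tiny_config, sub)
        assert all(
            np.array_equal(x.signal, y.signal) and np.array_equal(x.fd, y.fd)
            for x, y in zip(a, b)
        )

    def test_empirical_fc_converges_to_assigned(self):
        cfg = SyntheticConfig(
            n_majority=2, n_minority=1, n_roi=10, frames_per_run=10_000,
            runs_per_subject=1, motion_params=QUIET_MOTION, seed=9,
        )
        ds = generate_dataset(cfg)
        sub = ds.subjects[0]
        z = compute_rsfc(generate_timeseries(cfg, sub))
        target = assigned_fc_correlation(cfg, sub)
        z_target = np.arctanh(np.clip(target, -1 + 1e-7, 1 - 1e-7))
        np.fill_diagonal(z_target, 0.0)
        err = np.abs(vectorize_rsfc(z) - vectorize_rsfc(z_target)).max()
        assert err < 0.05

    def test_short_runs_rejected(self, tiny_dataset):
        cfg = SyntheticConfig(frames_per_run=5)
        with pytest.raises(ValueError, match="frames_per_run"):
            generate_timeseries(cfg, tiny_dataset.subjects[0])
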