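"""ROI FC matrices, the integration statistic, seed maps, and thresholding."""

import numpy as np
import pytest
from scipy import stats

from insulafc.atlas import RoiSignalSet, build_atlas, default_roi_table, extract_signals
from insulafc.cohort import BOLDRun
from insulafc.connectivity import (
    ROI_ORDER,
    ConnectivityError,
    fisher_z,
    integration_score,
    pairwise_fc,
    seed_map,
    threshold_map,
)
from insulafc.grid import GridSpec


def _signal_set(rng, n_t=100, override=None):
    signals = {rid: rng.standard_normal(n_t) for rid in ROI_ORDER}
    if override:
        signals.update(override)
    return RoiSignalSet(subject_id="s", signals=signals)


class TestPairwiseFc:
    def test_diagonal_is_one_and_symmetric(self, rng):
        fc = pairwise_fc(_signal_set(rng))
        assert np.allclose(np.diag(fc.r), 1.0)
        assert np.array_equal(fc.r, fc.r.T)

    def test_antiphase_pair_is_minus_one(self, rng):
        s = rng.standard_normal(100)
        fc = pairwise_fc(_signal_set(rng, override={("L", 1): s, ("L", 2): -s}))
        i, j = ROI_ORDER.index(("L", 1)), ROI_ORDER.index(("L", 2))
        assert fc.r[i, j] == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self, rng):
        sigset = _signal_set(rng, n_t=60)
        fc = pairwise_fc(sigset)
        for a in range(0, 20, 7):
            for b in range(a + 1, 20, 5):
                x = sigset.signals[ROI_ORDER[a]]
                y = sigset.signals[ROI_ORDER[b]]
                xc, yc = x - x.mean(), y - y.mean()
                expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
                assert fc.r[a, b] == pytest.approx(expected, abs=1e-12)

    def test_fisher_z_on_off_diagonal(self, rng):
        fc = pairwise_fc(_signal_set(rng))
        off = ~np.eye(20, dtype=bool)
        assert np.allclose(fc.z[off], np.arctanh(fc.r[off]))
        assert np.all(np.isnan(np.diag(fc.z)))

    def test_zero_variance_signal_names_roi(self, rng):
        with pytest.raises(ConnectivityError, match=r"\('R', 4\)"):
            pairwise_fc(_signal_set(rng, override={("R", 4): np.zeros(100)}))


class TestFisherZ:
    def test_round_trip_and_monotone(self):
        r = np.linspace(-0.99, 0.99, 199)
        z = fisher_z(r)
        assert np.all(np.diff(z) > 0)
        assert np.allclose(np.tanh(z), r, atol=1e-12)


class TestIntegrationScore:
    def test_posterior_equal_to_anterior_average_gives_one(self, rng):
        sigset = _signal_set(rng)
        ant_avg = np.mean([sigset.signals[("L", i)] for i in (1, 2, 4, 5, 8)], axis=0)
        for i in (3, 7, 10):
            sigset.signals[("L", i)] = ant_avg.copy()
        score = integration_score(sigset, "L")
        assert score.r_value == pytest.approx(1.0)

    def test_independent_noise_gives_small_r(self):
        # null Monte Carlo: with 250 independent time points the integration
        # statistic rarely strays far from zero
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            sigset = _signal_set(rng, n_t=250)
            if abs(integration_score(sigset, "L").r_value) < 0.2:
                hits += 1
        assert hits >= 97

    def test_transitional_rois_excluded(self, rng):
        sigset = _signal_set(rng)
        base = integration_score(sigset, "R").r_value
        sigset.signals[("R", 6)] = sigset.signals[("R", 1)] * 5  # perturb transitional ROIs
        sigset.signals[("R", 9)] = -sigset.signals[("R", 3)]
        assert integration_score(sigset, "R").r_value == pytest.approx(base)

    def test_missing_roi_raises(self, rng):
        sigset = _signal_set(rng)
        del sigset.signals[("L", 7)]
        with pytest.raises(ConnectivityError, match="incomplete"):
            integration_score(sigset, "L")


@pytest.fixture(scope="module")
def seedmap_setup():
    rng = np.random.default_rng(7)
    grid = GridSpec(dims=(8, 8, 8), n_volumes=120)
    data = rng.standard_normal(grid.shape4d)
    conf = rng.standard_normal((120, 15))
    seed_sig = rng.standard_normal(120) + conf[:, 4]
    data[2, 2, 2, :] = seed_sig  # voxel carrying the seed exactly
    # voxel driven by the same confound as the seed, not by the seed itself
    data[5, 5, 5, :] = 2.0 * conf[:, 4] + 0.3 * rng.standard_normal(120)
    run = BOLDRun("s", data, grid)
    return run, seed_sig, conf


class TestSeedMap:
    def test_voxel_equal_to_seed_maps_to_one(self, seedmap_setup):
        run, seed_sig, conf = seedmap_setup
        smap = seed_map(run, seed_sig, conf)
        assert smap.r_map[2, 2, 2] > 0.999
        assert smap.p_map[2, 2, 2] < 1e-12

    def test_confound_driven_voxel_has_no_partial_correlation(self, seedmap_setup):
        run, seed_sig, conf = seedmap_setup
        raw = np.corrcoef(run.data[5, 5, 5], seed_sig)[0, 1]
        assert raw > 0.4  # nuisance induces strong raw correlation
        smap = seed_map(run, seed_sig, conf)
        assert abs(smap.r_map[5, 5, 5]) < 3.0 / np.sqrt(smap.df)

    def test_equals_residualize_then_correlate(self, seedmap_setup):
        # Frisch-Waugh: the GLM partial correlation equals correlating seed
        # and voxel residuals after projecting out confounds + intercept
        run, seed_sig, conf = seedmap_setup
        smap = seed_map(run, seed_sig, conf)
        design = np.column_stack([np.ones(120), conf])
        proj = np.eye(120) - design @ np.linalg.pinv(design)
        seed_res = proj @ seed_sig
        flat = run.data.reshape(-1, 120)
        vox_res = flat @ proj.T
        num = vox_res @ seed_res
        den = np.sqrt((vox_res**2).sum(axis=1) * (seed_res**2).sum())
        expected = (num / den).reshape(run.grid.dims)
        assert np.max(np.abs(smap.r_map - expected)) <= 1e-8

    def test_p_values_from_t_distribution(self, seedmap_setup):
        run, seed_sig, conf = seedmap_setup
        smap = seed_map(run, seed_sig, conf)
        r = smap.r_map[3, 3, 3]
        t = r * np.sqrt(smap.df / (1 - r**2))
        assert smap.p_map[3, 3, 3] == pytest.approx(2 * stats.t.sf(abs(t), smap.df))

    def test_seed_voxels_flagged_and_excluded(self, small_cohort):
        from insulafc.preprocess import preprocess_run

        cfg = small_cohort.config
        atlas = build_atlas(cfg.roi_table, cfg.grid.with_volumes(75))
        clean, conf = preprocess_run(small_cohort.runs[0], small_cohort.confounds[0])
        signals = extract_signals(clean, atlas)
        roi = atlas[0]
        smap = seed_map(clean, signals.signals[roi.roi_id], conf, roi=roi)
        assert smap.seed_mask.sum() == 7
        assert np.all(smap.p_map[smap.seed_mask] == 1.0)


class TestThresholdMap:
    def test_all_p_one_gives_empty_mask(self):
        assert not threshold_map(np.ones((6, 6, 6))).any()

    def test_cluster_extent_is_strictly_greater_than_k(self):
        # 30-voxel blob survives k=20, a disjoint 20-voxel blob does not
        p = np.ones((20, 20, 6))
        p[0:5, 0:6, 0:1] = 1e-6  # 30 voxels
        p[10:14, 10:15, 0:1] = 1e-6  # 20 voxels
        mask = threshold_map(p, alpha=0.05, k=20)
        assert mask[0:5, 0:6, 0].all()
        assert not mask[10:14, 10:15, 0].any()

    def test_extent_operator_configurable(self):
        p = np.ones((20, 20, 6))
        p[10:14, 10:15, 0:1] = 1e-6  # exactly 20 voxels
        assert not threshold_map(p, k=20, extent_op=">").any()
        assert threshold_map(p, k=20, extent_op=">=").sum() == 20

    def test_bh_step_up_worked_example(self):
        # BH on {0.01, 0.02, 0.03, 0.9} at alpha 0.05: largest i with
        # p(i) <= i*alpha/m is i=3, so the first three are rejected
        p = np.ones((4, 1, 1))
        p[:, 0, 0] = [0.01, 0.02, 0.03, 0.9]
        mask = threshold_map(p, alpha=0.05, k=0)
        assert list(mask[:, 0, 0]) == [True, True, True, False]

    def test_connectivity_rule_changes_component_merging(self):
        # two diagonal-touching blobs of 15: one component of 30 under
        # 26-connectivity, two components of 15 under 6-connectivity
        p = np.ones((12, 12, 4))
        p[0:3, 0:5, 0] = 1e-9
        p[3:6, 5:10, 0] = 1e-9
        assert threshold_map(p, k=20, connectivity_rule=26).sum() == 30
        assert threshold_map(p, k=20, connectivity_rule=6).sum() == 0

    def test_monotone_in_alpha_and_k(self, rng):
        p = rng.uniform(0, 1, (10, 10, 10)) ** 3
        base = threshold_map(p, alpha=0.05, k=5)
        assert not (threshold_map(p, alpha=0.01, k=5) & ~base).any()
        assert not (threshold_map(p, alpha=0.05, k=10) & ~base).any()

    def test_bh_matches_exhaustive_step_up_oracle(self):
        # oracle: among all 2^8 candidate rejection sets that are internally
        # consistent with the step-up rule, take the largest; compare with BH
        from itertools import combinations

        for seed in range(25):
            rng = np.random.default_rng(seed)
            p = rng.uniform(0, 1, 8) ** 2
            m, alpha = 8, 0.05
            best: set = set()
            for size in range(m, 0, -1):
                for subset in combinations(range(m), size):
                    if all(p[i] <= size * alpha / m for i in subset):
                        best = set(subset)
                        break
                if best:
                    break
            mask = threshold_map(p.reshape(8, 1, 1), alpha=alpha, k=0)
            assert set(np.flatnonzero(mask[:, 0, 0])) == best

    def test_empty_brain_mask_raises(self):
        with pytest.raises(ValueError, match="mask"):
            threshold_map(np.ones((4, 4, 4)), brain_mask=np.zeros((4, 4, 4), dtype=bool))

    def test_bad_p_values_rejected(self):
        with pytest.raises(ValueError):
            threshold_map(np.full((4, 4, 4), 1.5))
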