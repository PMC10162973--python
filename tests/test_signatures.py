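"""ERP, ERD/S and cluster-based permutation statistics."""

import numpy as np
import pytest

from invdecode.datatypes import ValidationError
from invdecode.reduction import DegenerateInputError
from invdecode.signatures import (cluster_test_time, cluster_test_timefreq,
                                  coi_exclude_mask, compute_erp,
                                  condition_erps, erds_map,
                                  subject_condition_erds)


class TestERP:
    def test_identical_trials(self, rng):
        X = rng.standard_normal((68, 200))
        erp = compute_erp([X.copy() for _ in range(5)])
        assert np.allclose(erp, X)

    def test_trial_and_negation_cancel(self, rng):
        X = rng.standard_normal((68, 200))
        assert np.allclose(compute_erp([X, -X]), 0.0)

    def test_linearity(self, rng):
        X = rng.standard_normal((7, 68, 200))
        assert np.allclose(compute_erp(3.5 * X), 3.5 * compute_erp(X))

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            compute_erp([])

    def test_inverted_erp_larger_and_later(self, tiny_cohort):
        """The synthetic effect construction must show up in the ERPs:
        the inverted extremum is deeper and later at an effect ROI."""
        from invdecode.atlas import roi_index

        erps = condition_erps(tiny_cohort["face"])
        ri = roi_index("lateraloccipital-rh")
        up = erps[0].mean(axis=0)[ri]
        inv = erps[1].mean(axis=0)[ri]
        times = tiny_cohort["face"][0].trials[0].times
        assert inv.min() < up.min()
        assert times[np.argmin(inv)] > times[np.argmin(up)]


class TestERDS:
    def test_stationary_noise_conditions_cancel(self, rng):
        """Per-trial baseline normalization carries a positive small-sample
        bias (the baseline estimate sits in the denominator), identical for
        statistically identical conditions: the condition difference of
        stationary noise is flat even though each map is not."""
        maps = []
        for _ in range(200):
            x = rng.standard_normal(200)
            maps.append(erds_map(x, fs=200.0).power)
        cond_a = np.mean(maps[:100], axis=0)
        cond_b = np.mean(maps[100:], axis=0)
        coi = coi_exclude_mask(np.arange(4.0, 41.0), -0.5 + np.arange(200) / 200.0)
        assert abs((cond_a - cond_b)[~coi].mean()) < 0.05
        # the bias itself is positive post-stimulus and identical across
        # conditions (it cancels in every paired contrast)
        assert cond_a[~coi].mean() > 0

    def test_amplitude_doubling_triples_relative_power(self):
        t = np.arange(200) / 200.0 - 0.5
        sig = np.where(t >= 0, 2.0, 1.0) * np.sin(2 * np.pi * 10 * t)
        m = erds_map(sig, fs=200.0)
        fi = int(np.where(m.freqs == 10)[0][0])
        ti = int(np.argmin(np.abs(m.times - 0.3)))
        assert m.power[fi, ti] == pytest.approx(3.0, abs=0.4)

    def test_baseline_mean_is_zero(self, rng):
        x = rng.standard_normal(200)
        m = erds_map(x, fs=200.0)
        base = m.times < 0
        assert np.abs(m.power[:, base].mean(axis=1)).max() < 1e-9

    def test_degenerate_baseline(self):
        with pytest.raises((DegenerateInputError, ValidationError)):
            erds_map(np.zeros(200), fs=200.0)

    def test_theta_synchronization_in_cohort(self, tiny_cohort):
        """Inverted-minus-upright ERD/S is positive in the theta band
        during the burst window at an effect ROI (power gain 2)."""
        from invdecode.atlas import roi_index

        erds = subject_condition_erds(tiny_cohort["face"],
                                      roi_index("lateraloccipital-rh"))
        freqs = np.arange(4.0, 41.0)
        times = tiny_cohort["face"][0].trials[0].times
        fsel = (freqs >= 4) & (freqs <= 7)
        tsel = (times >= 0.15) & (times <= 0.35)
        diff = (erds[1] - erds[0]).mean(axis=0)
        assert diff[np.ix_(fsel, tsel)].mean() > 0


class TestClusterTime:
    def _effect_data(self, rng, n_subj=12, offset=1.0, lo=40, hi=60):
        base = rng.standard_normal((n_subj, 100)) * 0.3
        cond_b = base + rng.standard_normal((n_subj, 100)) * 0.3
        cond_a = cond_b.copy()
        cond_a[:, lo:hi] += offset
        return cond_a, cond_b

    def test_identical_conditions_no_clusters(self, rng):
        x = rng.standard_normal((8, 100))
        res = cluster_test_time(x, x.copy(), n_perm=500, seed=1)
        assert len(res.significant) == 0
        assert np.abs(res.t_obs).max() == 0.0

    def test_injected_window_recovered(self, rng):
        cond_a, cond_b = self._effect_data(rng)
        res = cluster_test_time(cond_a, cond_b, n_perm=1000, seed=2)
        assert len(res.significant) >= 1
        best = res.significant[int(np.argmax(np.abs(res.significant_masses)))]
        overlap = best[40:60].sum() / 20
        assert overlap >= 0.8

    def test_null_distribution_size(self, rng):
        a, b = self._effect_data(rng, offset=0.0)
        res = cluster_test_time(a, b, n_perm=5000, seed=0)
        assert res.null_distribution.shape == (5000,)

    def test_exchangeability_sign_flip(self, rng):
        cond_a, cond_b = self._effect_data(rng, offset=0.6)
        r1 = cluster_test_time(cond_a, cond_b, n_perm=500, seed=3)
        r2 = cluster_test_time(cond_b, cond_a, n_perm=500, seed=3)
        assert np.allclose(r1.t_obs, -r2.t_obs)
        assert np.allclose(sorted(r1.pvalues), sorted(r2.pvalues))

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValidationError):
            cluster_test_time(rng.standard_normal((4, 100)),
                              rng.standard_normal((4, 100)))

    def test_type_one_error_calibrated(self):
        """Under the null, the fraction of datasets with any significant
        cluster stays near the nominal 5% level."""
        hits = 0
        n_rep = 300
        for rep in range(n_rep):
            r = np.random.default_rng(1000 + rep)
            a = r.standard_normal((12, 100))
            b = r.standard_normal((12, 100))
            res = cluster_test_time(a, b, n_perm=400, seed=rep)
            hits += len(res.significant) > 0
        assert 0.02 <= hits / n_rep <= 0.08


class TestClusterTimeFreq:
    def test_identical_conditions(self, rng):
        x = rng.standard_normal((8, 20, 50))
        res = cluster_test_timefreq(x, x.copy(), n_perm=300, seed=0)
        assert len(res.significant) == 0
        assert np.abs(res.t_obs).max() < 1e-3

    def test_injected_blob_detected(self, rng):
        a = rng.standard_normal((12, 20, 50)) * 0.5
        b = rng.standard_normal((12, 20, 50)) * 0.5
        a[:, 3:8, 10:30] += 1.0
        res = cluster_test_timefreq(a, b, n_perm=500, seed=1)
        assert len(res.significant) >= 1
        blob = np.zeros((20, 50), dtype=bool)
        blob[3:8, 10:30] = True
        best = res.significant[int(np.argmax(np.abs(res.significant_masses)))]
        assert (best & blob).sum() / blob.sum() > 0.5
        assert res.masses[res.pvalues.argmin()] > 0

    def test_exclude_mask_blocks_points(self, rng):
        a = rng.standard_normal((10, 20, 50))
        b = rng.standard_normal((10, 20, 50))
        a[:, :2, :] += 5.0  # huge effect confined to excluded rows
        excl = np.zeros((20, 50), dtype=bool)
        excl[:2, :] = True
        res = cluster_test_timefreq(a, b, n_perm=300, seed=2, exclude=excl)
        for c in res.clusters:
            assert not (c & excl).any()


def test_coi_mask_wider_at_low_frequencies():
    freqs = np.arange(4.0, 41.0)
    times = -0.5 + np.arange(200) / 200.0
    m = coi_exclude_mask(freqs, times)
    assert m[0].sum() > m[-1].sum()
    assert not m[:, 90:110].any()  # epoch centre unaffected
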