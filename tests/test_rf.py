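import numpy as np
import pytest

from icresponse.cohort import (
    GroupEffectConfig,
    SiteParams,
    expected_tone_count,
    rate_profile,
    simulate_trials,
)
from icresponse.core import RecordingSite, TrialSpikes
from icresponse.metrics import compute_psth
from icresponse.rf import (
    FrequencyResponseArea,
    build_fra,
    extract_rf,
    latency_metrics,
    tonotopy_summary,
)
from icresponse.stimuli import ToneStimulus, build_tone_grid, tone_id


def make_site(**over):
    base = dict(
        cf=10600.0, threshold=35.0, bw10=1.0, bw40=2.0, onset_latency=8.2,
        peak_latency=13.4, end_of_peak=27.1, spontaneous_rate=0.0,
        depth=3000.0, peak_driven_rate=1400.0,
    )
    base.update(over)
    return SiteParams(**base)


def expected_fra(grid, site, effects=None):
    """Noiseless FRA: the generator's expected counts per grid cell."""
    effects = effects or GroupEffectConfig(group="saline")
    counts = np.zeros(grid.shape)
    for fi, f in enumerate(grid.frequencies):
        for ii, inten in enumerate(grid.intensities):
            counts[fi, ii] = expected_tone_count(
                ToneStimulus(f, inten), site, effects
            )
    return FrequencyResponseArea(counts, grid)


@pytest.fixture(scope="module")
def small_grid():
    return build_tone_grid(1000.0, 4000.0, 0.25, 0.0, 75.0, 5.0)  # 9 x 16


class TestBuildFRA:
    def _site_with_counts(self, grid, times):
        responses = {
            tone_id(k): [TrialSpikes(np.asarray(times, dtype=float),
                                     stimulus_id=tone_id(k))]
            for k in range(grid.n_stimuli)
        }
        return RecordingSite("s0", "saline", "a0", 2000.0, responses)

    def test_silent_site_gives_zero_matrix(self, small_grid):
        fra = build_fra(self._site_with_counts(small_grid, []), small_grid)
        assert fra.counts.shape == small_grid.shape
        assert np.all(fra.counts == 0)

    def test_one_spike_per_tone_gives_ones(self, small_grid):
        fra = build_fra(self._site_with_counts(small_grid, [10.0]), small_grid)
        assert np.all(fra.counts == 1)

    def test_missing_tones_reported(self, small_grid):
        site = self._site_with_counts(small_grid, [10.0])
        del site.responses[tone_id(3)]
        with pytest.raises(ValueError, match="missing 1 grid tones"):
            build_fra(site, small_grid)

    def test_noiseless_nonzero_cells_match_tuning_mask(self, grid):
        site = make_site()
        fra = expected_fra(grid, site)
        from icresponse.cohort import tuning_amplitude
        mask = np.array(
            [[tuning_amplitude(f, i, site) > 0 for i in grid.intensities]
             for f in grid.frequencies]
        )
        assert np.array_equal(fra.counts > 0, mask)


class TestExtractRF:
    def test_noiseless_v_shape_recovered(self, grid):
        site = make_site()
        rec = extract_rf(expected_fra(grid, site), 0.0)
        assert rec.responsive
        assert abs(rec.threshold - site.threshold) <= 5.0
        assert abs(np.log2(rec.cf / site.cf)) <= 0.0625
        assert abs(rec.bw10 - site.bw10) <= 0.0625 + 1e-9
        assert abs(rec.bw40 - site.bw40) <= 0.0625 + 1e-9

    def test_noiseless_recovery_sweep(self, grid):
        """Recovery is exact up to grid quantization over a (cf, threshold) sweep.

        CFs are kept at least one octave (half the bw40 band) inside the grid
        edges so the measured band is not truncated by the grid itself.
        """
        for cf in (2000.0, 4500.0, 9000.0, 12000.0, 16000.0):
            for threshold in (5.0, 15.0, 25.0, 30.0, 35.0):
                site = make_site(cf=cf, threshold=threshold)
                rec = extract_rf(expected_fra(grid, site), 0.0)
                assert rec.responsive
                assert rec.threshold == pytest.approx(threshold)
                assert abs(np.log2(rec.cf / cf)) <= 0.0625 + 1e-9
                assert abs(rec.bw10 - site.bw10) <= 0.0625 + 1e-9
                assert abs(rec.bw40 - site.bw40) <= 0.0625 + 1e-9

    def test_zero_matrix_unresponsive(self, grid):
        rec = extract_rf(FrequencyResponseArea(np.zeros(grid.shape), grid), 0.0)
        assert not rec.responsive
        assert np.isnan(rec.threshold) and np.isnan(rec.cf)

    def test_threshold_near_grid_top_leaves_bw40_undefined(self, grid):
        site = make_site(threshold=70.0)
        rec = extract_rf(expected_fra(grid, site), 0.0)
        assert rec.responsive
        assert rec.threshold == pytest.approx(70.0)
        assert np.isnan(rec.bw40)

    def test_raising_criterion_never_lowers_threshold(self, grid):
        rng = np.random.default_rng(5)
        site = make_site(spontaneous_rate=30.0)
        base = expected_fra(grid, site).counts
        noisy = rng.poisson(base + 30.0 * 0.032)
        fra = FrequencyResponseArea(noisy, grid)
        thresholds = []
        for crit in (2.0, 3.0, 4.0, 6.0, 9.0):
            rec = extract_rf(fra, 30.0, criterion=crit)
            thresholds.append(rec.threshold if rec.responsive else np.inf)
        assert all(a <= b + 1e-9 for a, b in zip(thresholds, thresholds[1:]))


class TestLatencyMetrics:
    def test_two_bin_mass_onset(self):
        counts = np.zeros(40)
        counts[8] = 10
        counts[9] = 12
        psth = compute_psth(
            [TrialSpikes(np.sort(np.concatenate(
                [np.full(10, 8.5), np.full(12, 9.5)])))],
            bin=1.0, window=(0, 40),
        )
        onset, peak, end = latency_metrics(psth, 0.0)
        assert onset == pytest.approx(8.0)
        assert peak == pytest.approx(9.5)
        assert end == pytest.approx(10.0)

    def test_synthetic_transient_recovered_within_one_bin(self):
        site = make_site(spontaneous_rate=25.0)
        eff = GroupEffectConfig(group="saline")
        tone = ToneStimulus(site.cf, site.threshold + 40)
        trials = simulate_trials(rate_profile(tone, site, eff), 50.0, 500,
                                 rng_seed=2)
        psth = compute_psth(trials, bin=1.0, window=(0, 50))
        onset, peak, end = latency_metrics(psth, site.spontaneous_rate)
        assert abs(onset - site.onset_latency) <= 1.0
        assert abs(peak - site.peak_latency) <= 1.0
        assert onset <= peak <= end

    def test_flat_psth_undefined(self):
        rng = np.random.default_rng(0)
        trials = [TrialSpikes(np.sort(rng.uniform(0, 40, 2))) for _ in range(50)]
        psth = compute_psth(trials, bin=1.0, window=(0, 40))
        onset, peak, end = latency_metrics(psth, 50.0)
        assert np.isnan(onset) and np.isnan(peak) and np.isnan(end)

    def test_ordering_whenever_defined(self):
        eff = GroupEffectConfig(group="saline")
        for seed in range(6):
            site = make_site(spontaneous_rate=10.0 + 5 * seed)
            tone = ToneStimulus(site.cf, 75.0)
            trials = simulate_trials(rate_profile(tone, site, eff), 50.0, 200,
                                     rng_seed=seed)
            psth = compute_psth(trials, bin=1.0, window=(0, 50))
            onset, peak, end = latency_metrics(psth, site.spontaneous_rate)
            if not np.isnan(end):
                assert onset <= peak <= end


class TestTonotopy:
    def test_monotone_map_gives_perfect_correlation(self):
        depths = np.linspace(1000, 5000, 60)
        cfs = 1000 * 2 ** (depths / 1000.0)
        rho, pcts = tonotopy_summary(cfs, depths)
        assert rho == pytest.approx(1.0)
        assert pcts.sum() == pytest.approx(100.0)

    def test_log_uniform_cfs_fill_bins_evenly(self):
        rng = np.random.default_rng(3)
        cfs = 1000 * 2 ** rng.uniform(0, 5, 20000)
        _, pcts = tonotopy_summary(cfs, rng.uniform(1000, 5000, cfs.size))
        assert np.all(np.abs(pcts - 20.0) < 1.5)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(9)
        cfs = 1000 * 2 ** rng.uniform(0, 5, 37)
        _, pcts = tonotopy_summary(cfs, rng.uniform(1000, 5000, 37))
        assert pcts.sum() == pytest.approx(100.0)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            tonotopy_summary([2000.0, 4000.0], [1500.0, 2500.0])
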