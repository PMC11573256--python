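import numpy as np
import pytest

import icresponse as ic
from icresponse.cohort import (
    GroupEffectConfig,
    SiteParams,
    RateProfile,
    default_group_effects,
    generate_cohort,
    rate_profile,
    simulate_trials,
    speech_consonant_share,
)
from icresponse.metrics import spontaneous_rate_estimate
from icresponse.report import site_speech_rate
from icresponse.rf import tonotopy_summary
from icresponse.stimuli import SILENCE_ID, speech_catalog


def make_site(**over):
    base = dict(
        cf=8000.0, threshold=20.0, bw10=1.0, bw40=2.0, onset_latency=8.0,
        peak_latency=13.0, end_of_peak=27.0, spontaneous_rate=25.0,
        depth=2500.0, peak_driven_rate=1000.0,
    )
    base.update(over)
    return SiteParams(**base)


class TestRateProfile:
    def test_tone_outside_tuning_extent_is_spontaneous_only(self):
        site = make_site()
        eff = GroupEffectConfig(group="saline")
        tone = ic.ToneStimulus(frequency=site.cf * 8, intensity=site.threshold + 10)
        prof = rate_profile(tone, site, eff)
        t = np.linspace(0, 50, 500)
        assert np.allclose(prof(t), site.spontaneous_rate)

    def test_tone_at_cf_well_above_threshold_peaks_at_site_rate(self):
        site = make_site()
        eff = GroupEffectConfig(group="saline")
        tone = ic.ToneStimulus(frequency=site.cf, intensity=site.threshold + 40)
        prof = rate_profile(tone, site, eff)
        t = np.linspace(0, 50, 20001)
        driven_max = prof(t).max() - site.spontaneous_rate
        assert driven_max == pytest.approx(site.peak_driven_rate, rel=1e-4)

    def test_zero_gains_reduce_every_stimulus_to_spontaneous(self, train):
        site = make_site()
        eff = GroupEffectConfig(
            group="saline", speech_gain=0, tone_gain=0, burst_gain=0
        )
        t = np.linspace(0, 600, 2000)
        for stim in (
            ic.ToneStimulus(site.cf, 60.0),
            speech_catalog()[1],
            train,
            None,
        ):
            assert np.allclose(rate_profile(stim, site, eff)(t),
                               site.spontaneous_rate)

    def test_unknown_stimulus_type_rejected(self):
        with pytest.raises(TypeError):
            rate_profile("dad", make_site(), GroupEffectConfig(group="vpa"))

    def test_max_rate_bounds_profile(self, train):
        site = make_site()
        eff = GroupEffectConfig(group="vpa_vns_tone", burst_gain=1.3)
        prof = rate_profile(train, site, eff)
        t = np.linspace(0, 600, 50000)
        assert prof.max_rate >= prof(t).max() - 1e-9


class TestSimulateTrials:
    def test_constant_rate_mean_count(self):
        # constant 50 Hz over 400 ms: mean count 20, SE = sqrt(20/1000)
        trials = simulate_trials(lambda t: np.full_like(t, 50.0), 400.0, 1000,
                                 rng_seed=3)
        counts = [tr.n_spikes for tr in trials]
        assert abs(np.mean(counts) - 20.0) < 3 * np.sqrt(20.0 / 1000)

    def test_profile_and_generic_paths_agree_in_mean(self):
        site = make_site()
        eff = GroupEffectConfig(group="saline")
        prof = rate_profile(speech_catalog()[1], site, eff)
        a = simulate_trials(prof, 400.0, 400, rng_seed=5)
        b = simulate_trials(lambda t: prof(t), 400.0, 400, rng_seed=6)
        ma = np.mean([tr.n_spikes for tr in a])
        mb = np.mean([tr.n_spikes for tr in b])
        se = np.sqrt(ma / 400) * np.sqrt(2)
        assert abs(ma - mb) < 4 * se

    def test_zero_rate_gives_empty_trials(self):
        trials = simulate_trials(RateProfile(0.0), 400.0, 50, rng_seed=0)
        assert all(tr.n_spikes == 0 for tr in trials)

    def test_same_seed_reproduces_spike_times(self):
        prof = rate_profile(speech_catalog()[0], make_site(),
                            GroupEffectConfig(group="saline"))
        a = simulate_trials(prof, 400.0, 20, rng_seed=11)
        b = simulate_trials(prof, 400.0, 20, rng_seed=11)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.spike_times, tb.spike_times)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            simulate_trials(lambda t: np.sin(t) * 10, 400.0, 5, rng_seed=0)

    def test_spike_times_sorted_within_duration(self):
        prof = rate_profile(speech_catalog()[1], make_site(),
                            GroupEffectConfig(group="saline"))
        for tr in simulate_trials(prof, 400.0, 50, rng_seed=2):
            assert np.all(np.diff(tr.spike_times) >= 0)
            assert np.all((tr.spike_times >= 0) & (tr.spike_times <= 400))


class TestGenerateCohort:
    def test_default_site_counts_match_recorded_cohort(self):
        effects = default_group_effects()
        cohort = generate_cohort(effects, seed=0, silence_repeats=0)
        assert len(cohort.sites) == 453 + 374 + 183 + 146
        assert cohort.group_counts() == {
            "saline": 453, "vpa": 374, "vpa_vns_speech": 183, "vpa_vns_tone": 146,
        }

    def test_missing_group_rejected(self):
        effects = default_group_effects()
        del effects["vpa"]
        with pytest.raises(ValueError, match="vpa"):
            generate_cohort(effects, seed=0)

    def test_regeneration_is_bit_identical(self, train):
        effects = default_group_effects(n_sites=2)
        speech = speech_catalog()[:3]
        a = generate_cohort(effects, speech=speech, train=train, seed=9)
        b = generate_cohort(effects, speech=speech, train=train, seed=9)
        for sa, sb in zip(a.sites, b.sites):
            assert sa.site_id == sb.site_id
            assert sa.params == sb.params
            for sid in sa.responses:
                for ta, tb in zip(sa.responses[sid], sb.responses[sid]):
                    assert np.array_equal(ta.spike_times, tb.spike_times)

    def test_speech_gain_ratio_recovered_by_driven_rate_pipeline(self):
        """A configured 0.7 VPA/saline speech-gain ratio is recovered within 3 SE."""
        effects = default_group_effects(n_sites=150)
        cohort = generate_cohort(
            effects, speech=speech_catalog(), seed=21, groups=["saline", "vpa"]
        )
        rates = {}
        for g in ("saline", "vpa"):
            vals = []
            for s in cohort.sites_by_group(g):
                spont = spontaneous_rate_estimate(
                    s.responses[SILENCE_ID], (0, 400))
                vals.append(site_speech_rate(s, cohort, (0, 400), spont))
            rates[g] = (np.mean(vals), np.std(vals, ddof=1) / np.sqrt(len(vals)))
        ratio = rates["vpa"][0] / rates["saline"][0]
        se_ratio = ratio * np.hypot(
            rates["vpa"][1] / rates["vpa"][0],
            rates["saline"][1] / rates["saline"][0],
        )
        expected = effects["vpa"].speech_gain / effects["saline"].speech_gain
        assert expected == pytest.approx(0.70)
        assert abs(ratio - expected) < 3 * se_ratio

    def test_tonotopy_by_construction(self):
        effects = default_group_effects(n_sites=150)
        cohort = generate_cohort(effects, seed=4, groups=["saline"],
                                 silence_repeats=0)
        cfs = [s.params.cf for s in cohort.sites]
        depths = [s.depth_um for s in cohort.sites]
        rho, _ = tonotopy_summary(cfs, depths)
        assert rho >= 0.9

    def test_vns_speech_defaults_balance_whole_window_contrast(self):
        """Consonant down, vowel up, whole-window factor exactly 0.95 x VPA."""
        effects = default_group_effects()
        w = speech_consonant_share()
        vns, vpa = effects["vpa_vns_speech"], effects["vpa"]
        assert vns.consonant_gain < 1 < vns.vowel_gain
        whole = w * vns.consonant_gain + (1 - w) * vns.vowel_gain
        assert whole == pytest.approx(1.0)
        assert vns.speech_gain / vpa.speech_gain == pytest.approx(0.95)

    def test_site_params_invariants_enforced(self):
        with pytest.raises(ValueError):
            make_site(bw40=0.5)
        with pytest.raises(ValueError):
            make_site(peak_latency=7.0)
        with pytest.raises(ValueError):
            make_site(spontaneous_rate=-1.0)
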