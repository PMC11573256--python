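import numpy as np
import pytest

from icresponse.classify import (
    bin_trials,
    consonant_discrimination,
    consonant_scheme,
    nn_classify_pair,
    vowel_discrimination,
    vowel_scheme,
    BinningScheme,
)
from icresponse.cohort import (
    GroupEffectConfig,
    RateProfile,
    _draw_site_params,
    rate_profile,
    simulate_trials,
)
from icresponse.core import TrialSpikes
from icresponse.stimuli import speech_catalog, speech_id


def trial(times, rep=0):
    return TrialSpikes(np.sort(np.asarray(times, dtype=float)), repeat_index=rep)


def oracle_nn_pair(trials_a, trials_b, scheme):
    """Independent fold-by-fold evaluation (expected accuracy, ties = 0.5).

    Pure-Python re-implementation: templates recomputed from scratch for each
    held-out trial, distances by explicit summation.
    """
    def vec(tr):
        w0, w1 = scheme.window
        v = [0.0] * scheme.n_bins
        for t in tr.spike_times:
            if w0 <= t < w1:
                v[min(int((t - w0) // scheme.bin), scheme.n_bins - 1)] += 1
        return v

    def mean_vec(vecs):
        n = len(vecs)
        return [sum(col) / n for col in zip(*vecs)]

    def dist(u, v):
        return sum((a - b) ** 2 for a, b in zip(u, v)) ** 0.5

    va = [vec(t) for t in trials_a]
    vb = [vec(t) for t in trials_b]
    correct = 0.0
    for own, other in ((va, vb), (vb, va)):
        other_template = mean_vec(other)
        for i, x in enumerate(own):
            rest = [v for j, v in enumerate(own) if j != i]
            d_own = dist(x, mean_vec(rest))
            d_other = dist(x, other_template)
            if np.isclose(d_own, d_other, rtol=1e-9, atol=1e-12):
                correct += 0.5
            elif d_own < d_other:
                correct += 1.0
    return 100.0 * correct / (len(va) + len(vb))


class TestNNClassifyPair:
    def test_identical_trials_score_chance_under_tie_randomization(self):
        trials = [trial([5.0, 12.0, 30.0], rep=i) for i in range(20)]
        res = nn_classify_pair(trials, list(trials), consonant_scheme(),
                               tie_mode="expected")
        assert res.accuracy == pytest.approx(50.0)
        assert res.n_decisions == 40
        assert res.n_ties == 40

    def test_disjoint_responses_are_perfectly_separated(self):
        a = [trial(np.linspace(1, 39, 10), rep=i) for i in range(20)]
        b = [trial([], rep=i) for i in range(20)]
        res = nn_classify_pair(a, b, consonant_scheme())
        assert res.accuracy == 100.0

    def test_matches_oracle_on_randomized_small_instances(self):
        """Exhaustive fold enumeration oracle, 200 random instances <= 5 trials."""
        rng = np.random.default_rng(99)
        for case in range(200):
            scheme = consonant_scheme() if case % 2 else vowel_scheme()
            na, nb = rng.integers(2, 6, size=2)
            rate_a, rate_b = rng.uniform(1, 25, size=2)
            a = [trial(rng.uniform(0, 340, rng.poisson(rate_a)), rep=i)
                 for i in range(na)]
            b = [trial(rng.uniform(0, 340, rng.poisson(rate_b)), rep=i)
                 for i in range(nb)]
            res = nn_classify_pair(a, b, scheme, tie_mode="expected")
            assert res.accuracy == pytest.approx(oracle_nn_pair(a, b, scheme))

    def test_label_symmetry(self):
        rng = np.random.default_rng(3)
        a = [trial(rng.uniform(0, 40, 8), rep=i) for i in range(10)]
        b = [trial(rng.uniform(0, 40, 4), rep=i) for i in range(10)]
        r_ab = nn_classify_pair(a, b, consonant_scheme(), tie_mode="expected")
        r_ba = nn_classify_pair(b, a, consonant_scheme(), tie_mode="expected")
        assert r_ab.accuracy == pytest.approx(r_ba.accuracy)

    def test_chance_convergence_over_sites(self):
        """Both sounds drawn from one distribution: 50% within 3 SE over 200 sites."""
        eff = GroupEffectConfig(group="saline")
        token = speech_catalog()[1]
        accs = []
        for i in range(200):
            params = _draw_site_params(eff, np.random.default_rng([40, i]))
            prof = rate_profile(token, params, eff)
            a = simulate_trials(prof, 400.0, 20, np.random.default_rng([41, i]))
            b = simulate_trials(prof, 400.0, 20, np.random.default_rng([42, i]))
            accs.append(
                nn_classify_pair(a, b, consonant_scheme(), tie_seed=i).accuracy
            )
        accs = np.asarray(accs)
        se = accs.std(ddof=1) / np.sqrt(accs.size)
        assert abs(accs.mean() - 50.0) < 3 * se

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            nn_classify_pair([trial([1.0])], [trial([2.0])] * 3,
                             consonant_scheme())

    def test_unexpected_repeat_count_warns(self):
        a = [trial([1.0, 2.0], rep=i) for i in range(5)]
        with pytest.warns(UserWarning, match="differ"):
            nn_classify_pair(a, a, consonant_scheme(), expected_repeats=20)

    def test_scheme_invariants(self):
        with pytest.raises(ValueError):
            BinningScheme(mode="consonant", window=(0.0, 50.0), bin=1.0)
        with pytest.raises(ValueError):
            BinningScheme(mode="vowel", window=(40.0, 340.0), bin=10.0)
        assert consonant_scheme().n_bins == 40
        assert vowel_scheme().n_bins == 1


class TestPairSets:
    def _site_responses(self, seed=0, gains=None):
        eff = GroupEffectConfig(group="saline")
        params = _draw_site_params(eff, np.random.default_rng([50, seed]))
        responses = {}
        for k, token in enumerate(speech_catalog()):
            cfg = eff if gains is None else gains
            prof = rate_profile(token, params, cfg)
            responses[speech_id(token.label)] = simulate_trials(
                prof, 400.0, 20, np.random.default_rng([51, seed, k])
            )
        return responses

    def test_consonant_pair_count_is_36(self):
        summary = consonant_discrimination(self._site_responses(), tie_seed=0)
        assert len(summary.results) == 36
        assert all(r.n_decisions == 40 for r in summary.results)

    def test_vowel_pair_count_is_3(self):
        summary = vowel_discrimination(self._site_responses(), tie_seed=0)
        assert len(summary.results) == 3

    def test_missing_token_named(self):
        responses = self._site_responses()
        del responses[speech_id("shad")]
        with pytest.raises(KeyError, match="shad"):
            consonant_discrimination(responses)

    def test_identical_token_profiles_score_chance(self):
        """All tokens simulated from one rate profile: mean accuracy ~ 50%."""
        eff = GroupEffectConfig(group="saline")
        token = speech_catalog()[1]
        accs = []
        for seed in range(30):
            params = _draw_site_params(eff, np.random.default_rng([60, seed]))
            prof = rate_profile(token, params, eff)
            responses = {
                speech_id(t.label): simulate_trials(
                    prof, 400.0, 20, np.random.default_rng([61, seed, k])
                )
                for k, t in enumerate(speech_catalog())
            }
            accs.append(
                consonant_discrimination(
                    responses, tie_seed=seed, tie_mode="expected"
                ).mean_accuracy
            )
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 50.0) < max(3 * se, 1.0)

    def test_accuracy_nondecreasing_with_consonant_separation(self):
        """Scaling the between-token consonant contrast never hurts accuracy."""
        means = []
        for strength in (0.0, 0.5, 1.0):
            accs = []
            for seed in range(25):
                eff = GroupEffectConfig(group="saline")
                params = _draw_site_params(eff, np.random.default_rng([70, seed]))
                base = rate_profile(speech_catalog()[1], params, eff)
                responses = {}
                for k, token in enumerate(speech_catalog()):
                    # amplify the token's deviation from the mean profile
                    factor = 1.0 + strength * (k - 5) / 5.0
                    prof = RateProfile(
                        base.spontaneous,
                        [(amp * factor, o, p, e)
                         for amp, o, p, e in base.transients],
                        base.plateaus,
                    )
                    responses[speech_id(token.label)] = simulate_trials(
                        prof, 400.0, 20, np.random.default_rng([71, seed, k])
                    )
                accs.append(
                    consonant_discrimination(
                        responses, tie_seed=seed, tie_mode="expected"
                    ).mean_accuracy
                )
            means.append(np.mean(accs))
        assert means[0] <= means[1] + 0.5
        assert means[1] <= means[2] + 0.5
        assert means[2] > means[0] + 5.0

    def test_one_dimensional_vowel_separation_pattern(self):
        """Vowel counts 20 vs 5 vs 20: outer pairs separate, equal pair at chance."""
        rng = np.random.default_rng(8)

        def make(mean, n=20):
            return [trial(rng.uniform(40, 340, rng.poisson(mean)), rep=i)
                    for i in range(n)]

        responses = {
            "dad": make(20.0), "deed": make(5.0), "dood": make(20.0),
        }
        summary = vowel_discrimination(responses, tie_mode="expected")
        acc = {tuple(sorted(r.pair)): r.accuracy for r in summary.results}
        assert acc[("dad", "deed")] > 90.0
        assert acc[("deed", "dood")] > 90.0
        assert abs(acc[("dad", "dood")] - 50.0) < 20.0
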