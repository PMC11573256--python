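# Methods

This note documents the models and procedures implemented in `icresponse`:
what each analysis stage computes, what the synthetic cohort generator
emulates (and what it deliberately does not), and the numerical choices made
where the design was genuinely open.

## Analysis stages

### Driven firing rates

The driven rate over a window `[t0, t1)` is the mean in-window spike count
per repeat divided by the window duration, minus the site's spontaneous rate.
Spontaneous rates are estimated from stimulus-free sweeps recorded alongside
the stimuli (the synthetic generator emits 20 silent 400-ms sweeps per site
for this purpose). Negative driven rates (suppression) are reported as-is.
Speech responses use three windows: the whole token (0–400 ms), the consonant
(0–40 ms), and the vowel (40–340 ms). Windows are half-open so consonant and
vowel counts add exactly to the 0–340 ms count. Tone response strength is the
mean spike count per tone presentation in the half-open interval (0, 32] ms
after tone onset, averaged over all grid tones (an RF-restricted variant is
available by passing a tone subset); a spike logged exactly at onset cannot
be stimulus-driven and is excluded.

### Frequency response areas and receptive fields

The FRA is the spike-count matrix over the 81 × 16 tone grid in the tone
window. Extraction proceeds as follows, with every constant exposed as an
argument:

1. Smooth the count matrix with a 3×3 median filter (nearest-edge padding).
2. Response criterion = expected spontaneous count in the tone window +
   `max(1, 2·sqrt(spontaneous count), 0.2·(smoothed max − spontaneous count))`.
   The `2·sqrt` term scales the floor with the Poisson SD of the spontaneous
   count; without it, sites with high spontaneous rates produce false
   supra-criterion runs below threshold and group-mean thresholds read low.
3. Threshold = lowest intensity whose smoothed row contains a run of at least
   two adjacent supra-criterion frequencies. CF = geometric-mean frequency of
   the strongest qualifying run at threshold.
4. BW10/BW40 = octave extent of the supra-criterion run at threshold + 10/40
   dB, measured on a *frequency-only* median-smoothed matrix. Smoothing
   across intensity rows erodes the band edges by roughly two grid steps (the
   row below threshold is silent), so the bandwidth read-out deliberately
   smooths only along frequency, which preserves band edges exactly in the
   noiseless limit. Bands extending past the grid's intensity ceiling are
   marked undefined (NaN).
5. A site with no qualifying row is unresponsive — a value, not an error.

Latencies come from the pooled 1-ms PSTH (across all grid-tone
presentations): onset is the left edge of the first of ≥ 2 consecutive bins
exceeding the expected spontaneous count + 2 SD (Poisson SD unless a
pre-stimulus sample is supplied), the peak is the center of the maximum bin
of that first excursion, and end-of-peak is the left edge of the first bin
after the peak at or below criterion. Criterion-crossing end-of-peak
estimates sit systematically earlier than the true return-to-baseline time
of a smooth transient (the tail crosses the criterion before it reaches
zero); onset and peak are recovered within one bin at realistic rates. A
per-trial median first-spike latency is also provided; for one-presentation
grid tones the pooled PSTH estimator is primary because single-trial first
spikes are dominated by spontaneous activity.

### Nearest-neighbor speech discrimination

For each sound pair, every single-trial response is held out in turn and
assigned to the nearer of two PSTH templates by Euclidean distance on binned
spike-count vectors: the held-out sound's template is the mean of its
remaining repeats (19 of 20), and the competing sound's template is the mean
of all its repeats. The held-out trial is excluded from template construction
wherever it appears — and only there; a strict variant that also drops the
same-index repeat from the competing sound is available
(`template_mode="loo-both"`). Consonant contrasts use forty 1-ms bins over
the first 40 ms; the vowel contrast uses a single 300-ms bin, where the
distance reduces to an absolute count difference and exact ties are common.
Ties are broken uniformly at random under a caller-supplied seed; an
expected-accuracy mode scores ties as one half. Accuracy is aggregated per
site (mean over the 36 consonant pairs or 3 vowel pairs), then compared
across groups at the site level.

### Noise-burst metrics

Driven spikes per burst: mean over bursts and repeats of the count in
`[onset_k, onset_k + w)` minus the expected spontaneous count, with `w`
defaulting to the full 100-ms inter-burst interval. Onset latency is the
median across repeats of the first spike after train onset; peak latency is
the peak-bin center of the first excursion of the pooled 1-ms PSTH over the
first interval. Vector strength is computed over all spikes pooled across
repeats within the train span (0 to last onset + one period), with phases
referenced to the inter-burst period; the paper-standard inclusion window is
not stated anywhere authoritative, and pooling maximizes the spike count.
The Rayleigh statistic is 2·n·VS² with 13.8 as the significance criterion
(p ≈ e^(−13.8/2) ≈ 10⁻³ under the uniform null).

### Group statistics

Normality screening uses the Lilliefors-corrected Kolmogorov–Smirnov test
(mean and SD estimated from the sample). The omnibus test is Kruskal–Wallis;
pairwise contrasts are two-sided Mann–Whitney U tests, exact when both
groups have n ≤ 20 and the pooled sample is tie-free, otherwise the normal
approximation with tie correction. Pairwise tests are uncorrected by default
(Holm adjustment by flag). Samples identical within and across groups return
p = 1 by convention. Receptive-field properties are compared with the
classic Brown–Forsythe heteroscedastic ANOVA: F* = Σ nᵢ(m̄ᵢ − m̄)² /
Σ (1 − nᵢ/N) sᵢ², with k − 1 numerator and Satterthwaite denominator degrees
of freedom (statsmodels' `anova_oneway(use_var="bf")` reproduces the same
statistic but applies a Mehrotra numerator-df correction; the classic form is
implemented here and cross-checked against statsmodels in the tests). The
analysis unit is the recording site; per-animal aggregation is available in
the site table but is not the tested unit.

## The synthetic cohort generator

The generator exists so every stage can be validated against known ground
truth. Each site is an inhomogeneous Poisson process: a spontaneous
background plus stimulus-locked driven components.

* **Transients** are compactly supported alpha-like bumps rising from zero
  at the onset latency to a unit peak at the peak latency and back to zero at
  the end-of-peak latency (`k(t) = u²·v^β` with β chosen to place the
  stationary point at the peak). Compact support — unlike a literal alpha
  function — makes all three latencies recoverable in principle.
* **Tones** drive a transient scaled by a V-shaped tuning surface: zero
  below threshold; above it, a frequency band centred on the CF whose octave
  extent widens linearly with level through (BW10 at threshold+10 dB, BW40
  at threshold+40 dB), uniform in amplitude across the band at each level
  (the V comes from the widening extent, and box flanks keep noiseless
  bandwidth recovery exact), growing from 0.85× at threshold to 1× at
  threshold+40 dB.
* **Speech tokens** drive a consonant transient (0.30× the site's peak tone
  rate, modulated per token) plus a sustained vowel plateau (0.009× the peak
  rate) over the 40–340 ms window. Token profiles give stops/affricates
  stronger and earlier consonant onsets than fricatives/aspirates, and the
  three "d"-initial tokens share one consonant profile so the vowel contrast
  isolates the vowel window; the "ee"/"oo" vowels sit at 0.5×/1.5× the "a"
  plateau. Consonant factors average 1 over the nine "-ad" tokens and vowel
  factors average 1 over the catalog, so the group-gain calibration is
  unaffected by token structure.
* **Noise-burst trains** drive one transient per burst onset (0.35× the peak
  rate), with per-group gain and onset/peak latency shifts.

Site parameters are drawn per site from one RNG stream keyed by (seed, group
index, site index), so cohorts are bit-reproducible and any subset of groups
regenerates identically. CF is log-uniform over 1–32 kHz and mapped
monotonically to recording depth (800 µm per octave from 1,000 µm, 150-µm
jitter) to create tonotopy. Thresholds are normal about the group mean (SD
8 dB) and snapped to the 5-dB grid lattice — an extracted threshold is only
ever observed at a grid level, and snapping makes the configured group mean
the expectation of the extracted mean rather than sitting half a grid step
below it. Latency, bandwidth, spontaneous-rate (lognormal, mean 30 Hz, CV
0.4), and peak-rate (lognormal, mean 1400 Hz, CV 0.25) distributions are
identical across groups.

Group contrasts enter only through the per-group gain configuration. The
packaged defaults encode the study's reported effect structure: the VPA
group's speech gain is 0.70× saline (the reduction is reported as
significant but without a printed magnitude; 0.70 is a fixed choice);
VNS-tone pairing multiplies the VPA speech gain by 1.44 and raises burst
gain to 1.30 with −1 ms onset/peak shifts; VNS-speech pairing multiplies the
VPA speech gain by 0.95 with the consonant gain at 0.8 and the vowel gain
raised to balance — the balance point uses the consonant's share of expected
whole-window driven spikes, computed from the kernel integral, so the
whole-window contrast is exactly −5% while the consonant component falls and
the vowel component rises. Tone gains are equal across groups. Group mean
thresholds are 17.35, 17.35, 17.78, and 12.35 dB; default site counts are
453, 374, 183, and 146.

**What the generator does not emulate:** spike waveforms and sorting,
non-Poisson spike-train statistics (refractoriness, bursting, adaptation
across the train), inhibitory sidebands and non-monotonic rate-level
functions, multi-peaked receptive fields, across-site and within-animal
correlations (sites are independent given the group), and any acoustic
structure of the tokens beyond the window-level response template. Passing
tests therefore demonstrate that the pipeline recovers known parameters from
data satisfying its distributional assumptions — not that those assumptions
hold for any particular recording.

## Simulation method

Spike trains are drawn by component: homogeneous components (background,
vowel plateaus) are drawn exactly (Poisson count + uniform times), and each
transient is thinned against its own amplitude over its compact support, so
no global-maximum rejection pass is needed and the acceptance rate stays
high. A generic rate callable is also supported, thinned against 1.05× its
maximum on a 4096-point grid. Tone-grid sweeps (1,296 single presentations
per site) are drawn in one vectorized pass, since all tones at a site share
the same transient timing and differ only in amplitude. Simulated sweep
durations are 50 ms for tones, 400 ms for speech and silence, and 600 ms
(train + one period) for burst trains.

## Problem sizes and tolerances

Stochastic validation uses parameter-recovery at 150 sites per group with
tolerances of ±3 Monte-Carlo standard errors (computed from the observed
across-site or across-seed spread, never hard-coded): the +44%/−5% speech
contrasts over 10 generator seeds, the saline threshold calibration
(17.35 dB within 1 dB), burst latency-shift recovery within 0.5 ms, and
classifier chance convergence over 200 sites. Exhaustive oracles back the
discrete procedures: leave-one-out classification is checked fold-by-fold
against an independent enumeration for ≤ 5 trials per sound, and
Mann–Whitney p values against full permutation enumeration for n ≤ 8.
Floating-point distance ties in the classifier are detected with a 1e−9
relative tolerance. The grid-design and vector-strength checks are exact.

## Known limitations

* End-of-peak latency is criterion-defined and reads earlier than a smooth
  transient's true return to baseline (see above); comparisons between
  groups are unaffected because the bias is shared.
* The Kruskal–Wallis/Mann–Whitney layer treats sites as independent;
  litter and within-animal correlations are not modeled.
* Bandwidths at band edges truncated by the grid's intensity or frequency
  limits are reported as measured (or NaN), not extrapolated.
* The classifier's default template asymmetry (held-out sound at 19 repeats,
  competitor at 20) leaves a sub-percent pessimistic bias at chance; the
  strict both-19 variant removes the asymmetry at the cost of pairing
  repeats by index.
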