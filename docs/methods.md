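# Methods

This package reimplements, as a tested pipeline, the statistical analysis of
prefrontal tetrode recordings taken across three behavioral sessions — an
unstimulated neutral baseline, a cued fear-recall session with intermittent
freezing, and a capsaicin tonic-pain session with intermittent nocifensive
behavior — together with the dual-label cell-count statistics used to
quantify engram reactivation and overlap. Because the original recordings
are not bundled, every stage is driven and validated by a synthetic-data
generator whose ground truth is known by construction. This note documents
the models, the parameters that matter, the numerical choices, and what the
synthetic validation does and does not establish.

## Spike extraction

Raw multi-channel traces are referenced by subtracting the across-channel
median at every sample, band-pass filtered 300–6,000 Hz with a fourth-order
Butterworth filter, and thresholded at 9× the per-channel median absolute
deviation (MAD). For Gaussian noise, 9×MAD ≈ 6.07σ, so chance crossings are
negligible even over hour-long sessions.

Numerical choices the procedure itself does not pin down:

- **Zero-phase filtering** (`sosfiltfilt`). Waveform features (trough width,
  trough-to-peak time) are meaningless if the filter shifts phase, so the
  band-pass runs forward–backward. The effective magnitude response is the
  square of the single-pass design.
- **Event extraction.** Each contiguous supra-threshold run yields one event
  at its signed extremum; a 1-ms per-channel dead time then merges
  re-triggers of a single spike, keeping the larger extremum. Snippets are
  2 ms, centered on the extremum.
- **MAD estimation window** is the whole session per channel. On traces that
  contain spikes this is still robust: at 5 Hz and ~1.5-ms templates, spikes
  occupy <1% of samples.
- **Degenerate inputs.** An all-zero channel has MAD 0 and produces no
  detections (not an error). Single-channel traces skip the common-median
  step with a warning.

A caveat surfaced by the synthetic oracle: with very few channels the
common-median reference is itself noisy. The median of 4 channels is the
mean of the two middle order statistics; subtracting it narrows the *core*
of each channel's noise distribution more than its tails, so a 9×MAD
threshold on the referenced signal is effectively slightly more permissive,
and coincident spikes on two of four channels leak ±half-amplitude artifacts
into the other channels. Neither effect is visible at the 64-channel
geometry the reference is designed for. The detection oracle therefore uses
a single 5-Hz unit on a 4-channel trace; there it measures 100% recall
within ±0.5 ms, a false-event rate ≤0.1 Hz, and MAD-based σ recovery within
2% (typically <0.2%).

### Duplicate-unit pruning

The same neuron can be isolated twice from neighboring channel groups. Pairs
of units sharing more than 10% of their spike times are resolved by removing
the member with the higher fraction of inter-spike intervals inside the 2-ms
refractory period (the more contaminated unit). "Common spike time" needs a
tolerance at finite sampling rates: spikes within ±0.5 ms count as shared,
and the denominator is the smaller unit's spike count, so a fully nested
duplicate scores 1 regardless of which unit is larger. Pruning iterates on
the currently worst pair until none exceeds the cutoff; ties in refractory
fraction are broken toward keeping the unit with more spikes, then by unit
id, making the procedure deterministic and idempotent. A brute-force O(n²)
oracle reproduces the fast implementation exactly on constructed unit sets.

## Global rate coding and the same-state null

For each unit the mean firing rate is computed over 4 min of baseline, 7 min
of the fear-recall session, and the first 3 min after capsaicin injection.
The decision statistic is L = ln(r_state / r_baseline). Its null
distribution is calibrated empirically from *same-state* session pairs
(repeated baseline or repeated fear sessions): pooled log ratios centered on
zero, whose sample standard deviation σ sets the significance threshold at
2σ. A unit is increased/decreased in a state when |L| exceeds 2σ, and
categorized fear-only / pain-only / common / neither from the two per-state
directions; the common-increased subset is reported separately because the
commonly activated population is the scientific quantity of interest.

Choices and caveats:

- **Natural log** throughout (any base is consistent if used everywhere).
- **Low-rate exclusion.** Units with any window rate below 0.05 Hz are
  excluded from null fitting and marked unclassifiable: the log ratio of a
  near-zero rate is dominated by counting noise and would inflate σ.
- **Centering.** σ is computed about the sample mean rather than forcing the
  mean to zero; a mean exceeding σ/2 triggers a data-quality warning, since
  a same-state data set should be centered on zero and a visible offset
  indicates drift.
- **Calibration is approximate under rate heterogeneity.** For pure Poisson
  spiking, var(L) ≈ 2/(rT), so slow units have wider nulls than fast ones. A
  *pooled* 2σ threshold then flags slow units at more than the normal
  two-tail mass and fast units at less. With base rates uniform on
  0.5–10 Hz and 4-min windows the net flagged fraction on same-rate units is
  ~4.6–5.5%, close to but not exactly the normal-theory 4.55%. In the real
  data, shared session-to-session variability (attention, arousal, drift)
  adds a common variance component that homogenizes the per-unit nulls; the
  generator deliberately omits such shared components, so this check is the
  harder case for the pooled threshold.

## Behavior-locked classification

Firing of the fear and pain sessions is binned with a sliding window 0.8 s
wide advanced in 0.4-s steps (rate = count/width). Bins lying entirely
inside a freezing or nocifensive episode form the behavior-matched group;
bins straddling an episode boundary are excluded; the out-of-episode bins
are retained as a secondary contrast. The tested contrast compares the
behavior-matched bins against the binned rates of the unstimulated baseline
session with a randomized permutation test: the statistic is the group-mean
difference, the null re-splits the pooled bins at the original group sizes,
and the one-sided p-value is (1 + #{null ≥ observed})/(n_perm + 1) with
n_perm = 10,000 by default. The effect size is the standardized mean
difference (pooled-s.d. denominator). A unit is behavior-locked in a state
when p < 0.001 and effect > 0.5, and categorized fear-specific /
pain-specific / common / unspecific from the two states.

- **One-sided test.** Only increases are categorized; decreases are
  reported descriptively via the sign of the effect.
- **Bin dependence.** Adjacent 0.8/0.4 bins share half their samples, so
  bins are not exchangeable and single-bin permutation p-values are not
  exactly calibrated under the null. The bin remains the permutation unit by
  design (matching the analysis being reproduced); a block-permutation
  option (`block=⌈width/step⌉`) is available for users who want
  exchangeability. The effect-size gate (>0.5, i.e. ~7 null standard errors
  at typical group sizes) makes the classifier's realized false-positive
  rate ≪ the nominal α in either case, which the type-I experiment confirms
  (0 of 500 gain-1 units flagged).
- **Discreteness and the uniformity diagnostic.** On integer spike counts
  the ≥-ties convention makes permutation p-values *conservative* — exact
  uniformity on (0,1] is a property of almost-surely tie-free statistics.
  The machinery diagnostic therefore draws exchangeable continuous
  (Gaussian, Poisson-moment-matched) null groups, where the Kolmogorov–
  Smirnov test confirms uniformity; on counts, conservatism (rejection rate
  ≤ nominal) is asserted instead.
- **Bin assignment semantics.** "Outside" means the bin overlaps no episode
  at all; a bin partially overlapping an episode at either boundary is
  excluded. (A literal endpoints-only rule would misfile a bin that strictly
  contains a very short episode.)
- **Heat-map normalization** divides binned rates by the baseline-session
  mean rate, so the baseline rows of a normalized heat map average 1.

## Cell typing

Units are split into putative principal neurons and interneurons by
agglomerative clustering (Ward linkage, Euclidean distance) on the z-scored
half-amplitude duration, trough-to-peak time and mean firing rate, cutting
the tree at k = 2. The cluster with the narrower trough-to-peak *and* higher
mean rate is labeled interneuron — the standard cortical extracellular
convention; if the two criteria disagree, trough-to-peak decides and an
ambiguity warning is raised (expected when a single-phenotype population is
forced into two clusters). Constant features are dropped before z-scoring.
Because clustering operates on z-scores, the partition is exactly invariant
to row order and to per-feature affine rescaling.

## Overlap quantification

For a count table (Fos⁺, tag⁺, double⁺, DAPI, volume): the chance overlap
under independence is (Fos⁺/DAPI)·(tag⁺/DAPI)·100%; the observed overlap is
double⁺ as a percentage of either single-label population (both framings
supported); densities are counts per mm³. The projection-intensity rule maps
8-bit pixels onto nine levels with 10-wide bins up to 50 and 50-wide bins
above, lower edge inclusive, top bin closed at 255 — the bin-edge
inclusivity is a convention choice the verbal rule leaves open.

## The synthetic generator

What it emulates, and the defaults (all in `SimConfig`):

- **Sessions**: baseline 300 s, fear 420 s, pain 300 s, matching the 5/7/5-min
  recording design; analysis windows 240/420/180 s.
- **Episodes**: alternating exponential on/off bouts, mean bout 5 s, duty
  cycle 0.3 per state, truncated at session edges. One timeline per session,
  shared by all units, as in a real recording. The bout-length distribution
  is a stand-in: no distributional description of freezing/nocifensive bouts
  was available, and exponential bouts are the simplest process with the
  right mean and coverage.
- **Spiking**: homogeneous Poisson at a base rate uniform on 0.5–10 Hz,
  multiplied by `episode_gain` (default 3) inside episodes of the unit's
  matched state(s); fear-specific units gain during freezing, pain-specific
  during nocifensive bouts, common units during both, unspecific never. A
  2-ms dead time (default on) enforces refractoriness so contamination
  bookkeeping is meaningful; at ≤10 Hz it removes <2% of spikes.
- **Class mix**: 20% fear-specific, 20% pain-specific, 15% common, 45%
  unspecific — roughly the proportion of responsive units in the recorded
  population. Recovery experiments override this to 50 units per class.
- **Waveforms**: piecewise-linear biphasic templates parameterized directly
  by the two features used for typing (descent width solved so the designed
  half-amplitude duration is exact; positive peak 0.4× the trough depth at
  exactly the designed trough-to-peak time), so typing ground truth is exact
  by construction. Phenotype defaults: principal 0.40/0.70 ms and ~2.5 Hz;
  interneuron 0.20/0.33 ms and ~11 Hz; 12% interneurons.
- **Count tables**: nuclei Poisson in the volume (5×10⁴ DAPI/mm³), each
  labeled multinomially. `true_overlap` interpolates the double-positive
  probability linearly between independence (0) and complete nesting of the
  rarer label (1). Default single-label densities follow the measured scale
  (~6×10³ Fos⁺ and ~3×10³ tag⁺ per mm³).

What it does **not** emulate — and hence what passing tests do not show
about real recordings: no local-field potentials, oscillations, bursting, or
cross-correlation structure; no electrode drift or amplitude instability; no
shared (non-Poisson) rate variability across sessions; rate and phenotype
are uncoupled in the spiking simulation (the phenotype-dependent rate enters
only the cell-typing feature mixture); spike sorting itself is out of scope,
so unit assignment is taken from the generator or from externally sorted
tables, and only the published duplicate-pruning rule is applied.

## Problem sizes used in the bundled experiments

The packaged experiments run at: 1,000 same-state pairs for null
calibration; 500 gain-1 units × 2 states × 10,000 permutations for type-I
control; 500 exchangeable null draws for the uniformity diagnostic; 200
units (50 per class) for category recovery; a 60-s, 4-channel, 30-kHz trace
(~300 spikes) for the detection oracle; 261 units for cell typing. These
sizes give standard errors comfortably inside the checked bands while
keeping a full run to a few minutes on one core.

## Known limitations

- The pooled 2σ global threshold is miscalibrated per unit when rates are
  heterogeneous and counting noise dominates (see above); it is reproduced
  as specified, not repaired.
- Permutation p-values on overlapping bins inherit serial dependence; the
  effect gate absorbs this in practice, but individual p-values should not
  be interpreted as exactly calibrated.
- The duplicate-pruning order (worst pair first) is one deterministic
  completion of a rule stated only pairwise; other orders can differ on
  chains of three or more mutually coincident units.
- `generate_voltage_trace` places templates at sample resolution, so the
  inserted amplitude can be up to one sample's interpolation below nominal.
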