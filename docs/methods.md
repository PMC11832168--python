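# Methods

This note records the models, algorithms and numerical choices behind
`slentrain`, and what the synthetic-data tests do and do not establish.

## Stream construction

Streams are sequences of tokens, each a (syllable, voice) pair drawn from
6 × 6 = 36 combinations; one token every 0.25 s, one duplet every 0.5 s.
A *structured* stream is a semi-random concatenation of three duplets
defined on a single feature. Two constraint rules apply to every element
sequence — no immediate repetition, and no X Y X Y alternation of two
elements — where the "element" is the duplet for the structured feature
and the per-token feature id for the unstructured feature. Under these
rules the structured feature's TPs alternate between 1 (within duplets)
and 0.5 (between duplets) and the unstructured feature's TPs converge to
0.2, which the `empirical_tp` audit verifies on generated output.

The generator samples the duplet sequence *without replacement* from a
balanced multiset (each duplet exactly n/3 times for n divisible by 3, so
a 240-duplet stream contains each duplet 80 times), choosing among legal
successors with probability proportional to the remaining counts. Two
safeguards keep the endgame feasible: an id whose remaining count exceeds
half the remaining slots is forced whenever legal, and states in which an
id has been exhausted with more than three slots left (or the majority
bound is violated) are pruned immediately — with three symbols and the
alternation ban, two surviving symbols can fill at most three more slots.
Dead ends trigger systematic backtracking with per-position tried-sets;
exhausting the backtrack budget restarts, and exhausting restarts raises
`GenerationError`. Constraints are never silently relaxed.

The default lexicon places the duplet *petu* in list A (with *kida* and
*boge* completing the partition); list B (*tuki*, *dabo*, *gepe*) is the
boundary-complement of list A, so every list-A Word is a list-B Part-word
and vice versa, and acoustic content cannot distinguish the two item
types across lists. Any other partition can be supplied as JSON. Test
blocks hold 18 isolated duplets (9 Words — each lexicon duplet three
times — and 9 Part-words cycling the six boundary pairs) with SOAs
uniform on [2.0, 2.3] s; the unstructured feature of test tokens is
resampled under the no-repeat rule. Two open details of the design were
resolved as follows: the alternation rule for the unstructured feature is
applied to per-token feature ids (not duplet positions), and test items
resample the unstructured feature rather than reusing stream tokens.

## Synthetic EEG

The simulator is a measurement model for the statistics downstream, not a
biophysical model. Each channel receives

    x_c(t) = noise_sd * pink_c(t)
           + a_syll * topo_syll[c] * r4(t)
           + a_dup(t) * topo_dup[c] * r2(t)

where `pink_c` is unit-SD 1/f^exponent noise (spectral shaping of white
noise; default exponent 1), `r4`/`r2` are trains of one-cycle
raised-cosine kernels at token/duplet onsets, and the duplet amplitude
follows a saturating learning curve `a_dup(t) = a_dup_max * (1 −
exp(−t/learn_tau_s))` with `t` the accumulated structured-exposure time
(zero during random streams). The curve's form is a modelling choice; the
phenomenon it emulates is a duplet-rate response that emerges over the
first minutes of structured exposure. Default τ = 60 s puts most of the
rise inside the 120 s long structured stream. Phase jitter is a common
latency shift per 7.5 s block, drawn N(0, phase_jitter_sd / 2π·2 Hz).

Test-phase recordings give every item a generic auditory response
(raised-cosine, 0.1–0.6 s, on the syllable topography); Words additionally
carry a dipolar component (`erp_effect` × `topo_erp`, frontal-right
positive / left-temporal negative by default) over 400–1500 ms — the
effect the Word vs Part-word contrasts are built to recover. Artifact
injection corrupts Poisson-placed segments (0.3–1.5 s, 10–60 % of
channels, 10× background SD) and records them in a ground-truth mask.

At 250 Hz a 0.25 s syllable is 62.5 samples; events are placed at the
nearest sample and the 7.5 s epoch (1875 samples — an integer, and an
exact multiple of both stimulation periods) is the alignment unit, so no
resampling is needed anywhere.

The 128-channel layout is a synthetic Fibonacci spiral on a 10 cm-radius
upper hemisphere (nearest-neighbour spacing ≈ 2.2 cm, matching the
≤2.5 cm adjacency criterion); real montage coordinates can be substituted
wherever positions are consumed. Seven disjoint ROIs (Central, Frontal
L/R, Occipital, Prefrontal, Temporal L/R) are defined by polar/azimuthal
sectors and are user-overridable as JSON.

What passing tests on this generator show: that the pipeline recovers
known spectral, temporal and topographic structure at realistic SNR, and
that its statistics are calibrated under its null. What they do not show:
robustness to real infant EEG properties the generator omits — non-1/f
background dynamics, sleep-stage changes, ocular/cardiac artifact
morphology, electrode drift, or violations of the evoked-kernel shape.

## Preprocessing

Filtering is 4th-order Butterworth, zero-phase (forward–backward, SOS).
The entrainment path uses 0.1–40 Hz then an additional 0.2 Hz high-pass;
the ERP path uses 0.2–20 Hz. Segments of 0.5 s are cut from each duplet
onset; a segment is rejected iff at any sample strictly more than 30 % of
channels are flagged; surviving flagged channels are replaced
sample-wise by inverse-distance-weighted means of the 8 nearest clean
channels (pluggable; spherical splines were deliberately not
reimplemented). Fifteen consecutive clean segments form one 7.5 s epoch,
chronologically, never across stream or condition boundaries — 240 clean
random segments yield 16 long epochs; the structured total is 16 + 40 =
56, which is where the 28-epoch (50 %) inclusion threshold comes from.
Epochs are average-referenced per sample and scaled to unit SD over
channels × time; ERP epochs are not baseline-corrected (normalisation is
the last step; a baseline option exists but defaults off).

## Entrainment statistics

ITC is the modulus of the mean unit phase vector over epochs, computed
from a rectangular-window DFT after per-epoch mean removal, with no
zero-padding: the 7.5 s epoch makes the bin spacing 1/7.5 Hz and puts
2 Hz and 4 Hz exactly on bins 15 and 30 (asserted, with no leakage for
on-bin tones). Under incoherent phases E[ITC] ≈ √(π/4N), which is why raw
ITC cannot be compared across different epoch counts; the neighbour-bin
SNR — (ITC − mean)/SD over the 6 bins on each side (0.8 Hz total),
sample SD, target excluded — cancels this bias (verified on noise).

Permutation tests: paired contrasts sign-flip per-subject difference
maps; group contrasts permute group labels; p = (1 + #{perm ≥ obs}) /
(1 + B) with B = 5000 by default, one-sided for
target-vs-neighbours and structured-vs-random, two-sided for the
group × condition interaction. When the full orbit (2^n or C(n, n_a)) is
no larger than B the test enumerates it and the p-value is exact; ties
are counted with a 1e-10 relative tolerance so a split and its complement
always match. Electrode-wise p-values are Benjamini–Hochberg corrected.

## Learning time course and mixed models

The 0.5 s segments of all phases are concatenated chronologically (2 min
random, 2 min structured, 5 min of short structured blocks). A 120 s
window slides in 1 s steps; each window contains 16 aligned 7.5 s
epochs, an epoch being usable iff its 15 segments are artifact-free; a
window needs ≥8 usable epochs, others are linearly interpolated; the
course is smoothed with a centred 30 s moving average that shrinks at the
edges (mean-preserving on linear trends). Window timestamps are window
centres from stream onset, so points centred in the first structured
minute deliberately mix random-phase data — a property of the windowing,
asserted in tests. Electrode sets for the course are the FDR-significant
sets from the static analysis (4 Hz during random for the syllable
course, 2 Hz during structured for the duplet course), with a
fall-back to the 10 strongest-SNR electrodes when nothing survives on a
small simulated cohort.

Learning over the long structured stream is quantified as
`itc ~ -1 + time + (1 + time | subject)` (REML, statsmodels MixedLM);
the group comparison expands `-1 + time * group` to per-group intercept
columns, a reference-group slope, and a slope difference, mirroring the
R-style no-intercept factor expansion. Two numerical details: time is
rescaled by 100 s internally (slopes of order 10⁻³/s otherwise leave the
random-slope variance ~10⁻⁶ times the intercept variance and the Hessian
near-singular) and estimates are back-transformed; Wald statistics are
referred to a t distribution with n_subjects − 1 df rather than a normal
— the slope is effectively a subject mean, the normal reference was
measurably anti-conservative at n = 8 in null calibration, and the
t-based 95 % CI half-width (≈2.02·SE at n = 32) matches how such CIs are
conventionally reported. Non-convergence is surfaced as an exception or
a `converged=False` flag, never swallowed.

## ERP statistics

Test epochs span [−0.2, 2.0] s; analysis restricts to [0, 1.5] s, i.e.
376 samples at 250 Hz. A trial is rejected if any sample is flagged;
subjects need ≥45 clean trials per condition (half of the 90 presented).
The criterion is applied to post-rejection counts.

The cluster test thresholds the per-sample t-map two-sided at clustering
alpha 0.10 (0.05 per tail), clusters supra-threshold samples by spatial
adjacency (≤2.5 cm on the montage; scale the threshold with channel
density when using sparser layouts) and temporal contiguity, separately
per polarity. The ≥3-electrode minimum is enforced per time slice:
slices with fewer members are removed and components re-extracted until
stable. Cluster mass is the summed t; the null is the permutation
distribution of the maximal |mass| (condition labels flipped within
subject, or group labels permuted), and each observed cluster gets
p = (1 + #{max-null ≥ |mass|}) / (1 + B). The ROI route tests each of
7 ROIs × 376 time points (paired t for duplet type, unpaired for group)
with BH-FDR over the full 2632-test family. The guard analysis is a
split-plot ANOVA (duplet type within, group between) computed in closed
form, with generalized η² = SS_effect / (SS_effect + SS_subjects(group) +
SS_error_within); it agrees with pingouin's implementation to machine
precision, which the tests use as an independent oracle.

## Adult ratings

Subject-level condition means feed a paired t per group (Cohen's d =
mean difference / SD of differences, so d = t/√n) and the same split-plot
ANOVA. The rating simulator discretises a latent normal (round, clip to
1–6) with a per-subject rating offset (SD 0.7), a per-subject learning
effect (group mean word-effect + SD 0.8 heterogeneity) and trial noise
(SD 1.4). Group defaults of 0.45 (phoneme) and 0.30 (voice) with 27 and
30 subjects put the subject-level effect sizes near d ≈ 0.55 and 0.37 —
moderate despite 90 trials per condition, because between-subject
heterogeneity, not trial noise, limits d.

## Problem sizes in the test suite

The statistical calibration and recovery suites run at desk scale, chosen
once as sizes at which the asymptotics under test are meaningful:
constraint audits on 1000 seeded streams; TP convergence on a
100,000-duplet stream (±0.02); permutation-vs-enumeration equality at
n ≤ 4; FDR false-positive calibration on 100 null cohorts of 12 × 128
difference maps (B = 500); mixed-model CI coverage on 100 cohorts of 8
subjects × 121 time points; cluster type-I calibration on 100 null
cohorts of 10 subjects on a 16-channel chain montage × 80 samples
(B = 200) and effect recovery with a 400–1500 ms dipole on 24 channels ×
376 samples (B = 500). Full-protocol pipeline tests use 3 subjects per
group at 16 channels with B = 100–200; the defaults of
`ExperimentConfig` (8 subjects per group, 128 channels, B = 500) run the
whole design in minutes on one core.

## Known limitations

* The simulator's evoked kernels, topographies and learning curve are
  stylised; parameter recovery on it bounds correctness, not field
  validity.
* Spatial interpolation is inverse-distance weighting, not spherical
  splines; on very sparse montages interpolation quality degrades.
* The per-slice reading of the 3-electrode cluster rule is one of two
  defensible readings (the other applies it to the whole cluster); it is
  the stricter one and is configurable via `min_electrodes`.
* EDF export is not provided; recordings persist as npz + JSON + TSV.
  EDF reading requires the optional mne dependency.
* `fit_lmm_group` supports exactly two groups, as the design requires.
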