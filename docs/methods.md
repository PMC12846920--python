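# Methods

This note documents the models, algorithms and numerical choices behind
`fearext`, in the spirit of a methods appendix: what each stage computes, what
the synthetic data do and do not emulate, and where design decisions were
genuinely open.

## Experimental design model

A session has three phases. Three cue identities are assigned one-to-one to
the contingency roles CS++ (reinforced in both learning phases), CS+−
(reinforced only during acquisition) and CS−− (never reinforced). Learning
phases present each cue 24 times (72 trials); the test phase presents each 16
times (48 trials) and is never reinforced. Reinforced cues receive the US on
exactly half of their presentations (12/24), with the reinforced ordinal
slots drawn uniformly per cue. Altogether the US occurs 36 times (CS++
12 + 12, CS+− 12).

Trial order is pseudo-random with at most 3 consecutive presentations of the
same cue, enforced by rejection sampling over random permutations with a
randomized-backtracking fallback (the fallback terminates whenever an
arrangement exists; for the default design rejection sampling almost always
succeeds within a few tries). Only same-*item* runs are constrained;
same-*contingency* runs are left free, since the item-level rule is the one
the design specifies.

Contexts are phase-specific (4 / 4 / 8, disjoint pools) and balanced: each
cue sees each context equally often (to within one trial when counts do not
divide). Balance makes context–role contingency exactly independent and gives
the context-specificity metric equal pair counts; a fully unconstrained
randomization would only add variance. Trial timing: 0.5 s fixation, 2 s
video alone, 1.75 s cue overlaid on the video, 1 s US slot, then the rating
prompt; the inter-trial interval is 1.5 s so that the −3 s epoch edge never
reaches the previous trial's US window.

During the unreinforced test phase "current valence" is defined as the
*expected* contingency (CS++ → CS+, others → CS−).

## Synthetic recordings

The generator emulates the statistical structure the analyses assume, not the
biophysics of depth recordings. Each ROI is modeled as one electrode shaft
whose contact count is chosen so that bipolar referencing yields roughly the
reported mean channel counts (e.g. 8 contacts → 7 virtual channels in
temporal cortex). Per contact the background is Gaussian 1/f^α noise
(default α = 1.3, a typical broadband iEEG slope; RMS 50 µV) synthesized by
spectral shaping in the Fourier domain, plus a per-shaft common 1/f component
(gain 0.5) that adjacent-contact subtraction removes — giving the bipolar
stage something real to do.

Planted effects are band-limited oscillatory components added to the
background with amplitudes expressed in multiples of the channel SD:

- **Safety theta**: a 3-sinusoid burst drawn from 3–10 Hz, Tukey-windowed to
  1.18–1.75 s after cue onset, added on currently-safe (CS−) extinction
  trials with a fixed random per-contact loading. An optional baseline theta
  component with trial-to-trial amplitude variation supports coupling
  studies.
- **Item and context signatures**: nonnegative sparse templates over
  contacts × 12 log-spaced frequency bands (top quartile of |N(0,1)| kept,
  unit Frobenius norm), expressed as one random-frequency sinusoid per band
  during cue presentation (items) or video + cue (contexts). Sparsity makes
  distinct signatures near-orthogonal in the *power* domain, where the
  rank-based similarity metrics live (measured band power scales with the
  squared amplitude pattern). The per-trial expression gain carries
  configurable jitter, an across-ROI shared fluctuation (driving cross-region
  coordination), and an optional coupling to the theta amplitude.
- **Memory traces across phases**: each cue's signature is a weighted sum of
  a phase-invariant component and a phase-specific component; test-phase
  trials can additionally re-express the acquisition and extinction traces
  with per-role weights. The mixed template is re-normalized before scaling,
  so reinstatement manipulations change the *direction* of the pattern, not
  the injected energy (deliberate: energy changes would interact with the
  amplitude-based artifact detector). This implements the fear-vs-extinction
  trace competition that differential reinstatement measures.
- **Artifacts**: biphasic spikes (5–50 ms) at a Poisson rate per channel,
  amplitude in channel-SD units, with a ledger of planted positions for
  detector sensitivity/specificity tests.

Ratings (1 = threatening … 4 = safe) follow role-specific target
trajectories: neutral until a changepoint at `learning_onset` (ordinal
position within the cue's own sequence), then the role's asymptote, with
Gaussian noise, rounding, clipping, and a configurable missing-response rate.
The changepoint default (width 0) makes onset recovery well defined; an
exponential transition width is available for smoother curves. Test-phase
targets encode partial renewal (CS++ rated most threatening).

What the generator does **not** emulate: volume conduction and electrode
geometry, phase–amplitude structure, evoked potentials, non-Poisson artifact
clustering, inter-site amplifier differences, and state drift across the
session. Passing recovery tests therefore show that the *pipeline* is
faithful and well calibrated under its own assumptions — not that those
assumptions hold for any particular patient dataset.

## Preprocessing

Filters are zero-phase forward–backward Butterworth sections (2nd-order
high-pass at 0.1 Hz, 4th-order low-pass at 200 Hz, 4th-order band-stops at
49–51/99–101/149–151 Hz); the family is a standard choice, the corner
frequencies are the design's. The artifact detector z-scores three measures
per channel over the whole recording — amplitude, sample-to-sample gradient,
and amplitude after a 250 Hz high-pass — and flags samples with any |z| ≥ 6
or amplitude |z| ≥ 4 together with gradient or high-frequency |z| ≥ 3,
padding ±1000 ms. The high-pass corner is a parameter because it must stay
below Nyquist; reduced-rate simulations use 200 Hz. Of note, in *white*
Gaussian noise the amplitude and gradient criteria co-occur strongly enough
that the conjunction fires about once per minute; under the 1/f backgrounds
the pipeline actually sees, false alarms are rare.

Epochs span −3 to 4 s around cue onset. An epoch is rejected for an ROI if
any sample of any channel in that ROI is flagged inside the window —
ROI-level rejection guarantees complete RSA feature vectors (per-channel
bookkeeping is logged, but partial vectors are never analyzed). Conditions
retaining fewer than 8 trials flag the participant-ROI as excluded from
condition contrasts. Bipolar virtual channels inherit the ROI of their deeper
contact.

## Spectral analysis

Wavelet power uses complex Morlet wavelets with linearly varying cycle
counts: 1–29 Hz in 29 steps with 3→6 cycles and 30–100 Hz in 15 steps with
6→12 cycles (44 frequencies, also the per-channel RSA feature dimension).
The transform is MNE's `tfr_array_morlet`; output is decimated to 100 Hz.
Bins closer to an epoch edge than 3 wavelet standard deviations
(σ_t = cycles / 2πf) are marked edge-contaminated; with the −3/+4 s epoch the
full cue window is valid down to 1 Hz. Video-locked windows near −2 s carry
partial wavelet support below ~1.5 Hz, as in any cue-locked epoching of this
design.

Power is z-scored per channel × frequency against the mean and SD pooled
over *all trials and time points* of the cue-locked reference window. The
pooled-over-time variant makes the reference a scalar pair per
channel × frequency, which matches the normalization's purpose (removing
common signal unrelated to conditions); a per-time-point variant is provided
for sensitivity checks. Condition contrasts average channels within the ROI,
compute per-participant condition means, apply a paired t-test per
time–frequency bin (20-ms steps over 0–1.75 s; a computational-economy
choice) and correct with the cluster permutation described below. The CS−
condition during extinction pools CS+− and CS−− trials (current-valence
definition).

## Pattern similarity

Feature vectors average z-scored power in 500-ms windows stepped by 50 ms
(90% overlap; 25-ms steps, 95% overlap, for coordination maps), flattened
over channels × 44 frequencies; window centres are reported at midpoints.
Trial pairs are compared with Spearman's ρ (average ranks for ties) at
matching window centres; values are Fisher z-transformed with |ρ| clamped to
1 − 10⁻¹² before atanh. Pairs involving a zero-variance vector are recorded
as missing, never as zero. Patterns are never averaged across repetitions.

Item stability averages within-item pair similarity; the contingency class
containing two cues is computed per cue and then averaged across cues
(never by pooling pairs), so each cue contributes equally despite the
unbalanced 2-vs-1 design. Context specificity is mean same-context minus
mean different-context pair similarity over all trial pairs; a variant
restricted to different-cue pairs controls the item-identity confound, since
whether the original analysis applied that restriction is ambiguous.
Single-trial versions average each trial's similarity to the relevant pair
set.

## Coordination, theta coupling, reinstatement

Single-trial metrics from two ROIs (intersection of retained trials, since
rejection is ROI-dependent) are Spearman-correlated across trials at every
pair of window centres, giving a temporal-generalization map per participant;
group inference is a t-test of Fisher-z ρ against zero per bin with 2D
cluster correction, the null re-shuffling one ROI's trial order. A
within-condition z-scoring control removes correlations driven purely by
condition mean differences. Cluster-averaged theta power (z-scored within
condition) is correlated with item stability / context specificity across
trials, window-averaged (Bonferroni across ROIs) or time-resolved
(cluster-corrected).

Differential reinstatement subtracts, on the Fisher-z scale,
extinction-to-test from acquisition-to-test same-item similarity, averaged
over trials and over the configured analysis window. The defaults reproduce
the windows the original analyses derived from data (context specificity
0.8–1.15 s; temporal-cortex item window 0.65–1 s); recovery studies set the
window to the planted extent instead, since synthetic effects span the whole
cue period. Fisher z is applied before any averaging, consistent with the
rest of the pipeline. Trial-level extinction reinstatement (same-item minus
different-item similarity, the different-item set being all non-matching
cues) is correlated with test ratings per participant; participants drop
below 4 usable trials, or with constant ratings (undefined correlation),
rather than being zero-filled. An optional 2-SD outlier exclusion replicates
the robustness variant.

## Cluster-based permutation inference

Bins whose group t exceeds the two-tailed cluster-forming threshold
(α = 0.05, df = participants − 1) form sign-homogeneous connected components
(adjacency in 1D; 4-neighbourhood in 2D — diagonal connectivity would only
enlarge clusters). Cluster mass is the summed t. The null distribution
collects the largest |mass| per permutation; per permutation, trial labels
are re-shuffled independently within every participant and the full group map
recomputed (a participant-level sign-flip scheme exists but is not the
default). Corrected p = (1 + #{null ≥ observed}) / (1 + n_perm), so p > 0
always; default 1000 permutations (200–500 in reduced-scale studies).
Non-finite bins are excluded from clustering with a log entry.

The behavioural learning-curve test runs a paired Wilcoxon signed-rank test
at every within-condition ordinal position. Observed and surrogate statistics
use S = Σ sign·rank; tail probabilities are *exact*, computed by dynamic
programming over the sign-randomization distribution of S (ties allowed,
zeros dropped), which is what makes the permutation thresholding consistent
between observed and null. Condition labels are flipped per
participant-position by default (a global per-position variant is provided,
since the randomization unit was ambiguous). Positions with fewer than 5
valid pairs are skipped. The two-way repeated-measures ANOVA is statsmodels'
`AnovaRM` with partial η² = F·df₁/(F·df₁+df₂) and Bonferroni-corrected
post-hoc paired t-tests; participants with incomplete cells are dropped
listwise.

## Validation studies and problem sizes

`fearext.studies` freezes the package's own evidence of correctness at sizes
that run in minutes on one CPU: 500 Hz recordings, 2 virtual channels per
ROI, 8–12 rep designs, 200–500 permutations.

- **FWER calibration**: 1000 Gaussian-null datasets (8 participants,
  16 trials, 4×6 maps, 500 permutations) — family-wise error within
  0.05 ± 0.02.
- **Null cohorts**: 100 full-pipeline cohorts (4 participants, extinction
  only) with all gains zero — theta, item-stability and context-specificity
  detection each ≤ 7%.
- **Effect recovery**: 20 cohorts of 8 participants with safety theta planted
  in the amygdala and item/context signatures in lateral prefrontal
  electrodes (separate ROIs, because the theta burst is shared across CS−
  trials and would itself raise CS− item stability) — each effect recovered
  in ≥ 90% of cohorts, the theta cluster overlapping 3–10 Hz × 1.18–1.75 s.
- **Coupling recovery**: 20 cohorts of 12 participants whose context-pattern
  gain and fear/extinction trace balance at test covary for CS+− only —
  selective recovery (CS+− significant, others not) in ≥ 80% of cohorts.
  Participant gains are evenly spaced rather than drawn at random, which is
  the efficient design for estimating a rank correlation from 12 points.
- **Behavioural onset**: 20 rating-only cohorts of 16 participants,
  changepoint at trial 10 — cluster onset within ±3 positions.

Simulation and permutation seeds are always drawn from separate streams: a
shared stream would make the surrogate labels a deterministic function of the
same bits that generated the data.

## Known limitations

- The generator's additive oscillatory signatures approximate multiplicative
  band-power modulation only to first order; at large gains the injected
  components dominate the background.
- EDF files can be read (via MNE) but not written; the native serialization
  is HDF5.
- White-matter channel exclusion and electrode localization are out of scope;
  synthetic data contain no white-matter contacts.
- No time–frequency output is produced above 100 Hz, and phase-based
  connectivity (e.g. weighted phase-lag index) is not implemented.
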