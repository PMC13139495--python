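# Methods

`songrules` reimplements, as a tested library, the analysis chain used to
study how a courting male fly patterns his song (pulse, sine, or silence)
as a function of sensory feedback from the partner: kinematic feedback
features from two-fly pose, an input-driven hidden-state multinomial model
(HMM-GLM) of song patterning, unsupervised behavioral maps, and song signal
statistics. Every stage can be exercised end to end on synthetic data with
known ground truth.

## Feedback features (kinematics)

Six tracked body parts per fly (head, neck, thorax, abdomen, wingtips) are
reduced to ten per-frame cues at 30 Hz: signed forward velocity along the
head–abdomen axis (cFV/pFV, mm/s), lateral speed (cLS/pLS, mm/s) and
rotational speed (cRS/pRS, deg/s) as magnitudes, thorax–thorax distance
(dis, mm), the courter's angular position in the partner's frame (cθ, deg,
0 = at the partner's head), the partner's position in the courter's frame
(pθ), and the absolute body-angle difference (φ). A frame counts as an
interaction when dis < 8 mm and at least one fly holds the other within
±60° of its heading; with mutual facing the previously established courter
keeps the role (at a cold start, the fly seeing the partner more centrally,
ties to fly 0). The head quadrant is cθ ∈ [0°, 90°), the tail quadrant
[90°, 180°]. Quadrant occupancy drops bouts shorter than 0.5 s and merges
same-quadrant bouts separated by less than 0.5 s before counting.
Tail-to-head transition events require ≥ 2 s in the tail quadrant
immediately followed by ≥ 2 s in the head quadrant; the event time is the
first head frame.

Numerical choices: tracks are resampled from the acquisition rate (100 Hz)
to 30 Hz with a polyphase anti-aliasing filter using line-extension padding
(constant and linear tracks stay transient-free at the edges); headings are
unwrapped before differentiating so 360° jumps do not inflate rotational
speed; missing keypoints are linearly interpolated up to 0.2 s, longer gaps
raise. Angles are degrees at all interfaces, radians internally.

The relative-angle convention deserves a note: cθ is measured in the
*partner's* frame (it decides head vs tail position) and pθ in the
*courter's* frame (it decides the field-of-view criterion). Swapping
courter and partner swaps cθ and pθ.

## Song statistics

Pulse waveforms are 35 ms snippets at 10 kHz centered on pulse times.
Carrier frequency is the argmax of the FFT magnitude below 1 kHz (the
spectral-centroid reading of "central frequency" is noted but not used).
The envelope is the magnitude of the analytic signal, smoothed with a
Gaussian of sd 1.5 ms truncated at ±4σ and normalized to unit peak; pulse
width is the time above half peak. Pulses whose normalized envelope has
max − mean < 0.08 are flagged noisy; envelopes crossing 0.5 into more than
one region are flagged multi-peak; flagged pulses are excluded from width
summaries. Inter-pulse intervals above 100 ms span bouts and are dropped.
Sine carrier is the modal per-segment FFT argmax over 256-sample segments.
Bouts are runs of song whose silent gaps are < 100 ms; bout order is one
plus the number of within-bout mode transitions. Windowed amount / onsets /
duration use 1-min windows at 50% overlap.

Pulse-type clustering normalizes waveforms to unit peak and fixes polarity
by correlation with a reference waveform, then with the aligned mean — a
per-waveform "dominant extremum positive" rule is unstable for symmetric
carrier pulses and splits each family into mirrored clusters. The
normalized waveforms are embedded with UMAP and clustered with HDBSCAN;
the two largest clusters define the fast (shorter mean envelope) and slow
types, and an RBF support-vector classifier trained on them labels the
remainder.

## The HMM-GLM

Hidden states are sensorimotor rules; observations are the song modes
{pulse, sine, silence} at 30 Hz (fast and slow pulses merged). The state
sequence follows a fixed K×K transition matrix α and initial distribution
π. Each state k owns a filter bank W_k mapping the covariate vector x_t to
softmax probabilities over the three modes; the silence filter of every
state is pinned to zero (softmax gauge fixing).

The covariate vector is the 4 s history (120 lags at 30 Hz) of all ten
cues — a raw lag vector of length 1200 — projected per cue onto D = 10
raised-cosine basis functions whose peaks are log-spaced in lag and which
broaden with delay (narrow resolution where recent history matters),
z-scored per column with statistics frozen on the training trials, and
augmented with a constant 1: (10 × D) + 1 = 101 values. D is a free
choice; 10 keeps
≈12:1 compression while resolving sub-second structure. Rows with
incomplete history at a trial's start are mean-padded (the causal filter
runs on the mean-centered signal), equivalent to mean-imputing missing
lags.

Inference is the scaled forward–backward recursion with per-step
normalizers; the per-step log normalizer is the predictive
log P(y_t | y_{1:t-1}, X), and their sum the trial log-likelihood. State
marginals γ, pairwise marginals ζ, and the Viterbi path (log-domain,
ties to the lower state index) follow. The inner recursions are jitted
with numba when available, with an identical numpy fallback.

Fitting is EM. The M-step updates π and α in closed form from γ and ζ and
fits each state's filters by γ-weighted multinomial logistic regression
with an L2 penalty (default 10⁻³ per training sample on the free filter
entries), warm-started from the previous iteration via L-BFGS. The inner
optimizer is capped (100 iterations on the first EM step, 25 after); if an
inner step fails to improve its objective the previous filters are
retained, so the penalized objective is non-decreasing every iteration
(generalized EM). Convergence: relative objective change < 10⁻⁶ or 200
iterations; multiple restarts, best by the penalized training objective.

**Initialization.** Small-variance random filters with a sticky transition
matrix leave all states with nearly identical emission maps, and EM then
converges to a merged-state optimum essentially every restart (we observed
all restarts landing ~200 nats below the basin reachable from the true
parameters, with decoded-state accuracy near chance). The default
initialization therefore first fits a label-only categorical HMM by
Baum–Welch (closed-form updates; itself exposed as the input-blind
baseline) and seeds each state's bias filters from that model's emission
frequencies, plus small random noise; `init="random"` gives the plain
random scheme. With the informed start, EM on default synthetic data
converges in a few dozen iterations to a basin slightly above the
truth-initialized objective.

Evaluation normalizes held-out log-likelihood against a chance model that
predicts each mode's empirical frequency on the evaluation frames:
NLL = (LL − LL₀) / (n·log 2) bits per sample; the chance model scores
exactly 0. Transition-restricted NLL evaluates the predictive per-step
normalizers only at frames where the song switches between two given
modes, referenced to the chance probabilities of the switched-to labels.
Baselines: the GLM-only model is the K = 1 fit; the HMM-only model is the
categorical HMM wrapped as bias-only filters.

Downstream analyses: states are named *whatever* (highest mean silence
emission), *chasing* (pulse-dominant of the rest) and *close*
(sine-dominant); ambiguous orderings raise rather than guess. Permutation
feature importance shuffles one cue's time series across time before lag
expansion and reports the drop in total log-likelihood (equivalent, up to
sign and normalization, to a likelihood log-ratio, and easier to read). The counterfactual position
sweep holds a swept angle (cθ or pθ) constant over its entire history at
each of 181 values from 0° to 180° in 1° steps (both endpoints included),
couples φ = 180° − angle, and exploits the linearity of the basis
projection: a constant-history cue contributes value × column-sums to the
design, so only two feature blocks of each design row change. The decision
space is the elementwise product of the active state/mode filter with the
design row, embedded in 2-D with seeded UMAP.

## Behavioral maps

Social maps flatten the last 15 samples of all ten cues into a 150-wide
lag design, fit a seeded 2-D UMAP on a temporally uniform 10% subsample of
the pooled frames, transform all frames, estimate a density on a grid
(histogram convolved with a Gaussian — a binned KDE; default 512² grid,
smoothing 4 cells; unit tests use smaller grids), and segment modes by
watershed on the inverted density masked above the 1% density quantile.
Per-fly maps use Morlet wavelet power at 25 dyadically spaced frequencies
(1–25 Hz) of 24 egocentric pose channels (both flies' six keypoints, x and
y, translated to the thorax, rotated to the heading, scaled by fly
length), flattened to 600 per frame. Embedding hyperparameters, bandwidth,
grid size and the background quantile are configuration with fixed
defaults; because the embedding is seed-dependent and these knobs shape
the segmentation, mode counts on real data are not treated as
reproducible targets.

## Synthetic data: the study conditions

Each cue follows a discretized Ornstein–Uhlenbeck process at 30 Hz with a
stationary mean, sd and correlation timescale chosen to be realistic for a
courting pair in a 44-mm chamber (e.g. courter forward velocity 5 ± 4 mm/s
with a 0.5 s timescale, distance 5 ± 3 mm with a 1 s timescale, angles
90 ± 50° with a 1 s timescale). Speed-like cues take the absolute value
and angles are folded into [0°, 180°], so their realized moments differ
from the underlying Gaussian ones the configuration states.

The default generative song model has three sticky states (diagonal 0.97):
a silence-biased *whatever* state, a pulse-biased *chasing* state whose
pulse filter loads on distance and courter lateral speed, and a
sine-biased *close* state with a negative distance loading on sine —
reflecting that lateral speed and distance are the leading cues during
courtship. Filter loadings decay across basis functions (recent history
matters most). Under the true parameters, Viterbi decoding recovers the
simulated state path at ≈93%, so the configuration is identifiable but not
trivial.

Scripted pose scenarios provide analytic ground truth for the kinematics
chain. `male_turns` alternates 6 s phases: the partner walks along +x at
4 mm/s with the courter trailing 3 mm behind (tail quadrant), then stands
reversed facing the courter (head quadrant); both paths are continuous and
the scripted reversal times are the ground-truth tail-to-head transitions.
`female_slows` drops the partner's forward speed from 8 to 2 mm/s during
scripted song epochs while the courter circles to the partner's front.
Synthetic audio renders pulses as a 250 Hz carrier under a Gaussian
envelope (FWHM = pulse width) and sine song as a pure 150 Hz tone; the
playback stimulus is a train of 4 ms pulses at a 36 ms inter-pulse
interval in ten ~30 s amplitude steps.

What the generator does *not* emulate: pose-estimation noise structure
(occlusions, identity swaps), chamber-wall geometry, the closed-loop
coupling between the partner's behavior and the male's song, audio
crosstalk across microphones, and agonistic song. Passing tests therefore
demonstrate that the algorithms recover what they are supposed to recover
under known generative conditions — not that the biological conclusions
transfer to any particular recording.

## Problem sizes and tolerances

Exhaustive-enumeration oracles check forward–backward, γ, ζ and Viterbi
for all random instances with T ≤ 8, K ≤ 3 at 10⁻⁸ in the log domain.
Parameter recovery uses one T = 50,000 trial from the default generative
model (α within ±0.05 elementwise, posterior-averaged per-state emission
probabilities within ±0.05 after best-permutation state alignment,
decoded-state accuracy > 85%); baseline-ordering checks train on 12,000
frames and hold out 6,000 with three EM restarts — enough data and
restarts that the full model's held-out advantage over the input-blind
HMM (≈0.04–0.06 bits/sample under the default generator) is not lost to
a poor EM basin. EM monotonicity is asserted across 20 restarts at
T = 3,000 with a relative slack of 10⁻⁸ for floating-point roundoff.
Kinematic recovery tolerances are set by finite-difference error at 30 Hz
plus resampler ripple (~0.01 mm/s on constant tracks). The pulse-width
check compares the measured half-peak duration of the playback pulse
against the closed-form Gaussian convolution
FWHM' = sqrt(FWHM² + (2.355·1.5 ms)²) within 0.5 ms (discretization plus
envelope-carrier leakage at a 250 Hz carrier).

## Known limitations

- Transitions are input-independent by design (fixed α); input-driven
  transitions are out of scope.
- UMAP is a stochastic, seed-dependent embedding; maps are reproducible
  under a fixed seed but not canonical across seeds.
- The M-step cap makes fitting a generalized EM; objectives can improve
  for many iterations on hard data before the relative-change stop fires.
- `sine_carrier` assumes a stationary carrier within a bout; frequency
  modulation shows up only through the segment mode.
- Wing-extension detection assumes the six-keypoint skeleton; it has no
  notion of wing occlusion.
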