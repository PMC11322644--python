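# Methods

This note records the modelling and analysis choices behind `criticaldyn`:
what is simulated, which knobs matter, where the design was genuinely open
and what was decided, and what the synthetic data do and do not establish.

## The Epileptor and its integration

The model is the standard five-dimensional Epileptor (fast pair x₁/y₁,
slow spike–wave pair x₂/y₂, permittivity z) with a long permittivity
timescale τ₀ = 20000 so that interictal and ictal episodes last realistic
times under the 1 model unit = 10 ms correspondence. The fast-subsystem
offset y₀ defaults to 1, the value of the original model formulation; it is
configurable but nothing in this package depends on another choice.

The exponentially weighted integral g(x₁) that feeds the spike–wave
subsystem is realized as the linear filter ġ = x₁ − γg, initialized at its
steady state x₁(0)/γ. This is the standard state-space realization of such
a kernel; the integral's printed bounds in the source formulation are
ambiguous, and the filter form is exact for an exponential kernel on the
whole past.

**Step sizes.** The fast subsystem has a local relaxation eigenvalue of
about −16 per model unit at the interictal fixed point, so explicit schemes
are only marginally stable at Δt = 1 (one 10 ms step). Stimulation
experiments integrate at Δt = 0.1 (1 ms of real time): fine enough that a
3 ms pulse occupies three internal steps, and trajectories are decimated
back to the canonical 10 ms grid on output. Stimulation-free signature
runs integrate at Δt = 0.02 (0.2 ms), where the stationary fluctuation
statistics of the stochastic system are converged (halving Δt again changes
the reported contrasts by less than their bootstrap error). A Richardson
estimate on a smooth sub-threshold transient confirms ≥ 3rd-order
convergence of the deterministic RK4 path.

**Noise.** Additive white Gaussian noise of variance (0.005, 10⁻⁴, 10⁻⁴)
per unit model time on (x₁, x₂, y₂); the per-step increment is
σ√Δt·N(0,1). The integrator is a stochastic Heun (predictor–corrector)
scheme, strong order 1.0 for additive noise; with all variances zero it
degenerates to a second-order deterministic scheme and matches RK4 to
< 10⁻⁶ on stationary runs. The exact scheme used in prior Epileptor work is
not identifiable, which matters for the skewness/autocorrelation contrasts
(below).

**Fixed points and the critical point.** The interictal equilibrium is the
root of the full six-dimensional field on the x₁ < −4/3 branch, found by a
Newton–Krylov solve from the analytic lower-branch cubic and verified
stable by finite-difference Jacobian eigenvalues. The fast-subsystem fold
sits at x₁ = −4/3, z ≈ 2.915 (for y₀ = 1, I₁ = 3.1), giving a critical
excitability x₀ ≈ −2.062: the three probe conditions (−2.30/−2.25/−2.20)
are subcritical, and x₀ = −2.0 is supercritical with recurrent spontaneous
seizures. The bifurcation diagram freezes the slow variables (x₂ at a
configurable value, default 0) to expose the S-shaped branch structure and
locates the fold by bisection on the existence of the stable non-ictal
branch.

**Seizure detection.** In-silico onsets are detected as the first crossing
of x₁ > 0 that stays above a sustain threshold for 10 s of real time
(mirroring the experimental "sustained > 10 s" rule). The sustain
threshold is −1.2: intra-ictal oscillation troughs reach about −0.8 and
the interictal rest sits near −1.5, so −1.2 separates the two regimes with
margin. A tighter threshold makes detected time-to-seizure fragile to
pulse-phase alignment and artificially non-monotone in frequency.

**Time-to-seizure.** Deterministic by default (continuous rhythmic train
from the fixed point, onset time returned). Even after correct detection,
the noise-free system integrates pulses with mild alignment effects;
monotonicity in x₀ and frequency holds cleanly on the 20/30/40 Hz grid
used in tests. Frequencies ≤ 10 Hz may never provoke a seizure at low
excitability (full recovery between pulses) — the returned value is then
None, not a number. An option averages stochastic realizations (stated
noise, independent seeds, censored at the maximum duration).

## The passive-signature experiment

Three stochastic runs (x₀ = −2.30, −2.25, −2.20) start at their fixed
points, discard a 100 s transient, and are chopped into 790 contiguous
stimulation-free 4 s epochs. Per epoch, four signatures:

* **variance, skewness, autocorrelation half-width** — computed on
  0.5–100 Hz band-passed epochs (4th-order zero-phase Butterworth), the
  standard passive-signature band. The half-width is the lag of the first
  downward crossing of r = 0.5 of the lag-0-normalized autocorrelation,
  linearly interpolated between integer lags (interpolation is needed to
  resolve the few-sample half-widths of weakly correlated epochs);
  skewness uses the √(N(N−1))/(N−2) adjustment, variance the population
  (N) denominator.
* **line length** — computed on the raw, unfiltered samples at the
  integration resolution. The proxy is a diffusion: its per-sample
  increments are dominated by the driving noise, which is what makes line
  length a near-condition-independent per-sample excursion measure (its
  percent contrasts stay below 1%). Low-passing first would replace the
  noise-dominated increments with slow-fluctuation amplitude and inflate
  the contrast by an order of magnitude, collapsing line length into a
  redundant variance measure.

Contrasts against the x₀ = −2.25 baseline are percent changes of epoch
means, with percentile-bootstrap 95% CIs (5000 resamples, unpaired —
epochs are independent across runs). Expected directions: every signature
decreases with lowered excitability and increases with raised
excitability. Magnitudes depend on the integration scheme: the closer the
condition sits to the fold, the more the fluctuation statistics are shaped
by the nonlinearity of the basin, and discretization bias at coarse steps
systematically damps the skewness and autocorrelation contrasts. The
values this package reports are the converged-SDE ones; the skewness
contrast of the raised-excitability condition in particular is both large
(≈ +45%) and heavy-tailed across seeds (bootstrap CI spanning tens of
points), which is genuine near-criticality behaviour, not estimator
failure.

## Synthetic recordings

The parametric generator emulates a 12-channel depth-electrode mouse
montage at 2000 Hz during stimulation sessions: per-channel AR(1)
background (lag-1 coefficient and amplitude ordered low < normal < high
across conditions), 50 Hz line noise, a biphasic damped evoked template
(two negative deflections over ~250 ms, the canonical evoked-potential
morphology) scaled by a logistic intensity map, per-channel weights and
propagation delays, a high-amplitude artifact confined to the [−2, +10] ms
peri-stimulus window (exactly the window preprocessing interpolates, so
artifact removal has a ground-truth test), and uniform 8–12 s
inter-stimulus intervals. Session defaults mirror a standard probing
protocol: 60 single pulses cycling through 12 intensity levels. An
alternative backend mixes the stochastic Epileptor proxy to channels
(weight + delay + independent noise), tying the synthetic network to the
model's physics.

What the generator does *not* contain: any biophysical forward model of
field potentials, 1/f background spectra, behavioural state changes,
electrode drift, or kindling. Passing tests on these data demonstrate that
the pipeline recovers known structure under realistic noise and ordering
assumptions — not that it would perform identically on real recordings.

## Preprocessing

Bipolar derivation subtracts neighbouring contacts within a lead (labels
"A1-A2"). Stimulation artifacts are interpolated in the [−2, +10] ms
window by a line between the boundary samples plus Gaussian noise with the
SD of the preceding 50 ms (seeded; overlapping windows merge). Filters are
4th-order Butterworth applied forward–backward (zero-phase) with
second-order IIR notches (Q = 30) at 50 Hz and all harmonics below the
high cutoff; profiles: human 0.5–200 Hz + resample to 500 Hz (polyphase,
rational ratio), mouse 0.5–800 Hz, no resampling. Filter family and order
are this package's choices — only "bandpass" and "notch" are standard
here, and Butterworth/zero-phase is the conventional reading. The
idempotence guarantee (second pass changes RMS < 1%) holds for signal away
from the band edges and outside the notch shoulders.

An automated screen replaces visual artifact checking of high-amplitude
trials: within each session × intensity group, trials whose response line
length exceeds median + 5·MAD are dropped. Deterministic, and conservative
at typical trial counts.

## Input–output curves and bootstrap

Responses are grouped by intensity, averaged, baseline-subtracted (the
line-length floor of unstimulated signal — without this a no-response
session would score IOC ≈ 1 instead of 0), normalized to a reference (own
maximum by default; a cross-session reference for condition comparisons),
and integrated by trapezoid over the intensity axis rescaled to [0, 1].
Rheobase is the smallest intensity whose mean response exceeds baseline
mean + 2 SD (the detectability rule is this package's choice). Bootstrap
contrasts are percentile CIs of mean differences (5000 resamples, paired
or unpaired), seeded; in rare heavily skewed small samples the percentile
interval can exclude the plug-in point estimate, in which case the
distribution median is reported as the point estimate.

## Network NMF

Trial responses (per-channel 250 ms line length) stack into V (channels ×
stimulations), factorized by Lee–Seung multiplicative updates for the
Frobenius objective (max 1000 iterations, relative tolerance 10⁻⁶, best of
20 seeded restarts, monotone per-iteration error recorded). W columns are
normalized to unit sum so H carries amplitude; dead channels are removed
before and reinstated as zero weights after. Rank selection runs restarts
per candidate rank and scores the cosine similarity of the *worst*
optimally matched W column across restart pairs; the selected rank is the
largest with score > 0.9. The worst-column statistic is deliberate: mean
similarity stays deceptively high past the true rank for sparse
nonnegative structure, while the surplus noise-fitting column varies
across restarts and drags the minimum down sharply. Components whose mean
activation increases with intensity (one-sided Spearman, α = 0.05) are the
responsive sub-networks; their mean H per intensity feeds the same IOC
machinery as channel-level curves. For single-site rodent-style data a
rank of 1 is configured directly.

## Decoding

Three multinomial logistic-regression classifiers (L2, C = 1.0, features
z-scored within training folds): *active* (raw concatenated multi-channel
voltage of the 250 ms post-pulse window), *passive* (four signatures per
channel plus mean spatial correlation of a 4 s pre-pulse epoch), and
*combined*. Cross-validation is stratified by class and grouped by session
(no session straddles folds — the conservative choice against within-
session leakage; a flag restores plain stratified folds). The permutation
null relabels whole sessions (respecting the grouping), repeats the full
CV per permutation, and reports p = (C+1)/(n_perm+1). Time-resolved
decoding trains one classifier per peri-stimulus sample with a per-
timepoint permutation chance band. Multiclass accuracy is the fraction of
correctly labelled test trials, i.e. the micro-average of the one-vs-rest
confusion counts.

## Scaling and seeds

Every experiment derives per-stage seeds from one master seed via
CRC32-keyed SeedSequences, so any stage reruns bit-identically in
isolation. The `scale` knob shrinks epoch counts and permutation counts —
never model parameters — so scaled runs stay faithful in expectation with
wider intervals. Default problem sizes (790 epochs × 3 conditions for the
signature experiment; 5 × 3 sessions for decoding rehearsals) run in about
one and two minutes respectively on a single CPU.

## Known limitations

* Single-node model: no coupling of multiple Epileptors; multi-channel
  structure comes from the synthetic mixing stage only.
* Line-length contrasts of simulated (diffusion) signal depend on the
  sampling resolution by construction; values are comparable only at a
  stated resolution.
* The skewness/autocorrelation contrast magnitudes depend on the SDE
  discretization; this package reports converged values and documents the
  sensitivity rather than matching any particular coarser scheme.
* EDF files can be read (via mne) but not written in this environment; the
  native session format is CSV + events CSV + JSON sidecar.
* The rank-stability criterion and threshold, the rheobase detectability
  rule, and the artifact screen are this package's surrogates for
  procedures that are conventionally manual or under-specified.
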