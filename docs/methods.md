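# Methods

This note documents the models implemented in `smtrace`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that make the analysis
deterministic and testable.

## Signal model and units

Intensities are in camera arbitrary units (A.U.).  One eGFP contributes
`unit_intensity` = 80 A.U.; traces destined for step analysis are divided
by `scale` = 800 A.U. (ten eGFP units) so one bound probe spans 0.1
scaled units.  Frames are `frame_interval` = 0.1 s apart.  Readout noise
is Gaussian with `noise_sd` = 20 A.U. by default, i.e. a
single-fluorophore SNR of 4; the true single-eGFP SNR and camera gain of
the instrument class being emulated are not published, so these defaults
are package choices, fixed once.  No EMCCD gain, drift or stage jitter is
modelled (rendered movies are pixel-integrated Gaussian PSFs plus
Gaussian noise).

## Synthetic data (`simkit`)

All stochastic processes run through one `numpy` generator seeded per
call; continuous-time events are drawn Gillespie-style (exponential
waiting times between state changes) and then point-sampled onto the
frame grid.  Identical configuration including the seed reproduces
bit-identical output.

- **Photobleaching.** Each fluorophore bleaches at an independent
  exponential time (default rate 0.1 s⁻¹); a noiseless trace is a
  non-increasing staircase with exactly `n_fluors` steps of
  `unit_intensity`.
- **Effector binding.** Each of `n_sites` (default 7, the PI3K-binding
  sites of a HER2–HER3 dimer: five on HER3, two on HER2) binds/releases a
  probe at per-site rates; when `phospho_gated`, binding requires the
  site's pTyr telegraph state to be on, and dephosphorylation ejects a
  bound probe immediately — the simplest model consistent with SH2–pTyr
  dependence.  Probe photobleaching empties a site without a binding
  event.
- **Telegraph pTyr dynamics.** A two-state Markov chain with generation
  rate `k_gen` and removal rate `k_rem` (defaults 0.8 and 0.58 s⁻¹, the
  equilibrium reached under saturating phosphatase); paths start in the
  off state; the stationary on-fraction is k_gen/(k_gen+k_rem).
- **FRET emission.** The donor leakage factor β (default 0.12) is defined
  operationally, as the acceptor-channel signal per unit *detected* donor
  signal on a donor-only molecule — exactly how β is measured in
  practice.  Leaked photons therefore come out of the donor channel:
  ideal detected intensities at true efficiency E are
  I_d = T(1−E)/(1+β) and I_a = T(E+β)/(1+β), with total T conserved.
  Two consequences fall out by construction: a zero-FRET molecule reads
  an apparent efficiency of β/(1+β) ≈ 0.107, and the standard correction
  (I_a − βI_d)/(I_d + I_a) returns E exactly in the noiseless limit
  (machine precision; this is a tested invariant).  Efficiency states
  switch as a continuous-time Markov chain started from its stationary
  distribution; donor bleaching zeroes both channels, a dark acceptor
  (bleach or blink) reverts the molecule to the zero-transfer signature.
  The first 15 frames are direct acceptor excitation (presence check).
- **Progress curves.** The per-site phosphorylation rate at [ATP] = S is
  k = k_cat,max·S/(K_M+S); the observed count at time t is
  Binomial(n_molecules, λ(1 − e^(−kt))) with labelling efficiency λ.
  Binomial, not Poisson: the number of surface molecules per field is
  fixed, so counts saturate.
- **Inhibition series.** Inhibitor occupancy is
  θ(c) = c^h/(c^h + IC50_intrinsic^h).  With phosphatase present
  (scale s > 0) the observable is the telegraph steady state
  f(c) = k_p(1−θ)/(k_p(1−θ) + s·k_dp); at s = 0 that steady state is
  saturated and carries no information, so the observable is the
  phosphorylation rate itself, k_p(1−θ) — the progress-slope readout of a
  phosphatase-free assay.  Activity is reported as 100·g(c)/g(0) with
  multiplicative Gaussian noise.  Solving f(c) = f(0)/2 gives the
  effective half-inhibition point in closed form,
  c_½ = IC50_intrinsic·((1+a)/a)^{1/h} with a = s·k_dp/k_p: strictly
  decreasing in phosphatase activity and divergent as s → 0 — a fast
  kinase under a slow phosphatase hides inhibition, which is the
  mechanism by which a high catalytic rate confers inhibitor resistance.

What the generator does **not** emulate: spectral cross-talk beyond the
single leakage term, direct acceptor excitation under donor illumination,
detection-efficiency (γ) asymmetry, dye photophysics beyond exponential
bleaching/blinking, diffusing background, camera gain statistics, focus
or stage drift, and inter-molecular aggregation.  Passing tests therefore
certify the estimators against the stated stochastic models, not against
every artefact of real recordings.

## Imaging

Background is removed per frame by subtracting the 6×6 boxcar mean; the
even kernel is anchored so its window spans rows r−3…r+2 (top-left at
(r−3, c−3)), with reflected edges — a documented convention instead of an
ambiguous centring.  Detection operates on the mean of the first 10
frames; spots are strict local maxima above `min_peak` (default: 5× the
MAD-based noise SD of the detection image), maxima closer than 3 px merge
keeping the brighter (ties to the smaller row, then column), and 3×3
windows that would leave the frame are discarded.  Traces are plain 3×3
sums; with a σ = 1 px PSF the window captures erf(1.5/√2)² ≈ 75.1% of a
spot's photons, a constant factor that cancels in step analysis.
Two-colour registration and time-gated appearance detection are out of
scope.

## Step analysis

`fit_levels` with free levels solves the change-point segmentation model
exactly: piecewise-constant means, Gaussian noise with one shared
variance per trace, minimum segment length 2 frames, optimum over all
change-point placements found by dynamic programming in O(k·n²).  For
traces that revisit levels (recurrent binding), level positions are first
calibrated from the brightest spots and then held fixed while each
trace's path is decoded by a Viterbi-style dynamic program with the same
minimum run length — the standard two-stage treatment for heterogeneous
single-molecule data, and the reason `StepFit.levels_free` exists.

Model size is chosen by BIC, with
BIC = −2 log L + (levels + 1 + change points)·ln(n) and the number of
states read off the knee of the BIC-versus-k curve: all two-segment
continuous piecewise-linear fits with integer breakpoints are scored by
least squares and the best breakpoint taken.  Two deterministic guards
complete the rule: the selected count is the smallest k at or below the
knee whose BIC does not exceed the knee's (so monotone-increasing curves
select k = 1), and if the knee's model is worse than the best candidate
by more than 10·ln(n) — the signature of a near-zero-residual cliff that
no two-segment line can follow — selection falls through to the smallest
candidate within 10·ln(n) of the best.  A variance floor of 1e-12 keeps
noiseless traces finite.  Ties everywhere go to the smaller model.

Bleach steps are transitions of the fitted path that land on a strictly
lower level.  A state must persist ≥ 3 consecutive frames to count as
visited (`count_max_bound`), a noise-spike guard standing in for the
manual blink curation of interactive analyses.  Level calibration pools
plateau means (≥ 3 frames) across the brightest traces and clusters them
by exact weighted 1-D k-means; a plateau of length w is modelled as
Gaussian around its level with variance σ²/w + τ², where τ = σ/4 absorbs
molecule-to-molecule variation of level positions, so long plateaus
cannot spawn spurious levels from small between-trace offsets.  The
cluster count minimises the resulting χ² deviance plus L·ln(#plateaus).

Dwell gaps (`extract_dwell_gaps`) measure, per trace, the time from the
first binding event to each subsequent binding event (one gap per probe
gained), stopping once occupancy has returned permanently to zero.

## FRET analysis

Apparent efficiency is I_a/(I_d+I_a); the corrected efficiency subtracts
donor leakage from the numerator only, matching the measurement
convention above.  Frames with non-positive total are undefined and
dropped.  Donor-bleached frames are excluded per trace: frames after the
last frame whose summed intensity exceeds background + 3× the MAD-based
noise SD.  Trace exclusion applies, in order: (a) no acceptor in the
direct-excitation check block (mean below 50 A.U. by default) or no
donor-excitation signal; (b) median summed intensity below 100 A.U.
(the threshold is unpublished for the reference instrument, so it is an
exposed parameter); (c) a stoichiometry proxy — check-block acceptor
intensity over (check-block + donor-excitation median) — outside
[0.3, 0.7], flagging spots without a 1:1 dye pair; (d) traces whose
apparent efficiency never exceeds 0.4, which are leakage-level traces of
inactive complexes.  Relaxing any single threshold can only grow the
kept set (tested monotonicity).

Framewise efficiencies of all kept traces pool into a histogram of 50
uniform bins on [−0.2, 1.2], normalised by the total frame count; the
low-E fraction at the 0.5 threshold is computed from raw frame values,
not binned mass, to avoid bin-edge artefacts.  An automated blink mask
(acceptor at leakage level while the donor stays bright, for runs of ≤ 5
frames) is available but off by default: with well-separated states it
can swallow genuine short low-E dwells, and the bundled schemes do not
simulate blinking.  No γ correction, no direct-excitation correction,
and no distance conversion (the Förster radius of the label pair is not
established).

## Kinetic fitters

All fitters are deterministic given data and options, use analytic
initial guesses, and recover noiseless model-generated data to at least
six significant digits (tested).

- **Progress curves**: weighted least squares for N_max(1 − e^(−kt)),
  weights from the binomial counting variance count·(1 − count/n) when
  the molecule number is known (Poisson-style 1/max(count, 1) otherwise).
  All-equal or fully saturated curves raise a fit failure rather than
  returning an unbounded rate.  The catalytic rate is defined as the
  exponential rate constant k — consistent with normalising curves by the
  extrapolated exponential maximum.
- **Michaelis–Menten**: nonlinear least squares with double-reciprocal
  initial guesses; when per-rate standard errors from the progress fits
  are supplied the fit is inverse-variance weighted.  This matters for
  K_M: rate errors grow roughly in proportion to the rate, and an
  unweighted fit lets the saturated high-[ATP] points dominate the
  half-saturation region (measured K_M RMSE halves under weighting).
- **Exponential dwells**: MLE rate 1/mean with the exact chi-square
  (gamma) confidence interval; requires ≥ 10 dwells; censored first/last
  dwells of each path are always discarded, with no survival correction.
- **Telegraph rates**: dwells split by state; the reciprocal-mean rates
  are then mapped through the exact transition probabilities of the
  grid-sampled two-state chain (per-frame switch probabilities
  p = dt/mean dwell, λ = −ln(1 − p01 − p10)/dt, rates λ·p/(p01+p10)).
  Without this inversion, frame quantisation biases both rates down by
  ≈ (k_gen+k_rem)·dt/2 — about 7% at the default rates and 0.1 s frames,
  most of a 10% accuracy budget.  `correct_discretization=False` gives
  the plain reciprocal-mean convention.
- **Dose–response**: four-parameter logistic with the Hill coefficient
  fixed at 1 unless freed; unweighted (replicate scatter is homogeneous
  on the percent scale at the simulated 5% CV).
- **Geometry**: the characteristic spacing of n spots in area A is
  √(A/n); 1000 spots in 40×80 μm² gives 1.79 μm, the sparsity regime in
  which one antibody captures one complex.

Each pTyr species is fitted independently; no global multi-site kinetic
model is attempted.

## Bundled studies and problem sizes

`smtrace.studies` fixes the reference conditions used for end-to-end
validation: Michaelis–Menten recovery from 7 [ATP] values × 8 time
points × 500 molecules at labelling efficiency 0.8 (heterodimer ground
truth K_M = 29.2 μM, k_cat,max = 0.22 s⁻¹; ligand-free 16.46 μM and
1.4×10⁻³ s⁻¹, with the time grid stretched 150-fold to match the slower
kinetics); telegraph recovery from 200 trajectories of 300 s at 0.1 s
sampling; IC50 recovery from a half-log 0.01–100 μM series with 10
replicates and 5% multiplicative noise (ground truths 6 μM and 0.7 μM);
single-step classification over 500 single-eGFP traces of 600 frames;
and a 300-trace FRET study at E = 0.2/0.8 with switching rates summing
to 1 s⁻¹ split for 35% stationary low-E occupancy.  The FRET noise of
42 A.U. per channel on a 500 A.U. pair follows from requiring an
efficiency SD of ≈ 0.07 via SD(E) ≈ σ√(E²+(1−E)²)/T; donor bleaching at
0.008 s⁻¹ is included because frame-wise exclusion makes it unbiased,
while acceptor bleaching is left out of this scheme — without the manual
segment curation used in interactive analyses it would masquerade as
extra low-E occupancy.  These sizes keep every study in the seconds
range while holding estimator errors to a few percent.

## Known limitations

- The free-level fitter counts segments, not reused levels; BIC state
  counts for strongly revisiting traces are meaningful only after level
  calibration (the fixed-level path decode).
- The segmentation cost matrix is O(n²) memory; traces beyond a few
  thousand frames should go through the fixed-level decoder.
- The blink mask cannot distinguish a true E≈0 dwell from an acceptor
  dark state — that ambiguity is physical, which is why the mask is
  opt-in.
- Dwell-based telegraph estimation discards censored dwells; for very
  short trajectories (few dwells per path) this loses real information
  and a trajectory-likelihood estimator would be preferable.
- The competition model treats inhibitor binding as quasi-static
  occupancy; no kinetic competition between inhibitor on/off rates and
  catalysis is modelled, so the dose–response shift with phosphatase
  activity is reproduced in direction and form but not calibrated to any
  particular phosphatase preparation.
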