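# Methods

`pulsereplay` is a fully software-simulated record-and-replay pipeline for
radial-pulse tactile waveforms. It stands in for a physical system made of a
PVDF-film pulse recorder and a piezoelectric-bender pulse player, and asks the
question such a system has to answer: given a recorded pulse and the palpation
force it was taken under, what driving voltage reproduces the felt waveform,
and how faithful is the reproduction?

## Signal chain

All signals are uniformly sampled (`Signal`: samples, rate, unit tag).
Displacement is in arbitrary units (a.u.); the fidelity metrics are
scale-free, so no absolute calibration is needed.

1. **Pulse synthesis** (`pulse_synth`). One beat is a baseline plus three
   raised-cosine bumps — percussion wave (largest, earliest), tidal wave,
   dicrotic bump — at phase offsets 0.15 / 0.40 / 0.62 of the beat with
   half-widths 0.11 / 0.16 / 0.10. Beats are laid end to end with a jittered
   period (CV 2% by default); white Gaussian noise is added in displacement.
   Force-regime presets follow clinical palpation practice: light pulses are
   faint and noisy (amplitude 0.4, noise sd 5% of the percussion amplitude),
   moderate 1.0 / 2%, heavy 1.3 / 1%. Heart rate is confined to the
   physiologic 0.6–2 Hz band.
2. **Recording** (`sensor_sim.pvdf_record`). A PVDF film outputs voltage
   proportional to strain *rate*; the simulated recorder differentiates
   (first difference × fs, front-padded) with optional white voltage noise.
   Acquisition is always at 1 kHz.
3. **Working-rate conversion**. A non-overlapping mean filter decimates
   1 kHz → 250 Hz (8 s → exactly 2000 points); cumulative trapezoidal
   integration recovers the displacement waveform. The 8-s acquisition is
   linearly detrended — integration of voltage noise is a random walk, and
   any slow trend belongs to the decomposition residue anyway.
4. **Decomposition** (`emd`). From-scratch empirical mode decomposition:
   cubic-spline envelopes through the local maxima/minima (strict
   sign-change extrema, plateau midpoints; the two extrema nearest each end
   mirrored about the record endpoints), sifting h ← h − (upper+lower)/2.
   Sifting stops when the Cauchy-type criterion
   SD = Σ(h_prev − h)² / Σ h_prev² falls below 0.1 **and** the candidate
   satisfies the two IMF conditions (extrema vs. zero-crossing counts differ
   by ≤ 1; boundary-excluded envelope mean ≤ 5% of amplitude), capped at 50
   iterations. The SD rule alone can stop after one or two passes on noisy
   data while the candidate is still far from a mode; requiring both
   conditions is standard sifting practice and costs little. IMFs are peeled
   off until the residue has fewer than two maxima or two minima (the robust
   reading of "monotonic") or seven IMFs exist. The decomposition telescopes,
   so IMFs + residue reconstruct the input to float accuracy.
5. **Normalization and weights**. Each IMF is scaled to unit max-abs; the
   scales are retained and recombination uses them, which restores the sum
   of the raw IMFs exactly. Per-IMF energies (sum of squares, normalized to
   sum 1) are computed as the energy-intensity ranking; they are reported
   and used diagnostically, but amplitude restoration during recombination
   uses the normalization scales — an energy-proportional weighting cannot
   reproduce the original amplitude and would break the recombination
   identity the pipeline is verified against.
6. **Plant** (`plant_sim`). The bender stack is a configurable
   voltage→displacement map: drive clipped to ±48 V, memoryless core
   y = g·(v + c·v³/v_limit²), gain attenuated by (1 − 0.08·force[N]),
   optional rate-lag hysteresis and output noise. Defaults: g = 0.04 a.u./V
   and c = 1.0. The real device's transfer characteristics are not
   published, so the plant is synthetic by construction; c = 1.0 places it
   in the regime the method exists for — nonlinear enough that a straight
   linear drive model visibly mis-reproduces waveforms while a learned
   pointwise inverse does not. (With c ≲ 0.3 the plant is so nearly linear
   that the linear baseline matches the noise-limited ANN and the
   comparison degenerates.) The default plant is memoryless because a
   pointwise sample-to-sample inverse can only invert a memoryless map;
   hysteresis mode exists to probe that limit, not for the benchmark.
7. **Inverse models** (`inverse_model`). Per force range, T(P) = U maps one
   displacement sample to one driving-voltage sample. The baseline is a
   least-squares line. The learned model is a 1-10-1 multilayer perceptron:
   logistic-sigmoid hidden layer, tanh output, inputs affinely scaled to
   [0.05, 0.95] and outputs to [−0.9, 0.9] to keep activations off their
   saturated tails. Training data: each recorded training pulse is
   decomposed, its normalized IMFs are driven at 40 V full scale through
   the plant (upsampled to 1 kHz, as the player runs), the response is
   re-recorded at 1 kHz, mean-filtered to 250 Hz and integrated —
   the integral (mean-centred; DC is unobservable through a rate sensor)
   is the model input P, the 250 Hz driving signal the target U. The IMF
   bank is padded to exactly seven series per pulse; a padded slot drives
   nothing and contributes exact rest-state (0, 0) pairs, so ten training
   pulses yield exactly 70 series = 140,000 pairs per force range.
8. **Reproduction** (`reproduce`). A held-out recording is processed through
   steps 3–5, each normalized IMF is mapped through the force range's
   inverse model, the per-IMF drives are recombined with the amplitude
   scales, clipped, upsampled to 1 kHz (linear interpolation), played
   through the plant and re-recorded; the integral of the re-recording
   (processed exactly like an acquisition) is the replayed waveform.
   The residue is never driven — it is the waveform's slow trend — so
   verification compares the replayed waveform against the residue-removed
   original on the 250 Hz grid, after removing the unobservable constant
   offset. Fidelity is NRMSE = RMSE / (max − min of the original) and the
   coefficient of determination R² = 1 − SS_res/SS_tot (squared-correlation
   variant available behind a flag).

## Training configurations

`TrainConfig` defaults follow the classic recipe: mini-batch (64) gradient
descent at a constant learning rate of 0.8 for 10⁴ epochs, seeded
uniform(±0.5) initialization. That recipe is faithful but fragile: from an
unlucky initialization the constant-rate descent stalls on a plateau at
roughly twice the converged loss and the resulting inverse is visibly wrong.
`FAST_TRAIN` — used by the benchmark and the tests — therefore optimizes the
same back-propagated gradients with full-batch L-BFGS (≤ 500 iterations) on a
12,000-pair subsample, from a Nguyen-Widrow-style initialization (sigmoid
transition centers spread across the scaled input range, alternating slope
signs), with five seeded restarts keeping the lowest final training loss.
This is deterministic for a fixed seed and converges the tiny network to its
loss floor in about a second per force range.

## The benchmark

`benchmark.run_benchmark` freezes the study conditions: representative
forces 0.5 / 1.2 / 1.8 N for the light / moderate / heavy ranges; ten 8-s
training pulse sets and eight held-out verification sets per range (subject
variation: heart rate uniform in 0.9–1.4 Hz, amplitude ±10%); recorder noise
equal to 2% of the peak voltage of a noiseless reference moderate-force
recording (the same noise fraction the cam-verification protocol uses), one
fixed value for all regimes — so light-force recordings have the worst
signal-to-noise ratio, as they should. One linear and/or one ANN model is
trained per force range and verified through the full replay chain; the two
model families are compared per force range and pooled with independent
two-sample t-tests (pooled variance by default, Welch behind a flag) at
α = 0.05.

`scripts/acceptance.py` recomputes, from scratch at a given seed: the two
design-score worked examples, the cam protocol's mean NRMSE and R² over ten
repeats, and the benchmark's 24-trial average NRMSE and R² for the ANN.

## What the synthetic data does and does not show

The generator reproduces the morphological and protocol-level features the
pipeline depends on: three features per beat above a baseline, beat-rate and
amplitude variation, force-dependent amplitude/noise, the acquisition rates
and record lengths, and a rate-sensing recorder. It does not model arterial
hemodynamics, sensor-skin contact mechanics, amplifier electronics, or
non-Gaussian artifacts; the plant is a parametric stand-in, not a fitted
device model. Two consequences worth knowing:

- EMD of our noisy synthetic waveforms places negligible energy in the
  leading (noise) IMF and spreads pulse energy over IMFs 2–5, whereas real
  wrist recordings concentrate the most energy in the first three IMFs; the
  energy-concentration property is therefore asserted on noiseless pulses.
- The simulated chain is cleaner than hardware: the cam-protocol and
  replay fidelities it achieves are comfortably better than a physical
  recorder/player pair would show. Bounds passed here demonstrate the
  pipeline's correctness and the method's behavior, not hardware
  performance.

## Numerical choices and degenerate inputs

- Derivative: first difference × fs (front-padded); integral: cumulative
  trapezoid starting at 0. Their composition is the identity up to a
  half-sample smoothing, an O(1/fs) error that is negligible at 1 kHz and
  ~1% of range at 250 Hz — one reason recording always happens at 1 kHz.
- Detrending policy: only the 8-s waveform acquisition is detrended. A
  linear detrend applied to a series with one or two cycles per record
  (slow IMFs, the 1-s cam profile) removes signal, not drift.
- Constant signals decompose to zero IMFs with the input as residue;
  all-zero IMFs keep scale and weight 0; a constant training input or a
  constant original waveform raises an error rather than dividing by zero.
- Upsampling is linear interpolation; mean-filter windows are
  non-overlapping and aligned to sample 0 (8 s at 1 kHz → exactly 2000
  points at 250 Hz).
- Every stochastic step (pulse synthesis, sensor noise, subsampling,
  initialization, restarts) draws from seeded generators spawned from a
  single run seed.

## Known limitations

- The pointwise inverse cannot represent a hysteretic plant; enabling
  `hysteresis_strength` degrades reproduction by design.
- Per-IMF inversion does not commute with recombination through a nonlinear
  plant; even a perfect inverse leaves a small cross-term error (~1% NRMSE
  at the default plant). This is inherent to the per-IMF architecture.
- The classic constant-rate SGD configuration is kept as the default for
  fidelity to standard practice but is not robust; use the L-BFGS path for
  anything quantitative.
- Recorder noise enters the training inputs as an integrated random walk,
  which bounds the achievable inverse accuracy (errors-in-variables); the
  benchmark's ANN error floor is set by this, not by network capacity.
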