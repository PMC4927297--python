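# Methods

## The measurement problem

At a giant glutamatergic presynaptic terminal, two complementary reporters
track the vesicle cycle after a depolarizing stimulus:

* **Membrane capacitance (Cm)** is an electrical proxy for plasma-membrane
  area.  Exocytosis adds membrane in step-like jumps; endocytosis removes it
  as a slow recovery decay.
* **A pH-sensitive reporter** (a cyanine dye coupled to an antibody against
  the luminal domain of synaptotagmin 2) is fluorescent in the acidic
  vesicle lumen (~pH 5.5) and quenched at the neutral extracellular pH
  (~7.4).  Exocytosis quenches it; it de-quenches only after the organelle
  that retrieved it has re-acidified.

The fluorescence therefore lags the capacitance by the organelle
re-acidification kinetics.  The core computation of this package extracts
that lag — an onset delay and an exponential re-acidification time constant
— by fitting a convolution of the measured membrane retrieval time course
with a per-organelle de-quench kernel.

## Forward model

All traces use t = 0 at the offset of the last stimulus pulse; the recovery
analyses concern the limb t >= 0.

**Capacitance.**  Each pulse adds `jump_total_pF * w_i` on top of the
baseline.  The recoverable part of the total jump (fraction `1 - p`, with
`p` the plateau) decays as a mixture of exponentials:

    C_norm(t) = p + (1 - p) * sum_i a_i * exp(-t / tau_i)

with the amplitude fractions `a_i` defined on the *recoverable* decay (they
sum to 1).  By default (`endo_onset="train_end"`) retrieval of the whole
train's membrane starts at the last pulse offset: over the 2.3-s train this
is the simplest model consistent with a summed jump equal to the per-pulse
increments and with an exactly bi-exponential recovery limb, and it can be
read as stimulation-suppressed endocytosis.  A `per_pulse` switch instead
superposes an independent recovery from each pulse's offset; the
long-interval four-pulse depression preset uses it, because retrieval
between 20-s-spaced pulses cannot plausibly be suspended.

**Titration mapping.**  Reporter fluorescence versus pH follows a
Henderson–Hasselbalch curve with the acid form fluorescent,
`phi(pH) = 1/(1 + 10**(hill*(pH - pKa)))`, with pKa 7.05 and Hill
coefficient 1 (the published calibration for this dye).

**Re-acidification kernel.**  An organelle retrieved `s` seconds ago is
held at surface pH during an onset delay `d`, after which its lumen pH
relaxes exponentially from 7.4 to 5.5 with time constant `tau_acid`:

    g(s) = (phi(pH(s)) - phi(7.4)) / (phi(5.5) - phi(7.4)),  g(s < d) = 0.

The phi-difference denominator pins the kernel endpoints at exactly 0 and 1
regardless of pKa (matching fluorescence normalized to its own stimulus
deltaF), so pKa shapes only the curvature.

**Quench trace.**  With `e(t) = -dC_norm/dt` the normalized endocytic flux,

    Q(t) = 1 - integral_0^t e(t') g(t - t') dt'

for the fully co-retrieved case; a stranding fraction `f` (reporter left on
the surface despite normal membrane retrieval) rescales this to
`Q = f + (1 - f) * Q_co`.  A re-acidification block sets the kernel to zero
(Q stays at 1), as does an infinite delay.  Raw fluorescence is emitted as
`F(t) = (1 - dF/F * U(t)) * bleach(t) + noise`, where `U` is the
unacidified exposed fraction, at the 0.5-Hz imaging rate.

**Delay semantics.**  The delay is applied per organelle by default (each
organelle's clock starts at its own retrieval).  Because the published
fitting procedure for this preparation is also describable as "hold the
curve at 1, then convolve", a `global_delay` mode is provided that holds
Q = 1 until `d` after stimulus end and convolves with the delay-free
kernel.  The two modes coincide exactly when all endocytosis occurs at one
instant, and differ little for the presets here; fits in both modes
recover the same parameters on the bundled presets.

**Acid puffs.**  A brief extracellular pH-5.5 application de-quenches only
surface-exposed reporter.  The transient amplitude is the surface pool
(pre-existing stranded reporter plus exposed-but-unretrieved reporter)
times the titration contrast `(phi(pH_puff) - phi(7.4))/(phi(5.5) -
phi(7.4))`, so a pH-5.5 puff reads the surface pool in stimulus-deltaF
units directly.  Puff amplitudes are measured as peak minus the mean of the
three pre-onset samples: a 5-s puff at 0.5 Hz spans only 2–3 samples, so a
plateau average is not available.

## Fitting stack

**Jump measurement.**  Per-pulse jumps are post-window minus pre-window
estimates (defaults: 50 ms pre-onset, 50–150 ms post-offset).  The
post-window samples are back-extrapolated linearly to the pulse offset;
without this, decay already under way inside the window biases the summed
train jump by about 0.7 %.  The same back-extrapolation anchors the
jump normalization of the recovery limb.

**Capacitance recovery.**  Nonlinear least squares
(`scipy.optimize.least_squares`) of the plateau + exponential-mixture
model, multistarted from a 5x5 logarithmic grid of time-constant pairs in
[0.5, 500] s.  Components are reported fast-first; time constants pinned at
the search bounds, and fast/slow pairs within 5 % of each other
(an effectively mono-exponential solution), are flagged rather than
rejected.  The trace is renormalized internally to its value at the fit
start, making the fit scale-equivariant.

**Convolution fit.**  The flux convolution is evaluated through integration
by parts,

    absorbed(t) = integral_0^t (1 - C(t - u)) dg(u),

which eliminates numerical differentiation of the capacitance trace: `C` is
represented by 2-s bin averages made monotone by isotonic regression
(imaging-rate noise would otherwise dominate), anchored at (0, 1), and the
kernel increment `dg` is evaluated analytically on a 0.05-s grid.  The
(delay, tau) surface is scanned exhaustively (delay 0–40 s in 1-s steps,
tau 5–200 s in 40 log-spaced steps), then refined by Nelder–Mead in
(delay, log tau) from the grid minimum — delay and tau trade off along a
diagonal sse valley, so coordinate-wise refinement would stall.  The full
sse surface is retained; a minimum on the grid boundary, or a surface with
no usable relief (e.g. under re-acidification block), sets a flag instead
of silently returning numbers.

**Delayed single exponential.**  For long recordings the quench recovery is
also summarized by `Q = A + (1 - A) * min(1, exp(-(t - d)/tau))`: the delay
is scanned over the sample grid with a continuous bounded refinement, and
(A, tau) are fitted per candidate delay.  The asymptote can be fixed or
free; free by default, since the published long-recording fit does not
state which was used and the noise-free forward model constrains it anyway.

**Bleach correction.**  A line or single exponential is fitted to the
normalized trace of an unstimulated neighbor terminal and subtracted
(minus its value at the trace start) from the target; `auto` picks the
model with the lower sse.  Subtraction (rather than division) mirrors the
published procedure; it is exact for the constant part of the signal and
first-order for the deflection.

**Statistics.**  Group values aggregate as mean ± SEM (n-1 denominator).
The two-sided Student's t test uses pooled variance by default (Welch
behind a flag), matching the source analysis; no multiple-testing
correction is applied because none was used there.

## Scenario presets and calibrations

Measured constants (rat train preset): baseline 18.87 pF, summed jump
1.52 pF over ten 50-ms pulses, recovery taus 5.2 s (37 %) and 66.5 s
(63 %) with plateau 0.12, re-acidification delay 14 s with tau 38.7 s,
pre-stimulus stranded surface pool 0.48 of stimulus deltaF.

Where the underlying kinetics were not reported, preset values are
calibrations to printed endpoints, and say so in their docstrings:

* dynamin block — only the fast component survives; retrieved fraction
  0.39 calibrated to the 60-s capacitance endpoint 0.61;
* mouse wild type — mono-exponential tau 25 s, plateau 0.10, calibrated to
  the 56-s endpoint 0.20; delay 12 s and tau 18.9 s are printed values;
* stranding scenarios (calmodulin peptide, Munc13-1 W464R) — stranding
  fraction 0.5 with unchanged membrane kinetics, calibrated to the printed
  60-s fluorescence endpoints (0.74 / 0.72);
* 2-s bulk preset — mono-exponential membrane retrieval tau 3 s; the
  endosome re-acidification tau is set to 300 s (delay 14 s), which
  reproduces both the printed 40-s quench endpoint (model 0.89 vs
  0.93 ± 0.07) and the printed 190-s endpoint (model 0.33 vs 0.36 ± 0.08).
  A faster calibration (tau ~150 s) fails the 40-s endpoint and was
  rejected.

Default measurement layer: imaging 0.5 Hz, capacitance sampling 20 Hz
(chosen so 50-ms pulse edges fall on the grid), Gaussian noise sd 3 % of
the stimulus-evoked amplitude, no bleaching unless enabled, exposure-time
integration ignored (samples treated as instantaneous).  Every random
draw comes from a named stream derived from `(seed, crc32(stream name))`,
so adding a consumer never perturbs existing draws and identical seeds
give bit-identical traces.

## What the generator does and does not emulate

The generator reproduces the statistical structure the analysis assumes:
step exocytosis, exponential-mixture retrieval, delayed-exponential
re-acidification through the titration curve, additive Gaussian noise,
mono-exponential or linear bleaching, neighbor-ROI references, and acid
puffs.  It does not emulate capacitance undershoot after strong
stimulation, exposure-time integration of the camera, spontaneous
exocytosis (the observed >1 fluorescence endpoints under re-acidification
block are not modelled), movement artifacts, or heterogeneity across
organelles in delay or tau.  A green recovery test therefore establishes
that the fitting stack inverts the stated forward model — not that the
model is the only one compatible with real recordings.

Known quantitative departures of the stated world from printed group means,
kept deliberately (no preset was tuned to them): the forward-model quench
endpoint at 60 s is 0.54 (printed 0.47 ± 0.07, within about 1 SEM); the
dynamin-preset quench endpoint is 0.66 (printed 0.92 ± 0.10) because the
surviving fast retrieval still internalizes reporter under normal
re-acidification; the control post/pre puff ratio is ~1.9 (printed
1.15 ± 0.20), which follows necessarily from the printed stranded pool
(0.48) and the unretrieved membrane fraction at +40 s (~0.42) — the
phenotype ordering (stranding raises the ratio, bulk ~1) is what the
package asserts.

## Numerical choices

* Fine-grid forward integration at 0.02 s; flux cell masses are analytic
  and the kernel is evaluated at cell midpoints (second order), which keeps
  the deterministic model within Monte-Carlo error (3 SE at 1e5 organelles)
  of an event-based simulation on every preset.
* Convolution-fit discretization: 2-s capacitance bins, 0.05-s kernel
  grid; on noise-free presets the recovered parameters sit within 0.1 s /
  0.5 % of truth, well inside the 0.5 s / 2 % acceptance band.
* Interpolation of endpoints is nearest-two linear; times outside the span
  raise rather than extrapolate.
* Degenerate inputs (flat quench, no stimulus response, zero pre-puff
  pool, windows colliding with the next pulse) raise with specific
  messages or set flags; fits never silently return boundary solutions.

## Limitations

Single-compartment organelles with a shared (delay, tau); no
vesicle-budding or proton-buffering models of acidification; no raw-current
or sine-wave admittance processing (traces enter as given); no pixel-level
image analysis (ROI-mean traces only); capacitance undershoot and
excess retrieval are out of scope (`plateau_frac >= 0`).
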