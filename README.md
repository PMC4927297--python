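# calyxcycle

Joint kinetic analysis of presynaptic **membrane capacitance** and
**pH-sensitive reporter fluorescence** at a giant central synapse (calyx of
Held), for synaptic physiologists who need to separate three entangled
processes after a stimulus: membrane retrieval, vesicle-protein retrieval,
and re-acidification of the retrieved organelle.

Capacitance jumps report exocytosis and their decay reports endocytosis:

    C_norm(t) = p + (1 − p) · Σᵢ aᵢ · e^(−t/τᵢ),   Σᵢ aᵢ = 1

with plateau *p* (membrane not retrieved on the recording timescale) and a
fast/slow mixture of retrieval time constants.  The reporter (fluorescent at
vesicular pH 5.5, quenched at extracellular pH 7.4, titration
φ(pH) = 1/(1 + 10^(pH − pKa)), pKa 7.05) de-quenches only after the
retrieved organelle re-acidifies.  The package's core statistic is the pair
(d, τ_acid) — the re-acidification onset delay and time constant — obtained
by least-squares fitting of the convolution model

    Q(t) = 1 − ∫₀ᵗ e(t′) · g(t − t′) dt′,    e(t) = −dC_norm/dt,

where Q is the normalized inverted ("quench") fluorescence and
g(s) = (φ(pH(s)) − φ(7.4)) / (φ(5.5) − φ(7.4)) is the per-organelle
de-quench kernel, zero during the delay and following an exponential pH
relaxation afterwards.

Because raw recordings for this preparation are not publicly deposited, the
package pairs the fitting stack with a fully seeded forward generator
(`calyxcycle.simulate`) whose presets encode the published experimental
conditions — control trains, dynamin block, re-acidification block,
reporter stranding, bulk endocytosis after a 2-s pulse, mouse wild-type —
including imaging noise, photobleaching, neighbor-ROI references and
extracellular acid puffs that read out the surface reporter pool.

## Worked example

```python
import calyxcycle as cc

scn = cc.preset("rat_control", noise_sd=0.0)      # noise-free ground truth
cm  = cc.simulate_capacitance(scn)                # pF trace, 20 Hz
fluor, state_log = cc.simulate_reporter(scn, cm)  # imaging trace, 0.5 Hz

jumps = cc.measure_jumps(cm, scn.protocol)
print(f"summed jump {jumps.total_dCm_pF:.3f} pF")

cm_norm = cc.normalize_capacitance(cm)
fit = cc.fit_endocytosis(cm_norm, model="bi")
(a_f, tau_f), (a_s, tau_s) = fit.components
print(f"fast tau {tau_f:.1f} s ({a_f:.0%}), slow tau {tau_s:.1f} s, "
      f"plateau {fit.plateau:.2f}")

q = cc.normalize_invert(fluor)
res = cc.fit_reacidification(cm_norm, q.trace, mode="per_organelle")
print(f"re-acidification: delay {res.delay_s:.1f} s, tau {res.tau_acid_s:.1f} s")
```

prints

```
summed jump 1.520 pF
fast tau 5.2 s (37%), slow tau 66.5 s, plateau 0.12
re-acidification: delay 13.9 s, tau 38.7 s
```

i.e. ten 50-ms pulses add 1.52 pF of membrane; 37 % of the recoverable
membrane returns with τ = 5.2 s and 63 % with τ = 66.5 s, 12 % is not
retrieved within the recording; and the reporter fluorescence is explained
by organelles that stay at surface pH for ~14 s after retrieval and then
re-acidify with τ ≈ 39 s — the generating values, recovered from the traces
alone.

The same stages are available from a shell:

```bash
calyxcycle simulate --preset rat_control --seed 1 --out sim/
calyxcycle capfit   --in sim/capacitance.csv --model bi --out fit.json
calyxcycle fluorfit --in sim/fluorescence.csv --out qtrace.csv
calyxcycle reacidfit --cm sim/capacitance.csv --fluor qtrace.csv --out reacid.json
calyxcycle replica  --seed 1 --out replica/   # all presets, results.json + plots
```

## Acceptance script

`scripts/acceptance.py` regenerates the noise-free rat and mouse presets
from their stated constants and recomputes, from the simulated traces
alone: the summed per-pulse capacitance jump; the bi-exponential recovery
constants (fast/slow τ and fast fraction); and the convolution-model
re-acidification delay and time constant for both presets.

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/calyxcycle/scenarios.py` — protocols, parameter types, presets
- `src/calyxcycle/simulate.py` — seeded forward generator + acid puffs
- `src/calyxcycle/capacitance.py` — jump measurement, recovery fits
- `src/calyxcycle/fluorescence.py` — bleach correction, quench traces, puff metrics
- `src/calyxcycle/reacidification.py` — titration, kernel, convolution fit
- `src/calyxcycle/stats.py` — mean ± SEM, Student's t, depression ratios
- `src/calyxcycle/pipeline.py`, `cli.py` — end-to-end runner and CLI

`docs/methods.md` documents the model, its assumptions, calibrated preset
values, numerical choices, and what the synthetic tests do and do not
establish.
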