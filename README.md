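# photokinetics

Kinetic analysis of biphotochromic fluorescent proteins — proteins such
as the coral-derived SAASoti that both photoconvert irreversibly from a
green- to a red-emitting chromophore under violet (400 nm) light and
switch reversibly between a fluorescent *on* and a dark *off* state
under blue (470 nm) light.  The package is aimed at protein
spectroscopists characterising mutant panels: it turns raw
intensity-versus-time traces, emission spectra and pH titrations into
the rate constants, amplitude ratios, pK_a and brightness values that
make up a standard variant-comparison table.

## Models

At fixed irradiance every phototransformation here is effectively
first order, giving four closed-form signal models:

* **Green-to-red photoconversion** — a consecutive monomolecular process
  Green → Red → Bleached.  The red-channel fluorescence follows

  I(t) = I·k₁/(k₂−k₁)·(e^(−k₁t) − e^(−k₂t)) + c

  with k₁ the red-form formation rate, k₂ its photodestruction rate and
  c a background term (the Bateman solution of A→B→C observed on B).
* **On-to-off photoswitching, first cycle** — opposed bi-exponential
  I(t) = I₁e^(−k₁t) − I₂e^(−k₂t) + c; the negative component reflects a
  transient green-intensity increase tied to a cycle-to-cycle emission
  blue-shift, both of which disappear when cysteine 175 is mutated.
* **On-to-off photoswitching, later cycles** — same-sign bi-exponential
  I(t) = I₁e^(−k₁t) + I₂e^(−k₂t) + c.
* **Thermal relaxation** (dark → fluorescent recovery) —
  A(t) = A₀(1 − e^(−kt)) + c, with half-life τ₁/₂ = ln2/k.

A generic first-order reaction-network integrator doubles as an
independent numerical oracle for the closed forms and as a simulator
for multi-population schemes (e.g. photo-oxidised subpopulations).

On top of the models sit bounded trust-region least-squares fitting
with AICc model selection, photofatigue cycle analysis (retention,
rate acceleration, wt-like vs C175A-like classification), emission-peak
and blue-shift quantification, Henderson–Hasselbalch pK_a fitting,
brightness (ε·φ), and seeded synthetic-data generators that emulate the
illumination experiments for all nine mSAASoti cysteine variants.

## Worked example

```python
import photokinetics as pk

# simulate a photoconversion experiment for the parent variant and fit it
preset = pk.load_preset("mSAASoti")
trace = pk.gen_conversion_trace(preset, noise=pk.NoiseModel(sigma=0.01, seed=1))
fit = pk.fit_trace(trace, "eq1")
print(f"k1 = {fit.params.k1*1e3:.2f}e-3 s^-1, k2 = {fit.params.k2*1e3:.2f}e-3 s^-1")

# three photoswitching cycles: fatigue, acceleration, behaviour class
series = pk.gen_cycle_series(preset, 3, pk.NoiseModel(sigma=0.01, seed=1))
metrics = pk.analyze_cycles(series)
print(f"acceleration = {metrics.acceleration:.2f}, "
      f"opposed first cycle = {metrics.first_cycle_opposed}")
print("behaviour:", pk.classify_variant_behavior(metrics))

print("brightness =", pk.brightness(preset.epsilon_1e3, preset.phi))
```

prints

```
k1 = 10.97e-3 s^-1, k2 = 2.00e-3 s^-1
acceleration = 1.44, opposed first cycle = True
behaviour: wt_like
brightness = 44.3
```

i.e. the fit recovers the generating photoconversion constants
(11, 2) × 10⁻³ s⁻¹ within noise, detects the opposed first-cycle
component and the ~1.4× switching-rate acceleration characteristic of
the parent protein, and reproduces its brightness of 44.3 × 10³
M⁻¹cm⁻¹ from ε = 75.0 × 10³ M⁻¹cm⁻¹ and φ = 0.59.

The same workflow is scriptable from the shell:

```bash
photokinetics simulate --preset mSAASoti --seed 1 --out data/
photokinetics convert data/conversion.csv
photokinetics cycles data/manifest.json
photokinetics report --dataset data/ --out report.csv
```

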