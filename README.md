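# pulsemei

Multiscale entropy index (MEI) and dilatation index (DI) analysis of wrist
arterial pulse recordings acquired under a cuff-occlusion reactive-hyperemia
protocol.

## The problem

Endothelial dysfunction — impaired vasodilatory capacity of the vascular
endothelium — is an early marker of atherosclerosis, and is classically
probed by occluding the upper arm with a pressure cuff and measuring how
strongly the distal pulse amplitude rebounds after release (reactive
hyperemia). The standard readout, the **dilatation index**, compares pulse
amplitudes in one representative minute before and after occlusion:

    DI = Amp_RH / Amp_Baseline × 100 %

DI uses two minutes of a 17-minute recording. `pulsemei` additionally
quantifies the *complexity* of the beat-to-beat amplitude fluctuations over
the entire baseline + hyperemic signal with **multiscale sample entropy**:
the amplitude series X₁…X_N (one value per beat, occlusion deleted) is
detrended by empirical mode decomposition, coarse-grained at scale factors
τ = 1…10 by non-overlapping block averages

    y_j^(τ) = (1/τ) Σ_{i=(j−1)τ+1}^{jτ} X'_i ,

and the sample entropy S_E(m=2, r=0.15·SD) of each coarse series is summed
into two indices:

    MEI_SS = Σ_{τ=1..5} S_E(τ)     MEI_LS = Σ_{τ=6..10} S_E(τ)

Healthy autonomic/vascular regulation produces long-range-correlated
(1/f-like) amplitude fluctuations whose entropy survives coarse-graining, so
MEI_LS stays high; ageing and poor glycemic control whiten the fluctuations
and MEI_LS falls — a more sensitive marker of subtle vascular change than
DI. The package is aimed at physiological-signal researchers who want the
full pipeline (beat detection → EMD detrending → MSE → indices), a seeded
synthetic cohort generator for validation, and clinical-style group
statistics.

## Worked example

```python
from pulsemei import ARCHETYPES, analyze_recording, render_waveform, simulate_amplitude_series

params = ARCHETYPES[1]                       # healthy-young archetype
series, _ = simulate_amplitude_series(params, seed=42)
recording, _ = render_waveform(series, params, seed=42)
result = analyze_recording(recording)
print(result.di.di_percent, result.mei.mei_ss, result.mei.mei_ls)
```

Running `python examples/02_analyze_recording.py` (the same computation,
annotated) prints:

```
beats detected: 995 (first hyperemic beat: #356)
entropy tolerance r = 0.0182 (0.15 x SD of the detrended series)

DI  = 202.9 %  (baseline window mean 0.974, hyperemic window mean 1.976)
...
MEI_SS = 10.38   MEI_LS = 10.05
```

DI ≈ 203 % says the hyperemic pulse amplitude roughly doubled — a healthy
endothelial response to the programmed gain of 2.0. The high MEI_LS
reflects the archetype's strongly 1/f-correlated fluctuations; the
poorly-controlled-diabetic archetype (whitened fluctuations, gain 1.33)
yields MEI_LS ≈ 7.5 and DI ≈ 133 % under the same analysis
(`examples/04_cohort_tables.py` builds the full four-group comparison).
Entropy magnitudes depend on the chosen (m, r) convention and the
fluctuation model; the group *ordering* and DI recovery are the validated
quantities.

The other examples: `01_simulate_subject.py` (generator ground truth),
`03_noise_signatures.py` (why MEI_LS separates 1/f from white noise).

## Command line

```bash
mei simulate --group cohort --n 5 --seed 1 --out sim/     # recordings + truth
mei analyze sim/g1s01.csv --out result.json               # one subject
mei cohort sim/manifest.csv --out report/                 # table1/table2/report
```

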