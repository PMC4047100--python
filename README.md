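# sahpkit

Current-clamp sweep analysis for studies of the slow after-hyperpolarization
(sAHP) in pyramidal neurons: from raw voltage traces to group-level
mixed-effects inference.

## The problem

Stress hormones such as corticosterone can selectively enlarge the sAHP — the
seconds-long membrane hyperpolarization that follows a spike train, carried by
calcium-dependent potassium currents — in some brain regions but not others.
Detecting such an effect from whole-cell recordings requires a chain of
analyses, each of which this package implements as tested, reusable code:

1. **Passive membrane properties** from a −20 pA / 200 ms probe, by fitting
   the two-component charging model
   `V(t) = V_offset + I·R_a·(1−e^(−t/τ_p)) + I·R_in·(1−e^(−t/τ_m))`
   (Nelder–Mead with profiled linear amplitudes), cross-checked by direct
   measurement, with a 100–450 MΩ input-resistance inclusion filter.
2. **Spike analysis**: local-linear smoothing, detection of peaks > 40 mV
   above baseline, threshold at the 20 mV/ms crossing of dV/dt, 20–80% rise
   time, rising slope, width at half maximum, inter-spike intervals, and the
   accommodation ratio (100 × last ISI / first ISI).
3. **AHP decomposition**: the post-step decay is fitted as
   `V(t) = V_med·e^(−t/τ_med) + V_slow·e^(−t/τ_slow)` with τ_med ∈ (0, 400] ms
   and τ_slow ∈ (400 ms, 8 s] (bounded Nelder–Mead, multi-start, r² scoring),
   plus an ablation contrast that verifies the two components separate.
4. **Cohort statistics**: a linear mixed model of sAHP amplitude on treatment
   group × injected current (random intercept and slope per cell, ML),
   likelihood-ratio tests, Cook's-distance influence screening (cutoff 4/n),
   multiple imputation of missing observations by EM-with-bootstrapping,
   Rubin/D2 pooling, and simulation-based power analysis.

Because raw recordings for such studies are rarely deposited, the package
ships a **synthetic sweep generator** (`sahpkit.synth`) that emulates the
recordings — accommodating spike trains, bi-exponential AHP tails, band-limited
noise, two-group cohorts with a treatment × current interaction and
per-cell random effects — with exact ground truth, so every stage is testable
end to end.

## Worked example

```python
import sahpkit as sk

proto = sk.CurrentProtocol(depol_step_amp=300)        # 300 pA step
params = sk.TraceGenParams(noise_sd=0.2, seed=11)     # one synthetic cell
trace, truth = sk.generate_trace(proto, params)

fit = sk.fit_ahp(trace)
print(f"mAHP {fit.v_med:.2f} mV (tau {fit.tau_med:.0f} ms), "
      f"sAHP {fit.v_slow:.2f} mV (tau {fit.tau_slow:.0f} ms), "
      f"r2 {fit.r2:.3f}")
```

prints

```
mAHP -3.33 mV (tau 148 ms), sAHP -1.42 mV (tau 6031 ms), r2 0.974
```

— the generative truth was −3.5 mV / 150 ms and −1.4 mV / 6000 ms, so at
acquisition-level noise (0.2 mV) the decomposition recovers both components to
a few percent.  The full study-scale analysis lives in the numbered scripts:

```bash
python analysis/01_simulate_cohort.py --seed 1   # 20+15 cells × 13 sweeps
python analysis/02_extract_features.py           # passive / spikes / AHP
python analysis/03_ablation_check.py             # component-separation check
python analysis/04_mixed_model_inference.py      # LME + imputation + LRT
python analysis/05_power_analysis.py             # power vs sample size
```

Each script prints what it found and writes its tables under `results/`.
`sahpkit.pipeline.run_pipeline` runs the same chain from a single config
(YAML-compatible) with a reproducibility manifest.

## Layout

```
src/sahpkit/      io, synth, passive, spikes, ahp, stats, pipeline
analysis/         numbered narrative drivers over the package
tests/            unit, property (hypothesis) and end-to-end suites
docs/methods.md   models, assumptions, numerical choices, limitations
```
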