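# fssfuse

Functional Source Separation (FSS) for steady-state visual evoked
potentials (ssVEPs) recorded simultaneously with fMRI, and the
downstream ssVEP–BOLD fusion statistics. The package is aimed at
EEG–fMRI researchers who want a tested, seeded reference implementation
of the semi-blind extraction + correlation-mapping pipeline, exercised
end to end on a bundled co-simulator with known ground truth.

## The method

EEG is modeled as a linear mixture `x = A s + n`. A single unmixing
vector **w** is chosen to maximize

```
F(w) = Σ_phases [ J(w) + λ · ψ(R_stim(w), k) ]
```

* `J(w) = (E{G(wᵀx)} − E{G(v)})²` — the fastICA log-cosh negentropy
  approximation (`G(u) = log cosh(a₁u)/a₁`, `a₁ = 1`, `v ~ N(0,1)`,
  `var(wᵀx) = 1`): non-Gaussianity of the candidate source.
* `R_stim` — mean Hilbert envelope of the trial-averaged source during
  stimulation (0–5 s) minus the pre-stimulus baseline (−1–0 s):
  the physiological prior that the source is stimulus-locked.
* `ψ(r, k) = min(r/k, 1)` — saturates at the admissibility scale `k`
  (the best `R_stim` over a plain fastICA decomposition), so above `k`
  only independence drives the optimization. `λ = 10`; `λ = 0` is the
  pure-ICA comparison mode.

The non-differentiable contrast is maximized by seeded simulated
annealing on the unit sphere, jointly over the three experimental
phases, on data band-passed 10 ± 0.5 Hz with a zero-phase filter.
The extracted source's per-scan amplitude envelope, shifted by the 4 s
hemodynamic lag (2 scans at TR = 1.98 s), is correlated with every BOLD
voxel (|Pearson r|, the bivariate xMCC); significance comes from
circular-shift permutation tests per participant and a
voxel-count-corrected binomial test on inter-subject overlap.

See `docs/methods.md` for the full model, parameter defaults and
numerical choices.

## Worked example

```python
import numpy as np
from fssfuse import RunConfig, extract_participant

cfg = RunConfig(mode="both").with_seed(1)       # simulate + extract
run = extract_participant(cfg, participant=0, with_fusion=False)

for mode in ("fss", "ica"):
    src = run.results[mode].sources["HAB"]
    truth = run.sims["HAB"].truth.ssvep_source
    print(mode, round(abs(np.corrcoef(src, truth)[0, 1]), 3))
print("R_stim/k per phase:",
      {p: round(d["R_stim"] / d["k"], 2)
       for p, d in run.results["fss"].phase_diagnostics.items()})
```

prints

```
fss 0.974
ica 0.042
R_stim/k per phase: {'HAB': 1.0, 'ACQ': 1.01, 'EXT': 1.02}
```

With the functional constraint the extracted source tracks the true
ssVEP almost perfectly (|corr| ≈ 0.97) and sits in the admissible
region (`R_stim ≥ k`) in every phase; with `λ = 0` the same annealer is
captured by the more non-Gaussian alpha-band distractor and the
recovered source is unrelated to the ssVEP (|corr| ≈ 0.04).

The same pipeline is scriptable from the shell:

```
fssfuse simulate --seed 1 --out sim/
fssfuse extract  --in sim/ --lambda 10 --seed 1 --mode fss --out ext/
fssfuse fuse     --source ext/source_fss_HAB.tsv --bold sim/bold_HAB.nii.gz \
                 --mask sim/mask_HAB.nii.gz --lag 4 --out fused/
fssfuse run      --seed 1 --out study/      # full multi-stage pipeline
```

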