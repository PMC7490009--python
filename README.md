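# tsquant

Quantification pipeline for single-molecule FISH-IF translation imaging,
built around one question: when puromycin releases a nascent chain from the
ribosome, does the released protein stay put?  The package implements the
three computations that answer it:

1. **Translation-site quantification (smFISH-IF).**  In two-channel 3D
   stacks (smFISH mRNA channel, SunTag/scFv-GFP protein channel), every
   diffraction-limited spot is fit with an anisotropic 3D Gaussian
   `A·exp(−(Δx²+Δy²)/2σ_xy² − Δz²/2σ_z²) + B`, whose background-subtracted
   integrated intensity is `I = A·(2π)^{3/2}·σ_xy²·σ_z`.  Released single
   SunTag peptides in the cytoplasm — protein spots away from every mRNA —
   are averaged into the *idealized single-peptide* unit `I_single`.  Each
   mRNA's translation site is then fit inside an 11 × 11 pixel box and its
   nascent-chain count is `N = I_ts / I_single`; sites failing shape,
   intensity or distance filters carry `I_ts = 0`, and an mRNA with `N < 1`
   is *unassociated* with SunTag signal.  Cells with more than five and
   fewer than 36 mRNAs contribute a per-cell colocalized fraction;
   conditions are compared by Welch's t-test.
2. **Synthetic scene generation.**  No raw images accompany the source
   study, so a first-class simulator renders two-channel stacks (107.5 nm
   x-y pixels, 300 nm z-steps, Gaussian PSF, Poisson + read noise) from
   ground-truth scenes whose translating fraction per mRNA is set by a
   drug-condition preset: untreated 0.63, puromycin 0.03,
   emetine + puromycin 0.05, anisomycin + puromycin 0.50.  Recovering those
   fractions from rendered pixels exercises the entire pipeline.
3. **Diffusion spatial resolution and ROI quantification.**  The
   mean-squared-displacement relation `⟨x²⟩ = 2nDt` (D = 126 µm²/s,
   cytosolic GFP) bounds how far a released protein travels during a
   labeling incubation, and a small ROI module measures polygonal regions
   on average-intensity projections with control-group normalization (the
   germline OPP experiment).

It is written for microscopists and quantitative biologists who want a
tested, scriptable reference implementation of this analysis rather than a
GUI tool.

## Worked example

```python
from tsquant import ExperimentConfig, run_experiment

report = run_experiment(ExperimentConfig(master_seed=1, n_cells=24))
for cond, s in report.summaries.items():
    print(f"{cond:>20s}: {100*s['mean_fraction']:5.1f}% +/- {100*s['sem_fraction']:.1f}%")
```

prints (24 synthetic cells per condition, master seed 1):

```
           untreated:  62.1% +/- 1.9%
           puromycin:   3.2% +/- 1.0%
   emetine_puromycin:   2.8% +/- 1.0%
          anisomycin:  54.4% +/- 2.2%
```

Each line is the across-cell mean (± SEM) fraction of mRNAs whose
translation site holds at least one single-peptide unit of SunTag
intensity.  The pipeline — spot detection, calibration, site fitting,
association threshold, cell filter — recovers the generating fractions
(63 / 3 / 5 / 50%) from rendered pixels to within a couple of percentage
points; puromycin strips translation sites whether or not emetine was added
first, while anisomycin pre-treatment protects them.
`report.pairwise` holds the corresponding Welch tests (untreated vs
puromycin p ≈ 8e-25; puromycin vs emetine + puromycin p ≈ 0.78 at this
seed).

The same stages are available as numbered drivers (`analysis/01_simulate.py`
… `05_diffusion.py`), which write their tables under `results/`, and as a
CLI:

```bash
tsquant simulate --preset untreated --cells 4 --seed 1 --out scratch/sim
tsquant diffusion --dim 1 --distance 100
# -> time to reach 100.0 um (1D, D=126.0): 39.68 s
```

## Layout

- `src/tsquant/` — library: `simulate`, `detect`, `quantify`, `stats`,
  `roi`, `diffusion`, `io`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `docs/methods.md` — models, parameter choices, limitations.
- `tests/` — unit, property and end-to-end suites.
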