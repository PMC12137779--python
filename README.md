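# cdti — free-breathing cardiac DTI motion correction and mapping

Cardiac diffusion tensor imaging (DTI) maps myocardial microstructure from
diffusion-weighted spin-echo EPI frames acquired over many heart beats.  Under
free breathing each frame lands at a different respiratory position, so the
frames must be co-registered before tensor fitting or the resulting mean
diffusivity (MD), fractional anisotropy (FA) and helix-angle (HA) maps are
corrupted by motion blur and misregistration.

`cdti` implements a complete, deterministic 2-D pipeline for this problem,
aimed at researchers processing per-slice short-axis DWI series:

* **Registration** — pair-wise *symmetric, inverse-consistent* deformable
  registration: a log-domain diffeomorphic demons engine optimizing one
  stationary velocity field `v`, with `forward = exp(v)` and
  `inverse = exp(-v)`, so the two output fields are mutual inverses by
  construction.  Similarity is local normalized cross-correlation (demons
  forces on Gaussian-locally-standardized intensities), which lets low-b
  (b = 50 s/mm²) and high-b (b = 500 s/mm²) frames register directly,
  without modeling diffusion contrast.
* **Motion correction schedules** — `moco_naive` registers every frame to
  the first acquired b50 frame; `moco_avg` first registers and averages the
  12 b50 frames into a high-SNR reference, registers every high-b frame to
  it, averages per diffusion direction, and re-registers the averages.
* **Tensor fitting** — cubic interpolation to a 1.4 mm map grid, then a
  per-pixel weighted linear least-squares fit of
  `ln S = ln S0 − b gᵀ D g` (OLS init, one reweighting pass with weights
  S²), giving MD = (λ₁+λ₂+λ₃)/3 and FA = √(3/2)·‖λ−MD‖/‖λ‖ in μm²/ms.
* **Cardiac geometry** — LV wall coordinates from endo/epi contours:
  transmural depth (0 % endo → 100 % epi), a right-handed
  circumferential/longitudinal/radial frame, the helix-angle map, and
  helix-angle transmurality (HAT): the sector-wise OLS slope of HA against
  depth in °/%.
* **Motion metric** — the epicardium line-tracking statistic: intensity
  profiles along a head-foot line through the heart, the per-frame
  epicardium index from the largest forward first difference in a 10-sample
  window, and the population SD of those indices across frames; plus paired
  t-tests with Bonferroni correction for comparing schedules.
* **Phantom** — a synthetic short-axis acquisition (torso, lung, LV wall
  with a +60°→−60° transmural helix-angle rule, blood pool; 12 directions ×
  two shells, Rician noise, sinusoidal head-foot respiratory motion) with
  exact ground truth for every quantity above.

## Worked example

Generate a moving, noisy phantom slice, correct it with the staged schedule,
and map it:

```bash
cdti phantom --out work/phantom --seed 1
cdti moco --strategy avg --series work/phantom/series.nii \
          --meta work/phantom/series_meta.csv --out work/moco
cdti fit --series work/moco/averaged.nii --meta work/moco/averaged_meta.csv \
         --bval work/phantom/series.bval --bvec work/phantom/series.bvec \
         --contours work/phantom/contours.json --out work/maps
cdti track --series work/moco/corrected.nii --meta work/moco/corrected_meta.csv \
           --line 36.0,24.0,92.0,24.0 --center 23 --out work/track
```

which prints, for the default phantom (prescribed MD 1.40 μm²/ms, FA 0.361,
HAT −1.20 °/%):

```
moco_avg: 0 flagged frame(s); output in work/moco
global HAT -1.103 deg/%; maps and summary.csv in work/maps
epicardium position SD = 0.266 px over 108 frames
```

The summary lists global MD 1.41 μm²/ms and FA 0.33, and the HAT of
−1.10 °/% sits close to the prescribed −1.20 °/% (the gap comes from
partial-volume pixels at the contour-defined wall rim).  The same
free-breathing series *without* correction tracks at an epicardium SD of
3.73 px — the SD collapse is the motion-correction effect the metric is
designed to show.  `work/maps/summary.csv` holds per-slice and
global mean/SD of MD, FA and HAT; `cdti run --config cfg.yaml --out dir`
chains all stages from one YAML config and emits a `resolved_config.yaml`
that reproduces the run byte-for-byte.

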