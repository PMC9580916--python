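# smlmkit

Single-molecule localization microscopy (SMLM) turns movies of blinking
fluorophores into coordinate lists with ~5–40 nm precision. `smlmkit` is a
Python toolkit covering the full computational chain for researchers who
want transparent, tested building blocks rather than a monolithic GUI:

* **Pre-processing and localization** — temporal median background
  subtraction; difference-of-Gaussian emitter detection; phasor (first-order
  DFT phase) sub-pixel localization.
* **Post-processing** — gap-tolerant nearest-neighbour linking for merging
  blinking emitters and for particle tracking; drift correction by fiducial
  markers or temporal image cross-correlation; affine chromatic-aberration
  correction from paired control points.
* **Data interpretation** — super-resolved rendering (histogram / bilinear /
  per-localization Gaussian); jump-distance, mean-jump-distance and MSD
  diffusion analysis; DBSCAN clustering with core/edge/noise roles; image
  resolution by Fourier ring correlation (FRC, 1/7 threshold) and
  localization precision by nearest-neighbour analysis (NeNA).
* **Synthetic data** — a ground-truth simulator for every stage: blinking
  emitters (two-state Markov kinetics) with pixel-integrated Gaussian PSFs,
  Poisson/read noise, inhomogeneous background, fiducial markers, smooth
  drift, chromatic offsets, Brownian mixtures and static filament scenes.

## The core models

Localization: a candidate peak's ROI (7×7 px) is localized from the phase
of its first-order Fourier coefficients, `Fx = Σ roi[v,u]·exp(−2πi·u/N)`;
the phase maps linearly onto the sub-pixel offset. Precision scales as
`σ ≈ σ_PSF/√N` with photon count N.

Diffusion: 2D Brownian single-frame jumps follow the Rayleigh mixture
`p(r) = Σᵢ fᵢ · r/(2Dᵢτ) · exp(−r²/(4Dᵢτ))`, fitted to the jump-distance
histogram; per-track mean jumps are near-Gaussian (CLT) with
`E[r] = √(πDτ)`; the ensemble MSD obeys `msd(Δt) = 4DΔt + 4σ_loc²`.

Precision/resolution: NeNA fits next-frame nearest-neighbour distances with
`p(d) = d/(2σ²)·exp(−d²/(4σ²))` (σ = per-axis precision); FRC reads the
structural resolution at the first 1/7 crossing of the ring-wise spectral
correlation of two random half-datasets, bounded below by 2σ (Nyquist).

## Worked example

```python
import numpy as np
import smlmkit as sk

rng = np.random.default_rng(0)
emitters = sk.EmitterModel(rng.uniform(5, 43, (12, 2)),
                           k_on=0.05, k_off=0.5, photons_per_frame=4000)
noise = sk.NoiseModel(background_offset=30, background_gradient=(0.3, -0.2),
                      read_noise_sigma=1.5)
movie, truth = sk.simulate_movie(emitters, noise, None, 400, (48, 48), seed=1)

filtered = sk.temporal_median_filter(movie, sk.MedianFilterParams(51), clamp=False)
locs = sk.localize_movie(movie, filtered, sk.DetectionParams(threshold_k=4))
print(f"{len(locs)} localizations in {movie.n_frames} frames")

nena = sk.nena_precision(locs)
print(f"NeNA localization precision: {nena.sigma_nm:.1f} nm")

linked = sk.link_localizations(locs, sk.LinkParams(max_jump_px=0.5, max_gap_frames=2))
merged = sk.merge_linked(linked)
print(f"merged to {len(merged)} emission events")

img = sk.render_histogram(merged, sk.RenderParams(zoom=10))
print(f"rendered {img.data.shape[0]}x{img.data.shape[1]} super-resolution image")
```

prints

```
433 localizations in 400 frames
NeNA localization precision: 3.2 nm
merged to 214 emission events
rendered 390x410 super-resolution image
```

12 blinking emitters over 400 frames produce 433 raw detections; NeNA puts
the single-frame precision at 3.2 nm (4000 photons/frame on a 100 nm-pixel
camera); merging collapses repeated detections of the same on-period into
214 events; the histogram render uses 10 nm sub-pixels (zoom 10).

The same chain is available from the shell:

```bash
smlm localize --window 51 --threshold 4 movie.tif locs.csv
smlm merge --max-dist 0.5 --gap 2 locs.csv merged.csv
smlm render --method bilinear --zoom 10 merged.csv image.tif
smlm resolution nena locs.csv nena.json
smlm run pipeline.yaml out/        # YAML-configured end-to-end run
```

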