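# hgiscan

An in-silico workbench for combining **Hermite–Gaussian imaging** (HGI,
spatial-mode demultiplexing) with **image scanning microscopy** (ISM,
focused-illumination scanning + pixel reassignment) on synthetic DMD-style
binary objects.

Conventional superresolution methods structure the *illumination* (confocal,
ISM, SIM); mode-demultiplexing methods instead restructure the *detection*:
the image-plane field is decomposed into Hermite–Gaussian modes

φ_mn(x, y) ∝ H_n(x/√2σ) H_m(y/√2σ) · exp(−(x²+y²)/4σ²),

whose complex amplitudes c_mn = ⟨φ_mn, E⟩ carry the geometrical moments of
the object and allow reconstruction beyond the direct-imaging Rayleigh
limit. The two ideas act on opposite ends of the microscope, so they can be
combined: scan a focused beam, read out each snapshot in the HG basis,
reconstruct it, and merge the snapshots by pixel reassignment. The governing
Gaussian geometry is the width composition

σ_ISM = σ_il σ_det / √(σ_il² + σ_det²),

with the per-snapshot rescale factor σ_det²/σ_ISM² (2 for matched widths).
`hgiscan` implements the full simulation: object generators (line pairs,
random training patterns, tiled emblems), the coherent/incoherent forward
model (Gaussian and Jinc APSFs), HG measurement with heterodyne-style
per-mode noise, damped-pseudoinverse and neural-network reconstruction,
pixel reassignment and stitching, and the evaluation stack (generalized
Rayleigh two-point resolution from line-pair series, Richardson–Lucy
deconvolution, sampled MS-SSIM).

Audience: researchers in computational imaging / quantum-inspired
superresolution who want a testable, seed-reproducible reference
implementation of the HGI + ISM pipeline and its metrology.

## Worked example

Resolution of the four pipelines on the standard line-pair series
(210-px frames, σ_det = 30 px, matched focused illumination, 20-px scan
step, 441 HG modes, per-mode noise at 0.1% of the peak mode amplitude for
the HGI pipelines):

```python
from hgiscan import ExperimentConfig, line_pair_resolution

for experiment, seps, noise in [
    ("widefield_di",  range(20, 131, 10), 0.0),
    ("scanning_di",   range(40, 131, 10), 0.0),
    ("widefield_hgi", range(20, 81, 10),  0.001),
    ("scanning_hgi",  range(20, 81, 10),  0.001),
]:
    cfg = ExperimentConfig(experiment, separations=tuple(seps),
                           mode_noise_rel=noise, seed=1)
    est, _ = line_pair_resolution(cfg)
    print(f"{experiment:14s} {est.resolution_px:6.1f} px  (+- {est.uncertainty_px:.0f})")
```

prints

```
widefield_di    107.5 px  (+- 5)
scanning_di      75.8 px  (+- 5)
widefield_hgi    53.3 px  (+- 5)
scanning_hgi     49.7 px  (+- 5)
```

Reading the numbers: scanning improves direct imaging by the factor
107.5/75.8 ≈ 1.42 (Gaussian theory √2); widefield HGI beats widefield DI
by 2.0×; and scanning adds ≈ 7% on top of widefield HGI — consistent with
the ≤ 8% bound from the width-composition formula at the fitted
illumination-to-detection width ratio. The ± value is the
interpolation-bracket half-width of the 10-px separation grid.

The same pipelines run from the shell:

```bash
hgiscan reproduce-analytics            # closed-form width/unit checks
hgiscan objects line-pairs --out out/  # write the 20..130 px series
hgiscan run --config config.yaml --out results/
```

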