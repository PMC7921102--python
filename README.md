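# chromemu

Euchromatin in early embryonic nuclei is organized into transcriptionally
inactive chromatin domains interspersed with RNA-rich "transcription
pockets".  `chromemu` implements a lattice model that explains this pattern
as an **active microemulsion** — RNA–RBP condensates and inactive chromatin
tend to phase-separate, while transcriptionally active chromatin, whose
nascent transcripts tether it to the condensate, acts as an amphiphile that
arrests coarsening at the microphase scale — together with the
image-quantification pipeline used to compare simulated concentration
profiles with micrographs.

It is aimed at quantitative cell biologists and biophysicists who want to

* simulate chromatin / RBP / RNA dynamics on a 2D lattice (chemical
  conversions on a fixed clock interleaved with Metropolis–Kawasaki
  neighbor swaps, chain connectivity preserved),
* render lattice snapshots into microscopy-like images (100 nm pixels,
  Gaussian blur σ = 120/450/150 nm),
* quantify nuclear organization in such images or in real ones: image
  contrast `C_DNA = σ_I/Î` (coefficient of variation, offset-corrected by
  `a = Î/(Î+I_offset)`), the mask-aware radial correlation function
  `g(r) = (g_x+g_y)/2` and its correlation length from the fit
  `g∞+(g0−g∞)e^(−r/L_corr)`, conditional intensity profiles, transcription
  focus detection and Chebyshev-ring radial profiles, live-cell nucleus
  segmentation/tracking, and
* test group differences with exact/Monte-Carlo permutation tests and
  Bonferroni-prefactor correction.

Because the original micrographs are not publicly deposited, a synthetic
phantom module generates images with known ground truth (prescribed
exponential correlation length, contrast, RNA anti-correlation, foci) for
validation.

## Worked example

```python
import numpy as np
from chromemu import lattice, params, render, image

# run the microphase scenario for 24 simulated minutes
traj = lattice.run_scenario(params.scenario("microphase"), seed=1,
                            duration=1440.0)

# render the final snapshot like a STED mid-section (sigma = 120 nm)
img = render.render_profile(traj.final_state,
                            render.RenderConfig(blur_sigma_nm=120.0))

c = image.image_contrast(img["dna"], img.mask)
curve = image.radial_correlation(img["dna"], img.mask, img.pixel_size_nm,
                                 max_lag_px=36)
fit = image.fit_correlation_length(curve)
print(f"C_DNA = {c.c_dna:.3f}, L_corr = {fit.l_corr_um:.3f} um")
```

```
C_DNA = 1.371, L_corr = 0.257 um
```

`C_DNA` is the coefficient of variation of the rendered DNA profile inside
the mask — a measure of how pronounced the chromatin domains are — and
`L_corr` is the decay length of its spatial autocorrelation, the
characteristic width of those domains.  Under the shipped surrogate
parameters the uniform-dispersion scenario gives a flatter profile (lower
contrast and correlation length), while the no-transcription
phase-separation scenario coarsens into fewer, larger domains (both
statistics higher); the microphase steady state sits between them.

The same analysis applies to real TIFFs:

```bash
chromemu analyze contrast --input nucleus.tif --pixel-size-nm 40 --out c.csv
chromemu analyze corrlength --input nucleus.tif --pixel-size-nm 40 --out g.csv
```

End-to-end reproductions of the in-silico experiments:

```bash
chromemu reproduce inhibitors --n 10 --seed 1 --out results/inhibitors
chromemu reproduce onset --n 12 --seed 1 --out results/onset
```

`reproduce inhibitors` runs post-mitosis control / flavopiridol /
actinomycin D conditions, quantifies each run and reports permutation
P values (Bonferroni m = 2): flavopiridol (amphiphile removal) coarsens the
pattern — markedly higher `C_DNA` than control within the 30-minute
window — whereas actinomycin D (amphiphile retention) stays
indistinguishable from control (see `docs/methods.md` for what the
correlation length does and does not resolve on this timescale).  `reproduce onset` averages radial
ring profiles around a single transcriptionally activated locus: after
onset, DNA intensity within the innermost rings drops while RNA rises —
the forming transcription pocket displaces inactive chromatin.

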