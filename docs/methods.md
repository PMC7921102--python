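# Methods

## The model

`chromemu` models euchromatin organization as an *active microemulsion* on a
two-dimensional square lattice.  Every interior site holds exactly one
particle: a chromatin monomer (part of a linearly connected chain, in a
transcriptionally *inactive* or *active* state) or an RNA-binding protein
(RBP, *unbound* or *RNA-bound*, i.e. holding at least one transcript).
Transcripts are integer counts resident on sites and travel with them.

Two segregating "phases" emerge from pairwise mismatch costs on the
8-neighborhood (diagonals included): inactive chromatin pays `w_inactive_boundRBP`
per RNA-bound-RBP neighbor, so chromatin and the RNA–RBP condensate demix.
Active chromatin is the amphiphile: it pays no cost next to RNA-bound RBPs
(it is wetted by the condensate, to which its transcripts are tethered), but
it pays `w_inactive_active` next to inactive chromatin and `w_active_active`
next to other active sites, which spreads it along the interface.  All other
neighbor pairs are neutral; in particular unbound RBPs mix freely with
everything.  Full phase separation of the condensate from chromatin is
arrested by the amphiphile, leaving interspersed microphase domains — unless
the amphiphile is removed (the flavopiridol mimic), in which case the
pattern coarsens.

### Dynamics

Chemistry and transport are interleaved:

* **Chemical conversions** run on a fixed clock `dt_chem = 0.1 / k_max`
  (`k_max` = fastest nonzero rate), each channel firing with per-interval
  probability `P = dt_chem * k ≤ 0.1`.  Channels: inactive→active (only on
  chains currently permissive for transcription), active→inactive (always),
  transcript production on active sites, transfer of one transcript to a
  uniformly chosen 8-neighbor RBP (no-op when none), per-transcript decay
  (optionally suppressed on chromatin — the actinomycin D mimic), and
  permissive/restrictive chain switching.  Decay is sampled exactly as a
  Binomial(n, p) draw by CDF inversion.  Note the first-order scheme's
  survival after m intervals is `(1 − dt·k)^m`, which deviates from
  `exp(−kt)` by about 5% per unit `kt` for the fastest reaction (`p = 0.1`);
  for reactions an order of magnitude below `k_max` the bias is ~0.25% and
  negligible against counting noise.

* **Neighbor swaps** (Kawasaki exchange): a uniformly random (interior site,
  8-neighbor direction) pair is proposed; proposals that would move a
  tethered site, swap with the static padding ring, or break a chain's
  Chebyshev-distance-1 connectivity are rejected outright.  Otherwise the
  energy change `dE` is the sum of mismatch-cost changes over both sites'
  neighborhoods and the swap is accepted with the Metropolis probability
  `min(1, exp(−dE))`.  Transcripts move with their site.

**Why Metropolis.** A normalized variant
`P = min(1, exp(delta_e_min − dE))` — acceptance proportional to
`exp(−dE)`, scaled so the largest conceivable energy drop is certain — is
also implemented (`EnergyParams(acceptance="normalized")`).  Because
`delta_e_min = −14·w` for a single cost class, that rule accepts even
energy-neutral swaps with probability `e^{−14} ≈ 10^{−6}` at `w = 1`: the
lattice is effectively frozen at any realistic attempt budget, and none of
the reference regimes can form.  The package therefore defaults to the
field-standard Metropolis rule, which shares the property `P = 1` at
`dE = delta_e_min` and produces the expected phase behavior.  Relative
acceptance ratios between competing moves are identical under both rules.

`delta_e_min` itself is computed by the convention of enumerating the two
swapped species together with independent species choices for their 7 + 7
non-partner neighbor slots (`−14·w` for one cost class).  On the actual
lattice, neighbors shared by the swapped pair cancel, so the geometrically
attainable minimum is `−10·w` (diagonal pair); `delta_e_min` is a lower
bound and only enters the normalized acceptance option.

* **Interleaving**: `swap_attempts_per_chem_interval` proposals run between
  consecutive chemical updates; one *sweep* is `width·height` attempts.  The
  physical time of a swap attempt is not defined by the model,
  so this ratio is the calibration knob tying diffusion to chemistry.  The
  shipped default is **50 sweeps per `dt_chem`** (with default rates,
  `dt_chem = 1 s`): at this setting a 30-minute inhibitor window contains
  ~9×10⁴ sweeps, enough for measurable domain coarsening after amphiphile
  removal, while the microphase steady state remains arrested.  Values of
  10 sweeps per interval and below leave too little transport per unit
  chemical time for any of the reference regimes to develop on observation
  windows of tens of minutes.

### Parameters

The reference study's numeric rates and mismatch costs are not published
alongside its text, so the defaults shipped in
`chromemu/data/default_params.yaml` are surrogate values calibrated once so
that the model reproduces the qualitative reference behaviors (regime
ordering; inhibitor responses), then frozen:

| parameter | default | meaning |
|---|---|---|
| `k_chrom_on` | 0.0125 /s | activation on permissive chains |
| `k_chrom_off` | 0.0375 /s | deactivation (≈25% of permissive chromatin active) |
| `k_rna_prod` | 0.1 /s | transcript production per active site |
| `k_rna_transfer` | 0.1 /s | transcript hand-off chromatin → RBP |
| `k_rna_decay` | 2×10⁻⁴ /s | per-transcript decay (τ ≈ 83 min) |
| `k_chain_on/off` | 0.005 /s | chain permissive/restrictive switching |
| `w_*` | 0.6 k_BT | all three mismatch costs |
| sweeps per `dt_chem` | 50 | diffusion/chemistry calibration |

Calibration rationale: the RNA lifetime must exceed the 30-minute inhibitor
window (nuclear RNA is retained after flavopiridol; with τ ≈ 8 min the
condensate would dissolve and the lattice would re-mix instead of
coarsening).  The active fraction controls amphiphile coverage: at ~50%
active the microphase domains collapse to the single-chain scale, at ~10%
the control is no longer arrested; ~25% balances both.  The mismatch cost
sets quench depth; `w = 0.6` is a moderate quench well above the
order–disorder point (≈0.38 for this neighborhood) with mobile interfaces —
the regime behavior is insensitive to `w` between 0.6 and 1.0.

## Scenarios

All scenarios place chains serpentine-wise, centered in a regular grid of
boxes, with everything else unbound RBP, and surround the lattice with a
static one-site padding ring that contributes to energies but never moves
or reacts.

* **Uniform dispersion** (50×50, 100 chains of 5 in 5×5 boxes, RNA–RBP
  padding): no chemistry, no RNA — chains and RBPs mix freely.
* **Phase separation** (same layout): every RBP starts RNA-bound, decay
  disabled, no chemistry — chromatin and condensate demix and coarsen.
* **Microphase** (same layout): all chains permissive, full chemistry with
  chain switching off — transcription builds the condensate and arrests
  coarsening in a stochastic steady state.
* **Post-mitosis control / flavopiridol / actinomycin D** (100×100, 100
  chains of 50 packed in 10×10 boxes, inactive-chromatin padding): all
  chains permanently permissive; chromatin touching the boundary layer
  (the interior ring next to the padding) is tethered permanently; 10 min
  relaxation with all rates 0, then free transcription, then inhibitor
  application mid-run.  Flavopiridol zeroes activation only (amphiphile
  removal — RNA is retained); actinomycin D freezes activation,
  deactivation, production and transfer and suppresses decay on chromatin
  (amphiphile retention).
* **Single-locus onset** (50×50, 25 chains of 20 in 10×10 boxes,
  inactive-chromatin padding, no tethering): only the central chain ever
  becomes permissive, at t = 10 min after relaxation.  The literature
  setup behind it ("5 × 5 chains … in a 50 × 50 lattice") is ambiguous; a
  5×5 grid of boxes is the only reading with a unique central chain, and
  length 20 keeps the ~20% chromatin area fraction of the exploratory
  setups.

## Rendering

One lattice site maps to one 100-nm pixel.  Channels: DNA = chromatin
indicator, RNA = transcript count, Ser2Phos = active-chromatin indicator;
each is blurred with a Gaussian of physical width σ (120 nm STED-like,
450 nm spinning-disk-like, 150 nm live-cell-like) using reflective
boundaries, which conserves channel mass exactly for the normalized
symmetric kernel.

## Image statistics

* **Contrast** `C_DNA` = sample SD / mean of in-mask pixels (coefficient of
  variation); an additive offset is corrected by `a = mean/(mean+offset)`.
* **Radial correlation** `g(r)`: intensities are normalized by the in-mask
  mean and mean-subtracted; `g_x` sums mask-weighted products over
  one-sided x-shifts divided by the mask-pair count, likewise `g_y`;
  `g = (g_x+g_y)/2` at integer pixel lags.  Lags with empty denominators
  are flagged and excluded.  Pixels outside the mask can never contribute.
* **Correlation length** `L_corr`: fit of `g∞ + (g0−g∞)·exp(−r/L)` with
  `g0` pinned to `g(0)`, `g∞` pinned to the mean of `g` over 2.0–3.5 µm,
  least squares over r ∈ [0, 3.5 µm] optimizing only L (bounded scalar
  minimization).  For two-phase lattice patterns `g(r)` dips negative at
  the inter-domain spacing; the fitted L then tracks the early-decay
  (domain-width) scale.  Because single-snapshot L estimates of evolving
  patterns are noisy, the pipeline quantifies each run as the mean of the
  fits over the last three saved snapshots.
* **Nuclear segmentation**: Otsu threshold on the DNA channel, hole
  filling, erosion (default radius 3 px; disk structuring element).  Shell
  background: mean over (dilation minus mask), default width 5 px.
  Z-stacks: the slice with the highest mean DNA intensity is the
  mid-section (ties → lowest index).
* **Conditional intensity analysis**: per-bin means of channel A over
  pixels binned by channel B (or jointly by B and C), 20 bins per axis on
  the channel's in-mask [0, 1] rescaled range.
* **Focus analysis**: local background is removed by subtracting a
  σ = 2.38 µm Gaussian-blurred copy; Otsu threshold, connected components,
  keep the two largest objects as the prominent transcription sites.
  Radial profiles grow Chebyshev rings from the rounded centroid (ring r
  holds 8r pixels in the interior; rings tile the image and are clipped at
  borders).
* **Live-cell segmentation**: two-stage Otsu (cells from background, then
  nuclei within cells).  The stage-2 threshold's separability measure
  (between-class variance / total variance) decides interphase vs mitosis:
  below 0.65 nuclei are segmented, at or above the nuclear pool is judged
  released to the cytoplasm.  Touching nuclei are split by a watershed
  seeded at maxima of the 3D distance-to-background transform.  Nuclei are
  tracked by greedy nearest-centroid linking with a configurable frame
  gap; per-nucleus radial-time profiles are aligned at the first frame
  with two detected foci and averaged per (relative frame, ring).

## Statistics

Group comparisons use two-sided permutation tests on |difference of group
means| (difference of medians available).  The arrangement space is
enumerated exactly when it fits the resampling budget; otherwise the
Monte-Carlo estimate uses the add-one estimator `(1+#extreme)/(R+1)` so p
is never 0, with resolution floor 10⁻⁵.  Bonferroni correction is a bare
prefactor, deliberately not clipped at 1 (values above 1 read "not
significant").  `resample_match` re-tests on subsamples matched to an
experimental n; `running_average` gives sliding-window mean ± SEM with a
minimum-count rule that leaves gaps where data are sparse.

## Synthetic ground truth

The study's micrographs are not publicly deposited, so validation uses
phantoms with machine-readable truth: stationary Gaussian random fields
with an exact exponential autocorrelation (circulant embedding: FFT of the
periodically sampled target covariance, clipped at 0, colors white noise) —
so the fitted `L_corr` has an exact target; disc nuclei whose in-mask DNA
texture is rescaled to hit a target contrast; an RNA channel built as
`−ρ·field + sqrt(1−ρ²)·independent field` (anti-correlation ρ,
RNA-rich where DNA-poor); Ser2Phos foci placed in the lowest-DNA /
highest-RNA decile; and 4D time-lapses in which two foci appear at a known
frame and exponentially deplete DNA within a known radius.  Phantoms share
none of the production code paths they test.  What they do *not* emulate:
photon noise statistics, anisotropic PSFs, chromatic shifts, nucleoli or
heterochromatin — so passing recovery tests demonstrates correctness of
the estimators, not robustness to every real-microscopy artifact.

## Problem sizes used by the validation suite

The in-silico experiments are scaled-down reproductions chosen to exercise
the full pipeline at desk scale: regime comparison over 20 seeds at 50×50
and 1440 s simulated (~7×10⁴ sweeps); inhibitor comparison on the 50×50
variant of the post-mitosis layout (25 chains of 50), 10 min relaxation +
10 min free transcription + 30 min inhibitor, with C/L time-averaged over
the last three snapshots; onset experiment over 12 runs with one-minute
snapshots; correlation-length recovery on 512² fields at targets 0.3, 0.5
and 1.0 µm (20 seeds each).  The full 100×100 scenario presets remain
available and identical in structure.

## Known limitations

* 2D only; no hydrodynamics; no sequence-specific loci; transcripts are
  unstructured counts.
* The swap-attempt clock has no independent physical calibration; only the
  sweeps-per-interval ratio is meaningful, and all length/time scales of
  the transport dynamics move with it.
* Surrogate parameters reproduce directions and orderings, not the study's
  numerical P values, which depend on unpublished parameter values and
  non-deposited micrographs.
* The exponential-decay model for g(r) is a summary, not a fit of a
  physical correlation model; for strongly periodic patterns the fitted
  L tracks domain width rather than spacing.
* Two long-time behaviors are out of reach of the scaled-down runs the
  validation suite performs.  (1) The unarrested phase-separation scenario
  coarsens extremely slowly once domains reach the microphase scale
  (droplet ripening with connected chains), so within ~10⁵ sweeps its
  median correlation length is statistically indistinguishable from the
  microphase steady state; the clear separation into a few large domains
  is a long-time limit.  (2) After the flavopiridol-like amphiphile
  removal, de-wetted domains first compact (reducing the fitted L, which
  tracks domain width) and only later merge; within a 30-minute window at
  the default transport calibration the two effects roughly cancel, so
  coarsening shows in the image contrast but not yet in L_corr.  A
  parameterization with twice the active fraction reverses this (L_corr
  rises significantly under flavopiridol) at the price of shrinking the
  microphase domains to the uniform-dispersion measurement floor; no
  single surrogate set exhibits both at these lattice scales and sweep
  budgets.
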