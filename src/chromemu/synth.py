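"""Synthetic phantoms with known ground truth.

The study's raw micrographs are not publicly deposited, so these generators
emulate their statistical structure for validation: stationary Gaussian
random fields with a prescribed exponential autocorrelation (so the fitted
correlation length has an exact target), disc-shaped nuclei whose DNA
texture carries a target contrast, an anti-correlated RNA channel (RNA
rich where DNA is poor), bright elongating-polymerase foci placed in
DNA-poor/RNA-rich pixels, and time-lapses in which two foci appear at a
known frame and locally deplete DNA.  Every generator is deterministic
under a fixed seed and returns machine-readable truth next to the pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .image import MultiChannelImage, NucleusMask

__all__ = [
    "PhantomTruth",
    "make_correlated_field",
    "make_nucleus_phantom",
    "make_foci_timelapse",
]


@dataclass
class PhantomTruth:
    """Ground truth attached to a generated phantom."""

    pixel_size_nm: float = 100.0
    l_corr_um: float = 0.5
    c_dna: float = 0.3
    background_offset: float = 0.0
    nucleus_radius_px: Optional[int] = None
    nucleus_center: Optional[Tuple[int, int]] = None
    rna_anticorrelation: float = 0.8
    n_foci: int = 2
    focus_sigma_px: float = 1.5
    focus_amplitude: float = 5.0
    foci: Optional[list] = None
    t0_frame: Optional[int] = None
    depletion_radius_px: Optional[int] = None

    def as_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)


def make_correlated_field(shape: Tuple[int, int], l_target_um: float, seed: int,
                          pixel_size_nm: float = 100.0) -> Tuple[np.ndarray, PhantomTruth]:
    """Stationary Gaussian random field with exponential autocorrelation.

    Synthesized spectrally (circulant embedding): the target autocovariance
    ``exp(-d / L)`` is sampled on the periodic grid, its FFT gives the power
    spectrum, and a white-noise field is colored with its square root.  The
    result has zero mean, unit variance, and autocorrelation matching the
    exponential target up to the (tiny) clipping of negative spectral
    weights.
    """
    l_px = l_target_um * 1000.0 / pixel_size_nm
    if l_px < 1.0:
        raise ValueError("target correlation length below the pixel size")
    ny, nx = shape
    fy = np.minimum(np.arange(ny), ny - np.arange(ny))
    fx = np.minimum(np.arange(nx), nx - np.arange(nx))
    d = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    cov = np.exp(-d / l_px)
    power = np.fft.fft2(cov).real
    power = np.clip(power, 0.0, None)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    fld = np.fft.ifft2(np.fft.fft2(noise) * np.sqrt(power)).real
    fld -= fld.mean()
    fld /= fld.std()
    truth = PhantomTruth(pixel_size_nm=pixel_size_nm, l_corr_um=l_target_um)
    return fld, truth


def field_as_image(field: np.ndarray, contrast: float = 0.25) -> np.ndarray:
    """Positive intensity image ``1 + contrast * field`` (clipped at 0)."""
    return np.clip(1.0 + contrast * field, 0.0, None)


def make_nucleus_phantom(truth: PhantomTruth, seed: int,
                         shape: Tuple[int, int] = (256, 256)):
    """Disc-shaped nucleus phantom with DNA / RNA / Ser2Phos channels.

    DNA inside the disc is ``1 + c * field`` with the field rescaled to zero
    mean and unit variance *within the disc*, so the in-mask coefficient of
    variation matches the target contrast; outside the disc the DNA channel
    holds the background offset.  RNA is a negatively coupled transform of
    the DNA field (correlation ``-rna_anticorrelation``) plus independent
    texture.  Ser2Phos holds small Gaussian foci placed at pixels in the
    lowest-DNA / highest-RNA quantile.  Returns
    ``(MultiChannelImage, NucleusMask, PhantomTruth)``.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    cy, cx = ny // 2, nx // 2
    radius = truth.nucleus_radius_px or int(0.4 * min(ny, nx))
    yy, xx = np.ogrid[0:ny, 0:nx]
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2

    fld, _ = make_correlated_field(shape, truth.l_corr_um, int(rng.integers(2**31)),
                                   truth.pixel_size_nm)
    fld = (fld - fld[disc].mean()) / fld[disc].std()
    other, _ = make_correlated_field(shape, truth.l_corr_um, int(rng.integers(2**31)),
                                     truth.pixel_size_nm)
    other = (other - other[disc].mean()) / other[disc].std()

    dna = np.full(shape, truth.background_offset, float)
    dna[disc] = np.clip(1.0 + truth.c_dna * fld[disc], 0.0, None)

    rho = truth.rna_anticorrelation
    rna_field = -rho * fld + np.sqrt(max(0.0, 1.0 - rho**2)) * other
    rna = np.full(shape, truth.background_offset, float)
    rna = np.where(disc, np.clip(1.0 + truth.c_dna * rna_field, 0.0, None), rna)

    ser2 = np.zeros(shape, float)
    inside = np.flatnonzero(disc.ravel())
    dna_in = dna.ravel()[inside]
    rna_in = rna.ravel()[inside]
    lo_dna = dna_in <= np.quantile(dna_in, 0.1)
    hi_rna = rna_in >= np.quantile(rna_in, 0.9)
    cand = inside[lo_dna & hi_rna]
    if cand.size == 0:
        cand = inside[lo_dna]
    picks = rng.choice(cand, size=min(truth.n_foci, cand.size), replace=False)
    foci = []
    for p in picks:
        py, px = divmod(int(p), nx)
        foci.append((py, px))
        ser2 += truth.focus_amplitude * np.exp(
            -(((yy - py) ** 2 + (xx - px) ** 2) / (2 * truth.focus_sigma_px**2))
        )
    out_truth = PhantomTruth(**{**truth.as_dict(), "foci": foci,
                                "nucleus_radius_px": radius,
                                "nucleus_center": (cy, cx)})
    img = MultiChannelImage(
        {"dna": dna, "rna": rna, "ser2phos": ser2},
        pixel_size_nm=truth.pixel_size_nm,
    )
    return img, NucleusMask(disc, provenance="ground_truth"), out_truth


def make_foci_timelapse(truth: PhantomTruth, n_frames: int, seed: int,
                        shape: Tuple[int, int, int] = (5, 64, 64),
                        t0: Optional[int] = None):
    """Time-lapse (T, Z, Y, X) in which two transcription foci appear.

    Before frame ``t0`` the Ser2Phos channel is noise only; from ``t0`` two
    Gaussian foci appear and grow linearly in amplitude, while DNA intensity
    within the depletion radius of each focus decays exponentially in time
    (euchromatin displaced by the forming RNA-rich pocket).  Returns
    ``(channels_dict, PhantomTruth)`` with 4D arrays.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    if t0 is None:
        t0 = truth.t0_frame if truth.t0_frame is not None else max(1, n_frames // 3)
    if not 0 < t0 < n_frames:
        raise ValueError("t0 must fall inside the time-lapse")
    rho = truth.depletion_radius_px or 4
    zc = nz // 2
    f1 = (zc, ny // 2, nx // 3)
    f2 = (zc, ny // 2, 2 * nx // 3)
    zz, yy, xx = np.ogrid[0:nz, 0:ny, 0:nx]
    dna0 = 1.0 + 0.05 * rng.standard_normal((nz, ny, nx))
    sig = truth.focus_sigma_px
    dna = np.empty((n_frames, nz, ny, nx))
    ser2 = np.empty_like(dna)
    rna = np.empty_like(dna)
    for t in range(n_frames):
        grow = max(0, t - t0 + 1)
        amp = truth.focus_amplitude * min(1.0, grow / 3.0) if t >= t0 else 0.0
        s = 0.02 * rng.standard_normal((nz, ny, nx))
        r = 0.02 * rng.standard_normal((nz, ny, nx))
        d = dna0 + 0.02 * rng.standard_normal((nz, ny, nx))
        for f in f1, f2:
            dist2 = ((zz - f[0]) ** 2 + (yy - f[1]) ** 2 + (xx - f[2]) ** 2)
            blob = np.exp(-dist2 / (2 * sig**2))
            s = s + amp * blob
            if t >= t0:
                # DNA displaced around the growing focus
                dep = 0.7 * (1 - np.exp(-grow / 3.0)) * (dist2 <= rho**2)
                d = d * (1 - dep)
                r = r + 0.5 * amp * np.exp(-dist2 / (2 * (2 * sig) ** 2))
        dna[t], ser2[t], rna[t] = d, s, r
    out = PhantomTruth(**{**truth.as_dict(), "t0_frame": int(t0),
                          "depletion_radius_px": rho,
                          "foci": [f1, f2]})
    return {"dna": dna, "ser2phos": ser2, "rna": rna}, out
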