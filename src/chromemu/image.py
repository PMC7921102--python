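"""Image quantification for nuclear organization.

Implements the full analysis used to compare micrographs and simulated
concentration profiles: Otsu-based nucleus segmentation with hole filling
and erosion, shell-based background-corrected intensities, image contrast
(coefficient of variation, with additive-offset correction), the
mask-aware radial correlation function and its exponential-decay fit
(correlation length L_corr), conditional intensity profiles/maps,
local-background subtraction, transcription-focus detection, Chebyshev-ring
radial profiles, live-cell nucleus segmentation/tracking, and temporal
alignment of per-nucleus radial profiles.

Conventions: 0-based pixel indices; centroids in continuous pixel
coordinates; ring membership by Chebyshev distance from the rounded
centroid; argmax ties resolve to the lowest index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import minimize_scalar
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import disk
from skimage.segmentation import watershed

__all__ = [
    "MultiChannelImage",
    "NucleusMask",
    "ContrastResult",
    "CorrelationCurve",
    "FitResult",
    "RingProfile",
    "RadialTimeProfile",
    "AlignedRadialProfile",
    "ConditionalProfile",
    "ConditionalMap",
    "LiveSegmentation",
    "Track",
    "segment_nucleus",
    "select_mid_section",
    "background_corrected_mean",
    "image_contrast",
    "radial_correlation",
    "fit_correlation_length",
    "conditional_profile",
    "conditional_map",
    "subtract_local_background",
    "detect_foci",
    "radial_ring_profile",
    "segment_live_nuclei",
    "track_nuclei",
    "align_average_profiles",
    "otsu_separability",
    "read_tiff",
    "write_tiff",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class MultiChannelImage:
    """Named intensity channels sharing one shape, with physical pixel size."""

    channels: Dict[str, np.ndarray]
    pixel_size_nm: float
    z_spacing_nm: Optional[float] = None
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("channels must share one shape")
        for name, c in self.channels.items():
            if not np.all(np.isfinite(c)):
                raise ValueError(f"channel {name!r} has non-finite intensities")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")

    @property
    def shape(self) -> Tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class NucleusMask:
    mask: np.ndarray
    provenance: str = "otsu"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)


@dataclass
class ContrastResult:
    c_dna: float
    mean: float
    sd: float
    offset: float
    correction: float

    @property
    def c_dna_corrected(self) -> float:
        return self.correction * self.c_dna


@dataclass
class CorrelationCurve:
    """g(r) sampled at integer pixel lags; r in micrometers."""

    radii_um: np.ndarray
    g: np.ndarray
    g_x: np.ndarray
    g_y: np.ndarray
    valid: np.ndarray
    pixel_size_nm: float


@dataclass
class FitResult:
    l_corr_um: float
    g0: float
    g_inf: float
    residual: float


@dataclass
class ConditionalProfile:
    centers: np.ndarray       # bin centers on the rescaled [0, 1] axis
    centers_raw: np.ndarray   # the same centers in raw channel-B units
    mean_a: np.ndarray
    counts: np.ndarray

    @property
    def empty(self) -> np.ndarray:
        return self.counts == 0


@dataclass
class ConditionalMap:
    centers_b: np.ndarray
    centers_c: np.ndarray
    mean_a: np.ndarray        # (bins_b, bins_c)
    counts: np.ndarray


@dataclass
class RingProfile:
    """Mean channel intensity on Chebyshev rings around one centroid."""

    rings: np.ndarray
    counts: np.ndarray
    means: Dict[str, np.ndarray]


@dataclass
class RadialTimeProfile:
    """Per-frame ring profiles for one tracked nucleus/transcription site."""

    rings: np.ndarray
    data: Dict[str, np.ndarray]          # channel -> (n_frames, n_rings)
    centroids: List[Optional[Tuple[float, ...]]]
    t0_index: Optional[int]              # first frame with two detected foci
    frame_interval_s: float = 1.0


@dataclass
class AlignedRadialProfile:
    rel_frames: np.ndarray
    rings: np.ndarray
    mean: Dict[str, np.ndarray]          # channel -> (n_rel, n_rings), NaN where no data
    n: np.ndarray                        # contributing profiles per rel frame


@dataclass
class LiveSegmentation:
    labels: Optional[np.ndarray]
    mitotic: bool
    otsu_metric: float


@dataclass
class Track:
    frames: List[int]
    labels: List[int]
    centroids: List[Tuple[float, ...]]


# ---------------------------------------------------------------------------
# segmentation


def segment_nucleus(dna_image: np.ndarray, erosion_radius: int = 3) -> NucleusMask:
    """Otsu threshold on the DNA channel, fill holes, erode.

    Erosion removes boundary imperfections (out-of-focus light) before
    structural statistics are computed.
    """
    img = np.asarray(dna_image, float)
    if img.max() == img.min():
        raise ValueError("constant image: Otsu threshold undefined")
    th = threshold_otsu(img)
    mask = img > th
    mask = ndi.binary_fill_holes(mask)
    if erosion_radius > 0:
        mask = ndi.binary_erosion(mask, structure=disk(erosion_radius))
    if not mask.any():
        raise ValueError("segmentation mask empty after erosion")
    return NucleusMask(mask, provenance="otsu")


def select_mid_section(stack: np.ndarray) -> Tuple[np.ndarray, int]:
    """Select the z-section with the highest mean intensity (ties -> lowest
    index); approximates the nuclear mid-section."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack, 0
    means = stack.reshape(stack.shape[0], -1).mean(axis=1)
    z = int(np.argmax(means))
    return stack[z], z


def background_corrected_mean(channel: np.ndarray, mask: Union[NucleusMask, np.ndarray],
                              shell_width: int = 5) -> float:
    """In-mask mean minus the mean over an outward dilation shell.

    The shell (dilated mask minus mask) samples the local surroundings
    (cytoplasm) as the background estimate.
    """
    m = mask.mask if isinstance(mask, NucleusMask) else np.asarray(mask, bool)
    shell = ndi.binary_dilation(m, structure=disk(shell_width)) & ~m
    if not shell.any():
        raise ValueError("empty background shell")
    channel = np.asarray(channel, float)
    return float(channel[m].mean() - channel[shell].mean())


# ---------------------------------------------------------------------------
# contrast


def image_contrast(channel: np.ndarray, mask: Union[NucleusMask, np.ndarray],
                   offset: float = 0.0) -> ContrastResult:
    """Root-mean-square image contrast of in-mask pixels.

    ``C = sd / mean`` with the sample standard deviation (1/(N-1)); this is
    the coefficient of variation of the pixel intensities.  An additive
    intensity offset changes the measured contrast by the factor
    ``a = mean / (mean + offset)``; ``c_dna_corrected`` applies it.
    """
    m = mask.mask if isinstance(mask, NucleusMask) else np.asarray(mask, bool)
    vals = np.asarray(channel, float)[m]
    if vals.size < 2:
        raise ValueError("mask must cover at least 2 pixels")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if mean + offset <= 0:
        raise ValueError("mean + offset must be positive")
    if mean == 0:
        raise ValueError("zero in-mask mean: contrast undefined")
    return ContrastResult(
        c_dna=sd / mean, mean=mean, sd=sd, offset=float(offset),
        correction=mean / (mean + offset),
    )


# ---------------------------------------------------------------------------
# radial correlation and L_corr


def radial_correlation(channel: np.ndarray, mask: Union[NucleusMask, np.ndarray],
                       pixel_size_nm: float,
                       max_lag_px: Optional[int] = None) -> CorrelationCurve:
    """Mask-aware radial correlation function of one channel.

    The channel is first normalized by its in-mask mean and the in-mask mean
    of the normalized image is subtracted.  For a lag of ``s`` pixels,

        g_x(s) = sum(sigma*J * shifted(sigma*J)) / sum(sigma * shifted(sigma))

    with one-sided shifts along x (axis 1), likewise g_y along y (axis 0),
    and g = (g_x + g_y) / 2, evaluated at r = 0, l, 2l, ... with l the pixel
    size.  Lags whose denominator vanishes are flagged invalid.
    Pixels outside the mask never contribute.
    """
    m = mask.mask if isinstance(mask, NucleusMask) else np.asarray(mask, bool)
    if not m.any():
        raise ValueError("empty mask")
    I = np.asarray(channel, float)
    mu = I[m].mean()
    if mu == 0:
        raise ValueError("zero in-mask mean")
    J = I / mu
    J = J - J[m].mean()
    S = m.astype(float)
    SJ = S * J
    ny, nx = m.shape
    if max_lag_px is None:
        max_lag_px = min(ny, nx) - 1
    max_lag_px = min(max_lag_px, min(ny, nx) - 1)
    n = max_lag_px + 1
    gx = np.full(n, np.nan)
    gy = np.full(n, np.nan)
    d0 = S.sum()
    gx[0] = gy[0] = (SJ * J)[m].sum() / d0 if d0 else np.nan
    for s in range(1, n):
        den = (S[:, :-s] * S[:, s:]).sum()
        if den > 0:
            gx[s] = (SJ[:, :-s] * SJ[:, s:]).sum() / den
        den = (S[:-s, :] * S[s:, :]).sum()
        if den > 0:
            gy[s] = (SJ[:-s, :] * SJ[s:, :]).sum() / den
    g = (gx + gy) / 2.0
    valid = np.isfinite(g)
    radii = np.arange(n) * pixel_size_nm / 1000.0
    return CorrelationCurve(radii, g, gx, gy, valid, pixel_size_nm)


def fit_correlation_length(curve: CorrelationCurve,
                           plateau_range_um: Tuple[float, float] = (2.0, 3.5),
                           fit_range_um: Optional[Tuple[float, float]] = None) -> FitResult:
    """Fit ``f(r) = g_inf + (g0 - g_inf) * exp(-r / L_corr)`` to g(r).

    ``g0`` is pinned to g(0); ``g_inf`` to the mean of g(r) over the plateau
    window (2.0-3.5 um by default); least squares optimizes only L_corr over
    the fit range.  The default fit range [0, 1.5 um] weights the decaying
    part of the curve (the plateau region already enters through g_inf);
    extending the range into the plateau window systematically biases the
    fitted length downward for decay lengths approaching 1 um.  Lags
    flagged invalid are excluded.
    """
    if fit_range_um is None:
        fit_range_um = (0.0, 1.5)
    r = curve.radii_um
    g = curve.g
    ok = curve.valid
    if not (ok & (r >= plateau_range_um[0]) & (r <= plateau_range_um[1])).any():
        raise ValueError("curve does not cover the plateau range")
    if not ok[0]:
        raise ValueError("g(0) undefined")
    g0 = float(g[0])
    sel_p = ok & (r >= plateau_range_um[0]) & (r <= plateau_range_um[1])
    g_inf = float(g[sel_p].mean())
    if np.isclose(g0, g_inf):
        raise ValueError("no decay: g0 equals the plateau level")
    sel = ok & (r >= fit_range_um[0]) & (r <= fit_range_um[1])
    rf, gf = r[sel], g[sel]

    def sse(L):
        pred = g_inf + (g0 - g_inf) * np.exp(-rf / L)
        return float(((pred - gf) ** 2).sum())

    l_px = curve.pixel_size_nm / 1000.0
    res = minimize_scalar(sse, bounds=(l_px / 10.0, 100.0), method="bounded",
                          options={"xatol": 1e-6})
    return FitResult(float(res.x), g0, g_inf, float(res.fun))


# ---------------------------------------------------------------------------
# conditional intensity analysis


def _rescale_in_mask(channel: np.ndarray, m: np.ndarray) -> Tuple[np.ndarray, float, float]:
    vals = channel[m]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return np.zeros_like(channel, float), lo, hi
    return (channel - lo) / (hi - lo), lo, hi


def conditional_profile(channel_a: np.ndarray, channel_b: np.ndarray,
                        mask: Union[NucleusMask, np.ndarray],
                        bins: int = 20) -> ConditionalProfile:
    """Mean of channel A over in-mask pixels binned by channel-B intensity.

    Channel B is rescaled to its in-mask [0, 1] range before binning (so bin
    centers are comparable across images); ``centers_raw`` maps them back to
    raw units.  Empty bins are flagged.
    """
    m = mask.mask if isinstance(mask, NucleusMask) else np.asarray(mask, bool)
    A = np.asarray(channel_a, float)
    B = np.asarray(channel_b, float)
    Bn, lo, hi = _rescale_in_mask(B, m)
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(Bn[m], edges) - 1, 0, bins - 1)
    sums = np.bincount(idx, weights=A[m], minlength=bins)
    counts = np.bincount(idx, minlength=bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (edges[:-1] + edges[1:]) / 2
    return ConditionalProfile(centers, lo + centers * (hi - lo), means, counts)


def conditional_map(channel_a: np.ndarray, channel_b: np.ndarray,
                    channel_c: np.ndarray, mask: Union[NucleusMask, np.ndarray],
                    bins_b: int = 20, bins_c: int = 20) -> ConditionalMap:
    """Mean of channel A binned jointly by channels B and C (2D binning)."""
    m = mask.mask if isinstance(mask, NucleusMask) else np.asarray(mask, bool)
    A = np.asarray(channel_a, float)
    Bn, lob, hib = _rescale_in_mask(np.asarray(channel_b, float), m)
    Cn, loc, hic = _rescale_in_mask(np.asarray(channel_c, float), m)
    eb = np.linspace(0.0, 1.0, bins_b + 1)
    ec = np.linspace(0.0, 1.0, bins_c + 1)
    ib = np.clip(np.digitize(Bn[m], eb) - 1, 0, bins_b - 1)
    ic = np.clip(np.digitize(Cn[m], ec) - 1, 0, bins_c - 1)
    flat = ib * bins_c + ic
    sums = np.bincount(flat, weights=A[m], minlength=bins_b * bins_c)
    counts = np.bincount(flat, minlength=bins_b * bins_c)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return ConditionalMap(
        (eb[:-1] + eb[1:]) / 2, (ec[:-1] + ec[1:]) / 2,
        means.reshape(bins_b, bins_c), counts.reshape(bins_b, bins_c),
    )


# ---------------------------------------------------------------------------
# foci and radial analysis


def subtract_local_background(image: np.ndarray, pixel_size_nm: float,
                              sigma_um: float = 2.38) -> np.ndarray:
    """Subtract a broadly Gaussian-blurred copy (sigma 2.38 um by default)
    from the image; removes slowly varying background, may yield negatives."""
    sigma_px = sigma_um * 1000.0 / pixel_size_nm
    img = np.asarray(image, float)
    return img - ndi.gaussian_filter(img, sigma_px, mode="reflect")


def detect_foci(channel: np.ndarray, n_keep: int = 2) -> List[Tuple[float, ...]]:
    """Detect the ``n_keep`` largest bright objects (transcription sites).

    Otsu threshold, connected components, keep the largest objects by
    pixel/voxel count; returns centroids (largest first).  Raises when fewer
    than ``n_keep`` objects exist ("no two foci yet").  Works on 2D images
    and 3D stacks.
    """
    img = np.asarray(channel, float)
    if img.max() == img.min():
        raise ValueError("constant channel: no foci")
    th = threshold_otsu(img)
    lbl = sk_label(img > th)
    nlab = int(lbl.max())
    if nlab < n_keep:
        raise ValueError(f"found {nlab} objects, need {n_keep}")
    sizes = np.bincount(lbl.ravel())[1:]
    order = np.argsort(sizes)[::-1][:n_keep] + 1
    cents = ndi.center_of_mass(img > th, lbl, order)
    return [tuple(float(v) for v in c) for c in cents]


def radial_ring_profile(channels: Union[MultiChannelImage, Dict[str, np.ndarray]],
                        centroid: Sequence[float], max_range: int) -> RingProfile:
    """Mean channel intensity on Chebyshev rings around a centroid.

    Range 0 is the pixel containing the (rounded) centroid; range r marks
    the next line of outward-lying 8-neighborhood pixels, so an unobstructed
    interior ring r holds 8r pixels (rings are clipped at image borders).
    Rings tile the image without overlap.
    """
    ch = channels.channels if isinstance(channels, MultiChannelImage) else channels
    shape = next(iter(ch.values())).shape
    cy, cx = int(round(centroid[0])), int(round(centroid[1]))
    if not (0 <= cy < shape[0] and 0 <= cx < shape[1]):
        raise ValueError("centroid outside image")
    yy, xx = np.ogrid[0:shape[0], 0:shape[1]]
    cheb = np.maximum(np.abs(yy - cy), np.abs(xx - cx))
    rings = np.arange(max_range + 1)
    counts = np.zeros(max_range + 1, int)
    means = {name: np.full(max_range + 1, np.nan) for name in ch}
    for r in rings:
        sel = cheb == r
        counts[r] = int(sel.sum())
        if counts[r]:
            for name, arr in ch.items():
                means[name][r] = float(arr[sel].mean())
    return RingProfile(rings, counts, means)


# ---------------------------------------------------------------------------
# live-cell segmentation, tracking, alignment


def otsu_separability(values: np.ndarray) -> Tuple[float, float]:
    """Otsu threshold and its separability measure.

    The measure is the between-class variance at the threshold divided by
    the total variance (in [0, 1]); it quantifies how well a single
    threshold splits the intensity distribution.
    """
    vals = np.asarray(values, float).ravel()
    th = threshold_otsu(vals)
    lo = vals[vals <= th]
    hi = vals[vals > th]
    tot = vals.var()
    if tot == 0 or lo.size == 0 or hi.size == 0:
        return float(th), 0.0
    w0 = lo.size / vals.size
    w1 = 1.0 - w0
    eta = w0 * w1 * (lo.mean() - hi.mean()) ** 2 / tot
    return float(th), float(eta)


def segment_live_nuclei(stack: np.ndarray, otsu_metric_threshold: float = 0.65,
                        min_distance: int = 5) -> LiveSegmentation:
    """Two-stage Otsu segmentation of nuclei in a live-cell z-stack.

    Stage 1 separates cells (nucleus + cytoplasm signal) from background;
    stage 2 thresholds within the cells to separate nuclei from cytoplasm.
    When the stage-2 separability metric is >= the threshold the frame is
    classified mitotic (the nuclear pool has been released to the
    cytoplasm) and no nuclei are returned.  Touching nuclei are split by a
    watershed initiated from the maxima of the 3D distance-to-background
    transform.
    """
    from skimage.feature import peak_local_max

    img = np.asarray(stack, float)
    if img.max() == img.min():
        raise ValueError("constant stack")
    t1 = threshold_otsu(img)
    cells = img > t1
    if not cells.any():
        raise ValueError("empty cell mask")
    t2, metric = otsu_separability(img[cells])
    if metric >= otsu_metric_threshold:
        return LiveSegmentation(labels=None, mitotic=True, otsu_metric=metric)
    nuclei = cells & (img > t2)
    if not nuclei.any():
        return LiveSegmentation(labels=None, mitotic=True, otsu_metric=metric)
    dist = ndi.distance_transform_edt(nuclei)
    peaks = peak_local_max(dist, min_distance=min_distance, labels=sk_label(nuclei),
                           exclude_border=False)
    markers = np.zeros_like(dist, int)
    for i, p in enumerate(peaks, start=1):
        markers[tuple(p)] = i
    labels = watershed(-dist, markers, mask=nuclei)
    return LiveSegmentation(labels=labels, mitotic=False, otsu_metric=metric)


def track_nuclei(label_volumes: Sequence[Optional[np.ndarray]],
                 max_distance: float = np.inf, gap: int = 0) -> List[Track]:
    """Greedy nearest-centroid linking of segmented nuclei through time.

    Unmatched labels start new tracks; a track missing for more than ``gap``
    frames is closed (a later reappearance starts a new track).  Frames with
    ``None`` labels (e.g. mitosis) contribute no centroids.
    """
    tracks: List[Track] = []
    open_tracks: List[Track] = []
    for t, vol in enumerate(label_volumes):
        cents: List[Tuple[int, Tuple[float, ...]]] = []
        if vol is not None and vol.max() > 0:
            ids = [int(i) for i in np.unique(vol) if i > 0]
            for i, c in zip(ids, ndi.center_of_mass(vol > 0, vol, ids)):
                cents.append((i, tuple(float(v) for v in c)))
        # drop stale tracks
        still = []
        for tr in open_tracks:
            if t - tr.frames[-1] > gap + 1:
                tracks.append(tr)
            else:
                still.append(tr)
        open_tracks = still
        # greedy matching by ascending distance
        pairs = []
        for ti, tr in enumerate(open_tracks):
            last = np.asarray(tr.centroids[-1])
            for ci, (_, c) in enumerate(cents):
                d = float(np.linalg.norm(last - np.asarray(c)))
                if d <= max_distance:
                    pairs.append((d, ti, ci))
        pairs.sort()
        used_t, used_c = set(), set()
        for d, ti, ci in pairs:
            if ti in used_t or ci in used_c:
                continue
            used_t.add(ti)
            used_c.add(ci)
            lab, c = cents[ci]
            tr = open_tracks[ti]
            tr.frames.append(t)
            tr.labels.append(lab)
            tr.centroids.append(c)
        for ci, (lab, c) in enumerate(cents):
            if ci not in used_c:
                open_tracks.append(Track([t], [lab], [c]))
    tracks.extend(open_tracks)
    return tracks


def align_average_profiles(profiles: Sequence[RadialTimeProfile]) -> AlignedRadialProfile:
    """Average radial-time profiles after aligning each at its t0.

    t0 is the first frame at which two transcription foci were detected;
    profiles without a defined t0 are excluded.  Averages are per (relative
    frame, ring) over the profiles contributing at that relative frame;
    cells with no contribution are NaN.
    """
    usable = [p for p in profiles if p.t0_index is not None]
    if not usable:
        raise ValueError("no profile with a defined t0")
    rings = usable[0].rings
    channels = list(usable[0].data)
    lo = min(-p.t0_index for p in usable)
    hi = max(p.data[channels[0]].shape[0] - p.t0_index for p in usable)
    rel = np.arange(lo, hi)
    n_rel = rel.size
    sums = {c: np.zeros((n_rel, rings.size)) for c in channels}
    cnts = {c: np.zeros((n_rel, rings.size)) for c in channels}
    n_contrib = np.zeros(n_rel, int)
    for p in usable:
        T = p.data[channels[0]].shape[0]
        for f in range(T):
            k = f - p.t0_index - lo
            n_contrib[k] += 1
            for c in channels:
                row = p.data[c][f]
                ok = np.isfinite(row)
                sums[c][k, ok] += row[ok]
                cnts[c][k, ok] += 1
    mean = {}
    for c in channels:
        with np.errstate(invalid="ignore"):
            mean[c] = np.where(cnts[c] > 0, sums[c] / np.maximum(cnts[c], 1), np.nan)
    return AlignedRadialProfile(rel, rings, mean, n_contrib)


# ---------------------------------------------------------------------------
# TIFF IO


def read_tiff(path, pixel_size_nm: Optional[float] = None,
              channel_names: Optional[Sequence[str]] = None) -> MultiChannelImage:
    """Read a (C, Y, X) or (Y, X) TIFF into a :class:`MultiChannelImage`.

    Pixel size is taken from the CLI/keyword when given; otherwise from the
    file's resolution metadata if present.
    """
    import json

    import tifffile

    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = None
        if tf.shaped_metadata:
            meta = tf.shaped_metadata[0]
        elif tf.imagej_metadata:
            meta = tf.imagej_metadata
    if arr.ndim == 2:
        arr = arr[None]
    if channel_names is None:
        if meta and "channel_names" in meta:
            names = meta["channel_names"]
            if isinstance(names, str):
                names = json.loads(names)
            channel_names = list(names)
        else:
            channel_names = [f"ch{i}" for i in range(arr.shape[0])]
    if pixel_size_nm is None:
        if meta and "pixel_size_nm" in meta:
            pixel_size_nm = float(meta["pixel_size_nm"])
        else:
            raise ValueError("pixel size not in metadata; pass pixel_size_nm")
    channels = {n: arr[i].astype(float) for i, n in enumerate(channel_names)}
    return MultiChannelImage(channels, pixel_size_nm)


def write_tiff(img: MultiChannelImage, path) -> None:
    import json

    import tifffile

    names = list(img.channels)
    data = np.stack([img.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(
        path, data,
        metadata={"pixel_size_nm": img.pixel_size_nm,
                  "channel_names": json.dumps(names)},
    )
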