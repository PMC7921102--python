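"""Render lattice snapshots into microscopy-like concentration profiles.

One lattice site maps to one pixel of 100 nm; each channel is smoothed with
a Gaussian of physical width sigma (120 nm to compare with STED, 450 nm with
spinning-disk, 150 nm with live-cell recordings).  The blur uses reflective
boundaries, which conserves total channel mass exactly for the normalized
symmetric kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
from scipy.ndimage import gaussian_filter

from .image import MultiChannelImage
from .lattice import SimulationState

__all__ = ["RenderConfig", "render_profile", "BLUR_PRESETS_NM"]

#: named blur widths (nm) matching the microscope modalities
BLUR_PRESETS_NM = {"sted": 120.0, "spinning_disk": 450.0, "live": 150.0}


@dataclass(frozen=True)
class RenderConfig:
    pixel_size_nm: float = 100.0
    blur_sigma_nm: float = 120.0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0 or self.blur_sigma_nm <= 0:
            raise ValueError("pixel size and blur sigma must be > 0")

    @property
    def sigma_px(self) -> float:
        return self.blur_sigma_nm / self.pixel_size_nm


def render_profile(snapshot: SimulationState, config: RenderConfig = RenderConfig()) -> MultiChannelImage:
    """Convert a lattice snapshot into a blurred multi-channel image.

    Channels: ``dna`` = indicator of chromatin sites, ``rna`` = per-site
    transcript count, ``ser2phos`` = indicator of transcriptionally active
    chromatin.  The returned image carries the pixel size and a mask covering
    the full interior lattice region.
    """
    if snapshot.width == 0 or snapshot.height == 0:
        raise ValueError("empty snapshot")
    raw: Dict[str, np.ndarray] = {
        "dna": snapshot.chromatin_mask().astype(np.float64),
        "rna": snapshot.rna_counts().astype(np.float64),
        "ser2phos": snapshot.active_mask().astype(np.float64),
    }
    channels = {
        name: gaussian_filter(arr, sigma=config.sigma_px, mode="reflect")
        for name, arr in raw.items()
    }
    mask = np.ones((snapshot.height, snapshot.width), bool)
    return MultiChannelImage(channels=channels, pixel_size_nm=config.pixel_size_nm,
                             mask=mask)
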