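"""Proximity-ligation-assay quantification.

Two read-outs: corrected total cell fluorescence (CTCF) of the PLA signal
in transfected cells, and per-image PLA spot counts in neurons, detected
as intensity maxima whose prominence exceeds a noise tolerance and
normalised to the mean synaptophysin intensity of the same image (which
accounts for culture-density variation across coverslips).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label
from skimage.morphology import local_maxima

from .imaging import ROI


@dataclass
class CTCFResult:
    integrated_density: float
    cell_area_px: int
    background_mean: float

    @property
    def ctcf(self) -> float:
        """Exact identity: integrated density − cell area × background mean.
        May legitimately be negative and is reported as-is."""
        return self.integrated_density - self.cell_area_px * self.background_mean


@dataclass
class PLACount:
    spot_count: int
    syp_mean_intensity: float

    @property
    def norm_pla(self) -> float:
        return self.spot_count / self.syp_mean_intensity


def ctcf(
    image: np.ndarray,
    cell_roi: ROI,
    background_rois: list[ROI],
    pixel_size: float = 1.0,
) -> CTCFResult:
    """Corrected total cell fluorescence of one cell.

    Integrated density is the pixel sum over the cell ROI; the background
    mean is the per-pixel mean over the (disjoint) background ROIs.
    """
    img = np.asarray(image, dtype=float)
    if not background_rois:
        raise ValueError("at least one background ROI is required")
    cell_mask = cell_roi.mask(img.shape, pixel_size)
    bg_mask = np.zeros(img.shape, dtype=bool)
    for roi in background_rois:
        bg_mask |= roi.mask(img.shape, pixel_size)
    if (cell_mask & bg_mask).any():
        raise ValueError("background ROIs overlap the cell ROI")
    if not cell_mask.any() or not bg_mask.any():
        raise ValueError("empty ROI after rasterisation")
    return CTCFResult(
        integrated_density=float(img[cell_mask].sum()),
        cell_area_px=int(cell_mask.sum()),
        background_mean=float(img[bg_mask].mean()),
    )


def default_noise_tolerance(image: np.ndarray, k: float = 5.0) -> float:
    """Noise tolerance from the robust background SD (MAD/0.6745) × k."""
    img = np.asarray(image, dtype=float)
    sd = np.median(np.abs(img - np.median(img))) / 0.6745
    return float(k * sd)


def count_pla_spots(pla_channel: np.ndarray, noise_tolerance: float) -> int:
    """Count intensity maxima with prominence above ``noise_tolerance``.

    A regional maximum of height v is counted when, within the connected
    superlevel set {f >= v − tolerance}, no brighter pixel is reachable —
    i.e. its height above the highest saddle leading to a larger maximum
    exceeds the tolerance.  Maxima touching the 1-pixel image border are
    excluded, and connected maxima of equal height count once.
    """
    if noise_tolerance < 0:
        raise ValueError("noise tolerance must be non-negative")
    img = np.asarray(pla_channel, dtype=float)
    if img.size == 0 or np.ptp(img) == 0:
        return 0
    peaks = local_maxima(img, connectivity=2)
    # exclude the 1-pixel border, mirroring the reference routine
    peaks[0, :] = peaks[-1, :] = False
    peaks[:, 0] = peaks[:, -1] = False
    if not peaks.any():
        return 0
    plateau_labels = label(peaks, connectivity=2)
    vmin = float(img.min())
    counted: set[tuple[float, int]] = set()
    components_cache: dict[float, np.ndarray] = {}
    for region_id in range(1, plateau_labels.max() + 1):
        ys, xs = np.nonzero(plateau_labels == region_id)
        v = float(img[ys[0], xs[0]])
        if v - vmin <= noise_tolerance:
            # even the global maximum must stand out by more than the
            # tolerance above the image floor
            continue
        comp = components_cache.get(v)
        if comp is None:
            comp = label(img >= v - noise_tolerance, connectivity=2)
            components_cache[v] = comp
        cid = int(comp[ys[0], xs[0]])
        if img[comp == cid].max() <= v:
            counted.add((v, cid))
    return len(counted)


def normalize_pla(spot_count: int, syp_channel: np.ndarray) -> PLACount:
    """Normalise the spot count to the mean synaptophysin grey value."""
    mean = float(np.asarray(syp_channel, dtype=float).mean())
    if mean <= 0:
        raise ValueError("zero synaptophysin mean: image excluded")
    return PLACount(spot_count=int(spot_count), syp_mean_intensity=mean)
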