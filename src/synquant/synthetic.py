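"""Ground-truthed synthetic data for every assay in the package.

Each generator draws from a single seeded NumPy generator, returns the
simulated measurement object together with an exact ground-truth record,
and is deterministic given identical parameters and seed.  Defaults are
chosen to emulate the corresponding real preparations: dissociated
hippocampal cultures at ~12 DIV (sparse neurites, sub-µm synaptic puncta,
synapse densities of a few tenths per µm dendrite), whole-cell mEPSC
recordings (10 kHz sampling, ~1 Hz event rates, −20 pA-scale events with
millisecond rise and ~10 ms decay), MEA cultures with quasi-periodic
network bursts riding on sparse tonic firing, and EM profiles of boutons
(~1 µm² terminal area, ~50 nm vesicles, a docked pool near the active
zone).  Two-condition designs are expressed as multiplicative factors on
density, rate or intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import brentq

from .em import VesicleAnnotation
from .geometry import point_to_polyline_distance, points_in_polygon, shoelace_area
from .imaging import FieldOfView
from .mea import SpikeTrain
from .minis import CurrentTrace

# ---------------------------------------------------------------------------
# parameter records


@dataclass
class ImagingSimParams:
    """Conditions for synthetic 2-D synapse fields (lengths in µm)."""

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.12
    n_neurites: int = 4
    neurite_width: float = 1.0
    cell_body_radius: float = 4.0
    puncta_density_per_um: float = 0.35
    coloc_fraction: float = 0.8
    punctum_radius: float = 0.25
    punctum_intensity_mean: float = 120.0
    punctum_intensity_sd: float = 25.0
    background_level: float = 10.0
    noise_sd: float = 4.0
    psf_sigma: float = 0.15
    condition_effects: dict = field(
        default_factory=lambda: {
            "control": {"density": 1.0, "intensity": 1.0},
            "knockdown": {"density": 0.75, "intensity": 1.0},
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must be in [0, 1]")
        for name in ("pixel_size", "neurite_width", "cell_body_radius",
                     "punctum_radius", "psf_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.punctum_intensity_mean < 0 or self.background_level < 0:
            raise ValueError("intensities must be non-negative")
        min_side = min(self.image_shape) * self.pixel_size
        if self.n_neurites > 0 and min_side < 6 * self.cell_body_radius:
            raise ValueError("image too small for the requested neurite layout")


@dataclass
class TraceSimParams:
    """Conditions for synthetic mEPSC current traces."""

    sampling_rate: float = 10_000.0
    duration: float = 120.0
    event_rate: float = 1.0
    amplitude_mean: float = -22.0   # pA, negative-going
    amplitude_sd: float = 4.0
    rise_tau: float = 1.0           # ms
    decay_tau: float = 8.0          # ms
    baseline_noise_sd: float = 2.0  # pA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.event_rate < 0 or self.duration < 0:
            raise ValueError("rates and duration must be non-negative")
        if not self.decay_tau > self.rise_tau > 0:
            raise ValueError("requires decay_tau > rise_tau > 0")


@dataclass
class RasterSimParams:
    """Conditions for synthetic MEA spike rasters."""

    n_channels: int = 12
    duration: float = 300.0
    tonic_rate: float = 0.4          # Hz per channel
    burst_rate: float = 1.0 / 7.3    # network bursts per second (array-wide)
    intra_burst_rate: float = 100.0  # Hz within a burst
    burst_length: float = 0.3        # s
    channel_jitter_sd: float = 0.02  # s
    participation_fraction: float = 0.9
    interval_shape: float = 5.0      # gamma shape of the inter-burst renewal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channel_jitter_sd < 0:
            raise ValueError("jitter must be non-negative")
        if not 0.0 <= self.participation_fraction <= 1.0:
            raise ValueError("participation_fraction must be in [0, 1]")


@dataclass
class VesicleSimParams:
    """Conditions for synthetic EM vesicle annotations."""

    terminal_area: float = 1.2        # µm²
    vesicle_density: float = 120.0    # vesicles/µm²
    docked_fraction: float = 0.15
    vesicle_diameter_mean: float = 50.0  # nm
    vesicle_diameter_sd: float = 5.0
    docking_radius: float = 125.0     # nm, placement target for the docked pool
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vesicle_density < 0 or self.terminal_area <= 0:
            raise ValueError("densities and areas must be non-negative")
        if not 0.0 <= self.docked_fraction <= 1.0:
            raise ValueError("docked_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# imaging fields


@dataclass
class FieldTruth:
    """Exact ground truth for one synthetic field."""

    table: pd.DataFrame             # one row per punctum site
    n_pairs: int
    skeleton_length_um: float       # pixel-count convention (matches measurement)
    euclidean_length_um: float
    condition: str
    seed: int


def _splat(image: np.ndarray, y: float, x: float, mass: float) -> None:
    """Bilinear deposit of ``mass`` at a subpixel position."""
    y0, x0 = int(np.floor(y)), int(np.floor(x))
    fy, fx = y - y0, x - x0
    h, w = image.shape
    for dy, wy in ((0, 1 - fy), (1, fy)):
        for dx, wx in ((0, 1 - fx), (1, fx)):
            yy, xx = y0 + dy, x0 + dx
            if 0 <= yy < h and 0 <= xx < w:
                image[yy, xx] += mass * wy * wx


def _random_walk(rng, shape, start, max_steps, turn_sd=0.04, margin=10):
    """Gently curving 2-D walk from ``start``, ending at the image border.

    The initial heading points roughly across the field and the per-step
    turning is small, so a neurite never doubles back onto itself — real
    dendrite stretches in a field of view are locally smooth, and a
    self-overlapping path would be unresolvable once rendered at the
    stated width.
    """
    h, w = shape
    pos = np.array(start, dtype=float)
    center = np.array([h / 2, w / 2])
    to_center = center - pos
    theta = np.arctan2(to_center[0], to_center[1]) + rng.uniform(-0.7, 0.7)
    path = [pos.copy()]
    for _ in range(max_steps):
        theta += rng.normal(0, turn_sd)
        pos = pos + np.array([np.sin(theta), np.cos(theta)])
        if not (margin <= pos[0] <= h - margin and margin <= pos[1] <= w - margin):
            break
        path.append(pos.copy())
    return np.array(path)


def _raster(path, shape):
    iy = np.clip(np.round(path[:, 0]).astype(int), 0, shape[0] - 1)
    ix = np.clip(np.round(path[:, 1]).astype(int), 0, shape[1] - 1)
    out = np.zeros(shape, dtype=bool)
    out[iy, ix] = True
    return out


def gen_neuron_field(
    params: ImagingSimParams, condition: str = "control"
) -> tuple[FieldOfView, FieldTruth]:
    """Synthesise a MAP2/presynaptic/postsynaptic field with ground truth.

    Neurites are smoothed random walks of the stated width emanating from
    disc-shaped cell bodies.  Punctum sites are placed along the neurite
    paths at the condition-scaled linear density with a minimum spacing of
    three punctum radii; a site is a matched pre/post pair with
    probability ``coloc_fraction`` (the partners offset by one pixel),
    otherwise alternately pre-only or post-only.  Channels are rendered as
    Gaussian spots, blurred by the PSF and degraded with Gaussian read
    noise on a constant background.
    """
    effects = params.condition_effects.get(condition, {"density": 1.0, "intensity": 1.0})
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    px = params.pixel_size

    body_r_px = params.cell_body_radius / px
    margin = int(body_r_px + 8)
    paths = []
    origins = []
    steps_per_neurite = int(0.9 * (h + w) / 2)
    width_px = max(1, int(round(params.neurite_width / px)))
    from skimage.morphology import disk, dilation

    # draw neurites one by one, rejecting walks that run for long
    # stretches alongside an existing one: parallel sub-resolution runs
    # would be unresolvable in the rendered image, whereas steep crossings
    # (which real neurites do make) touch only briefly
    occupancy = np.zeros((h, w), dtype=bool)
    for _ in range(params.n_neurites):
        best_path, best_frac = None, np.inf
        for _try in range(15):
            origin = rng.uniform(margin, [h - margin, w - margin])
            path = _random_walk(rng, (h, w), origin, steps_per_neurite)
            raster = _raster(path, (h, w))
            frac = (raster & occupancy).sum() / raster.sum()
            if frac < best_frac:
                best_path, best_frac, best_origin = path, frac, origin
            if frac < 0.05:
                break
        paths.append(best_path)
        origins.append(best_origin)
        occupancy |= dilation(_raster(best_path, (h, w)), disk(2 * width_px))

    # cell-body mask
    yy, xx = np.mgrid[0:h, 0:w]
    body_mask = np.zeros((h, w), dtype=bool)
    for oy, ox in origins:
        body_mask |= (yy - oy) ** 2 + (xx - ox) ** 2 <= body_r_px**2

    # skeleton raster outside cell bodies (the measured-length convention)
    skel = np.zeros((h, w), dtype=bool)
    for path in paths:
        iy = np.clip(np.round(path[:, 0]).astype(int), 0, h - 1)
        ix = np.clip(np.round(path[:, 1]).astype(int), 0, w - 1)
        skel[iy, ix] = True
    skel_outside = skel & ~body_mask
    skeleton_length_um = float(skel_outside.sum()) * px
    euclidean_length_um = sum(len(p) - 1 for p in paths) * px

    # neurite area mask: dilate the skeleton to the stated width
    half_width_px = max(1, int(round(params.neurite_width / px / 2)))
    neurite_area = dilation(skel, disk(half_width_px))

    # ---- punctum sites along the paths
    density = params.puncta_density_per_um * effects.get("density", 1.0)
    all_path = np.vstack(paths)
    n_sites = int(round(density * euclidean_length_um))
    min_sep_px = 3 * params.punctum_radius / px
    sites = []
    attempts = 0
    while len(sites) < n_sites and attempts < 50 * n_sites + 100:
        attempts += 1
        cand = all_path[rng.integers(0, len(all_path))]
        if body_mask[int(round(cand[0])), int(round(cand[1]))]:
            continue
        if sites and np.min(np.linalg.norm(np.array(sites) - cand, axis=1)) < min_sep_px:
            continue
        sites.append(cand)
    sites = np.array(sites) if sites else np.empty((0, 2))

    matched = rng.random(len(sites)) < params.coloc_fraction
    kinds = np.where(matched, "pair", "")
    unmatched_idx = np.flatnonzero(~matched)
    for j, idx in enumerate(unmatched_idx):
        kinds[idx] = "pre_only" if j % 2 == 0 else "post_only"

    intensity_mean = params.punctum_intensity_mean * effects.get("intensity", 1.0)
    sigma_blob_px = params.punctum_radius / 2 / px
    sigma_psf_px = params.psf_sigma / px
    sigma_total = float(np.hypot(sigma_blob_px, sigma_psf_px))
    pre_img = np.zeros((h, w))
    post_img = np.zeros((h, w))

    rows = []
    for i, (site, kind) in enumerate(zip(sites, kinds)):
        row = {"site_id": i, "kind": kind,
               "pre_y_um": np.nan, "pre_x_um": np.nan,
               "post_y_um": np.nan, "post_x_um": np.nan,
               "pre_amplitude": np.nan, "post_amplitude": np.nan}
        if kind in ("pair", "pre_only"):
            amp = max(rng.normal(intensity_mean, params.punctum_intensity_sd),
                      0.2 * intensity_mean)
            mass = amp * 2 * np.pi * sigma_total**2
            _splat(pre_img, site[0], site[1], mass)
            row.update(pre_y_um=site[0] * px, pre_x_um=site[1] * px, pre_amplitude=amp)
        if kind in ("pair", "post_only"):
            if kind == "pair":
                ang = rng.uniform(0, 2 * np.pi)
                ppos = site + np.array([np.sin(ang), np.cos(ang)])  # 1 px offset
            else:
                ppos = site
            amp = max(rng.normal(intensity_mean, params.punctum_intensity_sd),
                      0.2 * intensity_mean)
            mass = amp * 2 * np.pi * sigma_total**2
            _splat(post_img, ppos[0], ppos[1], mass)
            row.update(post_y_um=ppos[0] * px, post_x_um=ppos[1] * px, post_amplitude=amp)
        rows.append(row)
    truth_table = pd.DataFrame(
        rows, columns=["site_id", "kind", "pre_y_um", "pre_x_um",
                       "post_y_um", "post_x_um", "pre_amplitude", "post_amplitude"]
    )

    pre_img = ndi.gaussian_filter(pre_img, sigma_total)
    post_img = ndi.gaussian_filter(post_img, sigma_total)

    map2 = np.where(neurite_area, 80.0, 0.0) + np.where(body_mask, 150.0, 0.0)
    map2 = ndi.gaussian_filter(map2, sigma_psf_px)

    def finish(img):
        out = img + params.background_level + rng.normal(0, params.noise_sd, (h, w))
        return np.clip(out, 0, None)

    fov = FieldOfView(
        channels={"MAP2": finish(map2), "pre": finish(pre_img), "post": finish(post_img)},
        pixel_size=px,
        metadata={"condition": condition, "seed": params.seed},
    )
    truth = FieldTruth(
        table=truth_table,
        n_pairs=int(np.sum(kinds == "pair")),
        skeleton_length_um=skeleton_length_um,
        euclidean_length_um=euclidean_length_um,
        condition=condition,
        seed=params.seed,
    )
    return fov, truth


def gen_tissue_section(
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.12,
    n_pairs: int = 50,
    n_pre_only: int = 10,
    n_post_only: int = 10,
    punctum_radius: float = 0.25,
    intensity_mean: float = 120.0,
    intensity_sd: float = 25.0,
    background_level: float = 10.0,
    noise_sd: float = 4.0,
    psf_sigma: float = 0.15,
    seed: int = 0,
) -> tuple[FieldOfView, pd.DataFrame]:
    """Dual-stained tissue field: matched pre/post pairs scattered
    uniformly (no neurite geometry), for ROI-normalised density work."""
    rng = np.random.default_rng(seed)
    h, w = shape
    margin = 8
    sigma_total = float(np.hypot(punctum_radius / 2 / pixel_size, psf_sigma / pixel_size))
    pre_img = np.zeros((h, w))
    post_img = np.zeros((h, w))
    min_sep = 3 * punctum_radius / pixel_size
    pts: list[np.ndarray] = []
    total = n_pairs + n_pre_only + n_post_only
    attempts = 0
    while len(pts) < total and attempts < 200 * total + 100:
        attempts += 1
        cand = rng.uniform(margin, [h - margin, w - margin])
        if pts and np.min(np.linalg.norm(np.array(pts) - cand, axis=1)) < min_sep:
            continue
        pts.append(cand)
    rows = []
    for i, p in enumerate(pts):
        kind = "pair" if i < n_pairs else ("pre_only" if i < n_pairs + n_pre_only else "post_only")
        if kind in ("pair", "pre_only"):
            amp = max(rng.normal(intensity_mean, intensity_sd), 0.2 * intensity_mean)
            _splat(pre_img, p[0], p[1], amp * 2 * np.pi * sigma_total**2)
        if kind in ("pair", "post_only"):
            off = p if kind == "post_only" else p + rng.normal(0, 0.7, 2)
            amp = max(rng.normal(intensity_mean, intensity_sd), 0.2 * intensity_mean)
            _splat(post_img, off[0], off[1], amp * 2 * np.pi * sigma_total**2)
        rows.append({"site_id": i, "kind": kind,
                     "y_um": p[0] * pixel_size, "x_um": p[1] * pixel_size})
    pre_img = ndi.gaussian_filter(pre_img, sigma_total)
    post_img = ndi.gaussian_filter(post_img, sigma_total)

    def finish(img):
        return np.clip(img + background_level + rng.normal(0, noise_sd, (h, w)), 0, None)

    fov = FieldOfView(
        channels={"pre": finish(pre_img), "post": finish(post_img)},
        pixel_size=pixel_size,
        metadata={"seed": seed},
    )
    return fov, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# current traces


def mepsc_kernel_peak_time(rise_tau_ms: float, decay_tau_ms: float) -> float:
    """Time-to-peak (ms) of (1 − e^{−t/τr}) e^{−t/τd}."""
    return rise_tau_ms * np.log((rise_tau_ms + decay_tau_ms) / rise_tau_ms)


def mepsc_kernel(t_ms: np.ndarray, rise_tau_ms: float, decay_tau_ms: float) -> np.ndarray:
    """Biexponential event kernel normalised to unit peak."""
    t = np.asarray(t_ms, dtype=float)
    raw = (1.0 - np.exp(-t / rise_tau_ms)) * np.exp(-t / decay_tau_ms)
    tp = mepsc_kernel_peak_time(rise_tau_ms, decay_tau_ms)
    peak = (1.0 - np.exp(-tp / rise_tau_ms)) * np.exp(-tp / decay_tau_ms)
    out = raw / peak
    out[t < 0] = 0.0
    return out


def mepsc_kernel_rise_10_90(rise_tau_ms: float, decay_tau_ms: float) -> float:
    """Exact 10–90% rise time (ms) of the normalised kernel."""
    tp = mepsc_kernel_peak_time(rise_tau_ms, decay_tau_ms)

    def f(t, level):
        return mepsc_kernel(np.array([t]), rise_tau_ms, decay_tau_ms)[0] - level

    t10 = brentq(f, 1e-9, tp, args=(0.1,))
    t90 = brentq(f, t10, tp, args=(0.9,))
    return t90 - t10


def gen_current_trace(params: TraceSimParams) -> tuple[CurrentTrace, pd.DataFrame]:
    """Poisson-timed mEPSC train on Gaussian baseline noise.

    Each event is the biexponential kernel scaled to its (negative) peak
    amplitude; the ground-truth table lists onset, amplitude and the
    kernel's exact 10–90 rise time and decay constant per event.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    n = int(round(params.duration * fs))
    trace = rng.normal(0.0, params.baseline_noise_sd, n)
    n_events = rng.poisson(params.event_rate * params.duration)
    onsets = np.sort(rng.uniform(0, params.duration, n_events))
    amps = rng.normal(params.amplitude_mean, params.amplitude_sd, n_events)
    amps = np.minimum(amps, -10.0)  # truncate: sub-threshold events are not modelled
    rise_10_90 = mepsc_kernel_rise_10_90(params.rise_tau, params.decay_tau)
    kernel_len = int(min((params.decay_tau * 8e-3) * fs, n))
    t_ms = np.arange(kernel_len) / fs * 1e3
    kernel = mepsc_kernel(t_ms, params.rise_tau, params.decay_tau)
    for onset, amp in zip(onsets, amps):
        i0 = int(round(onset * fs))
        seg = min(kernel_len, n - i0)
        if seg > 0:
            trace[i0:i0 + seg] += amp * kernel[:seg]
    truth = pd.DataFrame(
        {
            "onset_s": onsets,
            "amplitude_pA": amps,
            "rise_tau_ms": params.rise_tau,
            "decay_tau_ms": params.decay_tau,
            "rise_10_90_ms": rise_10_90,
        }
    )
    return CurrentTrace(trace, fs), truth


# ---------------------------------------------------------------------------
# spike rasters


def gen_spike_raster(
    params: RasterSimParams,
) -> tuple[list[SpikeTrain], dict]:
    """Multi-channel raster with channel-synchronised network bursts.

    Array-wide burst onsets follow a gamma renewal process (shape
    ``interval_shape``, mean interval ``1/burst_rate``); each channel
    joins a burst with ``participation_fraction``, its onset jittered by a
    Gaussian of ``channel_jitter_sd``; within-burst spikes are Poisson at
    ``intra_burst_rate`` over ``burst_length``, on top of tonic Poisson
    firing.  Ground truth records the scheduled array onsets and every
    per-channel burst window.
    """
    rng = np.random.default_rng(params.seed)
    onsets = []
    if params.burst_rate > 0:
        t = rng.uniform(1.0, 2.0)
        mean_iv = 1.0 / params.burst_rate
        while True:
            if t > params.duration - params.burst_length - 0.5:
                break
            onsets.append(t)
            t += rng.gamma(params.interval_shape, mean_iv / params.interval_shape)
    onsets = np.asarray(onsets)

    trains = []
    burst_rows = []
    for ch in range(params.n_channels):
        spikes = []
        if params.tonic_rate > 0:
            n_tonic = rng.poisson(params.tonic_rate * params.duration)
            spikes.append(rng.uniform(0, params.duration, n_tonic))
        for k, onset in enumerate(onsets):
            if rng.random() > params.participation_fraction:
                continue
            ch_onset = onset + rng.normal(0, params.channel_jitter_sd)
            n_burst = rng.poisson(params.intra_burst_rate * params.burst_length)
            if n_burst == 0:
                continue
            burst_spikes = np.sort(
                ch_onset + rng.uniform(0, params.burst_length, n_burst)
            )
            spikes.append(burst_spikes)
            burst_rows.append(
                {
                    "channel": f"ch{ch:02d}",
                    "network_burst_id": k,
                    "onset_s": ch_onset,
                    "first_spike_s": burst_spikes[0],
                    "last_spike_s": burst_spikes[-1],
                    "n_spikes": n_burst,
                }
            )
        all_spikes = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
        all_spikes = all_spikes[(all_spikes >= 0) & (all_spikes <= params.duration)]
        trains.append(SpikeTrain(f"ch{ch:02d}", all_spikes))

    truth = {
        "network_onsets_s": onsets,
        "mean_interval_s": float(np.mean(np.diff(onsets))) if len(onsets) >= 2 else float("nan"),
        "bursts": pd.DataFrame(
            burst_rows, columns=["channel", "network_burst_id", "onset_s",
                                 "first_spike_s", "last_spike_s", "n_spikes"]
        ),
    }
    return trains, truth


# ---------------------------------------------------------------------------
# vesicle annotations


def _random_terminal_polygon(rng, area_um2: float) -> np.ndarray:
    """Irregular convex polygon (nm coordinates) scaled to a target area."""
    n_vert = 8
    # jittered regular angles keep the polygon star-shaped about the
    # origin, hence always simple
    angles = (np.arange(n_vert) + rng.uniform(-0.35, 0.35, n_vert)) * 2 * np.pi / n_vert
    radii = rng.uniform(0.7, 1.3, n_vert)
    verts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    current = shoelace_area(verts)
    target_nm2 = area_um2 * 1e6
    verts *= np.sqrt(target_nm2 / current)
    return verts


def gen_vesicle_annotation(
    params: VesicleSimParams, synapse_id: str = "syn0"
) -> tuple[VesicleAnnotation, pd.DataFrame]:
    """Vesicle point cloud in a random terminal with a docked pool.

    The presynaptic membrane is a stretch of the terminal boundary (three
    consecutive vertices).  A ``docked_fraction`` of vesicles is placed
    within the docking radius of that polyline; the remainder are uniform
    in the terminal.  Ground truth stores each centre's exact distance to
    the membrane.
    """
    rng = np.random.default_rng(params.seed)
    poly = _random_terminal_polygon(rng, params.terminal_area)
    # membrane: the boundary stretch around the lowest vertex
    low = int(np.argmin(poly[:, 1]))
    idx = [(low - 1) % len(poly), low, (low + 1) % len(poly)]
    membrane = poly[idx]

    n_total = rng.poisson(params.vesicle_density * params.terminal_area)
    n_docked = int(round(params.docked_fraction * n_total))
    centroid = poly.mean(axis=0)
    lo, hi = poly.min(axis=0), poly.max(axis=0)

    centers = []
    # docked pool: points near the membrane polyline, inside the terminal
    seg_len = np.linalg.norm(np.diff(membrane, axis=0), axis=1)
    seg_cum = np.concatenate([[0], np.cumsum(seg_len)])
    while len(centers) < n_docked:
        s = rng.uniform(0, seg_cum[-1])
        k = min(np.searchsorted(seg_cum, s, side="right") - 1, len(seg_len) - 1)
        frac = (s - seg_cum[k]) / seg_len[k]
        on_line = membrane[k] + frac * (membrane[k + 1] - membrane[k])
        inward = centroid - on_line
        inward = inward / np.linalg.norm(inward)
        cand = on_line + inward * rng.uniform(2.0, params.docking_radius - 3.0)
        if points_in_polygon(cand, poly)[0]:
            centers.append(cand)
    # reserve pool: uniform in the polygon by rejection
    while len(centers) < n_total:
        cand = rng.uniform(lo, hi)
        if points_in_polygon(cand, poly)[0]:
            centers.append(cand)
    centers = np.asarray(centers) if centers else np.empty((0, 2))
    diameters = rng.normal(params.vesicle_diameter_mean, params.vesicle_diameter_sd,
                           n_total)
    diameters = np.clip(diameters, 20.0, None)

    ann = VesicleAnnotation(synapse_id, poly, membrane, centers, diameters)
    dist = (point_to_polyline_distance(centers, membrane)
            if n_total else np.empty(0))
    truth = pd.DataFrame(
        {
            "x_nm": centers[:, 0] if n_total else [],
            "y_nm": centers[:, 1] if n_total else [],
            "diameter_nm": diameters,
            "distance_nm": dist,
            "docked": dist <= params.docking_radius if n_total else [],
        }
    )
    return ann, truth
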