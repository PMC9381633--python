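"""Electron-microscopy vesicle-pool quantification.

Works on point annotations of single synaptic profiles: a terminal outline
(polygon), the presynaptic membrane at the active zone (polyline), and
vesicle centres with diameters, all in nanometres.  Reported quantities are
the synaptic-vesicle density per terminal area and the number of docked
vesicles, defined as vesicles lying within a fixed radius (default 125 nm)
of the presynaptic membrane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import point_to_polyline_distance, shoelace_area, validate_polygon

#: docking criterion: maximal centre-to-membrane distance in nm
DOCKING_RADIUS_NM = 125.0

#: plausible synaptic-vesicle diameters in nm (nominal ~50 nm); anything
#: outside is treated as an endosome/vacuole and excluded from counts
DEFAULT_DIAMETER_BAND_NM = (30.0, 70.0)


@dataclass
class VesicleAnnotation:
    """Point annotation of one synaptic profile (all coordinates in nm)."""

    synapse_id: str
    terminal_polygon: np.ndarray      # (N, 2) nm
    membrane_polyline: np.ndarray     # (M, 2) nm
    centers: np.ndarray               # (K, 2) nm vesicle centres
    diameters: np.ndarray             # (K,) nm
    valid: np.ndarray = field(default=None)  # (K,) bool, set by validate_vesicles

    def __post_init__(self) -> None:
        self.terminal_polygon = np.asarray(self.terminal_polygon, dtype=float)
        self.membrane_polyline = np.asarray(self.membrane_polyline, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        self.diameters = np.asarray(self.diameters, dtype=float).reshape(-1)
        validate_polygon(self.terminal_polygon)
        if self.membrane_polyline.ndim != 2 or self.membrane_polyline.shape[0] < 2:
            raise ValueError("membrane polyline needs at least 2 vertices")
        if len(self.diameters) != len(self.centers):
            raise ValueError("centers and diameters length mismatch")
        if np.any(self.diameters <= 0):
            raise ValueError("vesicle diameters must be positive")
        if self.valid is None:
            self.valid = np.ones(len(self.centers), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool).reshape(-1)

    @property
    def n_total(self) -> int:
        return len(self.centers)


@dataclass
class VesicleCounts:
    """Per-synapse quantification result."""

    synapse_id: str
    n_vesicles: int           # valid vesicles
    terminal_area_um2: float
    sv_density_per_um2: float
    n_docked: int
    n_valid_diameter: int


def validate_vesicles(
    ann: VesicleAnnotation,
    diameter_band: tuple[float, float] = DEFAULT_DIAMETER_BAND_NM,
) -> VesicleAnnotation:
    """Flag vesicles whose diameter falls outside ``diameter_band`` (nm).

    Returns a new annotation with the ``valid`` mask set; flagged vesicles
    are excluded from all downstream counts.
    """
    lo, hi = diameter_band
    if not lo < hi:
        raise ValueError("diameter band must satisfy low < high")
    valid = (ann.diameters >= lo) & (ann.diameters <= hi)
    return replace(ann, valid=valid)


def terminal_area_um2(ann: VesicleAnnotation) -> float:
    """Terminal polygon area converted from nm² to µm²."""
    return shoelace_area(ann.terminal_polygon) / 1e6


def sv_density(ann: VesicleAnnotation) -> VesicleCounts:
    """Synaptic-vesicle density: valid vesicle count per terminal area (µm²)."""
    area = terminal_area_um2(ann)
    if area <= 0:
        raise ValueError("terminal polygon has zero area")
    n_valid = int(ann.valid.sum())
    return VesicleCounts(
        synapse_id=ann.synapse_id,
        n_vesicles=n_valid,
        terminal_area_um2=area,
        sv_density_per_um2=n_valid / area,
        n_docked=count_docked(ann),
        n_valid_diameter=n_valid,
    )


def vesicle_membrane_distances(ann: VesicleAnnotation) -> np.ndarray:
    """Centre-to-membrane distance (nm) of every vesicle, valid or not."""
    if len(ann.centers) == 0:
        return np.empty(0)
    return point_to_polyline_distance(ann.centers, ann.membrane_polyline)


def count_docked(
    ann: VesicleAnnotation,
    radius_nm: float = DOCKING_RADIUS_NM,
    from_edge: bool = False,
) -> int:
    """Count valid vesicles within ``radius_nm`` of the presynaptic membrane.

    ``from_edge=True`` measures from the membrane-proximal vesicle edge
    (centre distance minus diameter/2) instead of the centre.
    """
    if radius_nm <= 0:
        raise ValueError("docking radius must be positive")
    if len(ann.centers) == 0:
        return 0
    dist = vesicle_membrane_distances(ann)
    if from_edge:
        dist = dist - ann.diameters / 2.0
    return int(np.sum(ann.valid & (dist <= radius_nm)))


def summarize_em(
    annotations_by_group: dict[str, list[VesicleAnnotation]],
    radius_nm: float = DOCKING_RADIUS_NM,
    diameter_band: tuple[float, float] = DEFAULT_DIAMETER_BAND_NM,
    from_edge: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-synapse table and group-level summary of vesicle-pool metrics.

    Returns
    -------
    per_synapse : DataFrame
        One row per synapse: group, synapse_id, n_vesicles, terminal area,
        SV density (/µm²) and docked count.
    groups : DataFrame
        One row per group with n, mean/median SV density and docked count,
        plus the box-whisker statistics (Q1/Q3/min/max) of the density.
    """
    rows = []
    for group, anns in annotations_by_group.items():
        if not anns:
            raise ValueError(f"group {group!r} has no annotations")
        for ann in anns:
            ann = validate_vesicles(ann, diameter_band)
            counts = sv_density(ann)
            rows.append(
                {
                    "group": group,
                    "synapse_id": counts.synapse_id,
                    "n_vesicles": counts.n_vesicles,
                    "terminal_area_um2": counts.terminal_area_um2,
                    "sv_density_per_um2": counts.sv_density_per_um2,
                    "n_docked": count_docked(ann, radius_nm, from_edge),
                }
            )
    per_synapse = pd.DataFrame(rows)

    from .stats import box_whisker

    grows = []
    for group, sub in per_synapse.groupby("group", sort=False):
        bw = box_whisker(sub["sv_density_per_um2"].to_numpy())
        grows.append(
            {
                "group": group,
                "n_synapses": len(sub),
                "mean_sv_density": sub["sv_density_per_um2"].mean(),
                "median_sv_density": bw["median"],
                "q1_sv_density": bw["q1"],
                "q3_sv_density": bw["q3"],
                "min_sv_density": bw["min"],
                "max_sv_density": bw["max"],
                "mean_docked": sub["n_docked"].mean(),
                "median_docked": sub["n_docked"].median(),
            }
        )
    return per_synapse, pd.DataFrame(grows)
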