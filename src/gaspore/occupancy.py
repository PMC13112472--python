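"""Explicit-ligand (flooding) analysis.

Gas-probe trajectories are reduced to time-averaged occupancy histograms
along the pore axis; Boltzmann inversion against the bulk density gives
transfer free energies ΔG(z) = −RT ln(p_i/p_sol).  Also here: convergence
and fourfold-symmetry diagnostics, and the permeation-event state machine
(pore entries, exits, full crossings) with a debounce rule.

The counting region is a cylinder about the pore axis; the paper-scale
default radius is 5 Å and is always echoed in output headers because
occupancy counts depend on it.  Bulk densities are taken from z-slabs on
either side of the pore — by default restricted to the same cylinder
cross-section so that, for laterally confined systems, the ratio p_i/p_sol
reduces to the axial Boltzmann weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import RT, T_DEFAULT
from .core import Trajectory
from .grids import Profile1D

__all__ = [
    "PoreRegion",
    "OccupancyProfile",
    "EventRecord",
    "EventCounts",
    "bin_occupancy",
    "free_energy_from_occupancy",
    "occupancy_free_energy",
    "convergence_check",
    "symmetry_check",
    "count_events",
]


@dataclass(frozen=True)
class PoreRegion:
    """Cylindrical counting region about the +z pore axis with bulk slabs.

    ``bulk_top``/``bulk_bottom`` are (z_lo, z_hi) slabs disjoint from the
    cylinder span.  ``bulk_in_cylinder`` restricts bulk counting to the
    cylinder cross-section (default); set False to count the full box
    cross-section (requires a trajectory box).
    """

    center_xy: tuple[float, float] = (0.0, 0.0)
    cylinder_radius: float = 5.0
    z_bottom: float = -10.0
    z_top: float = 10.0
    bulk_top: tuple[float, float] = (12.0, 18.0)
    bulk_bottom: tuple[float, float] = (-18.0, -12.0)
    bulk_in_cylinder: bool = True

    def __post_init__(self) -> None:
        if self.z_top <= self.z_bottom:
            raise ValueError("z_top must exceed z_bottom")
        if self.cylinder_radius <= 0:
            raise ValueError("cylinder_radius must be positive")
        for name, (lo, hi) in (("bulk_top", self.bulk_top), ("bulk_bottom", self.bulk_bottom)):
            if hi <= lo:
                raise ValueError(f"{name} slab must be increasing")
            if lo < self.z_top and hi > self.z_bottom:
                raise ValueError(f"{name} slab overlaps the cylinder span")

    def classify(self, xyz: np.ndarray) -> np.ndarray:
        """State per point: 0=bulk_top, 1=pore, 2=bulk_bottom, 3=elsewhere."""
        xyz = np.asarray(xyz, dtype=float)
        x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
        in_cyl = (x - self.center_xy[0]) ** 2 + (y - self.center_xy[1]) ** 2 <= self.cylinder_radius**2
        state = np.full(z.shape, 3, dtype=int)
        state[(z >= self.bulk_top[0]) & (z <= self.bulk_top[1])] = 0
        state[(z >= self.bulk_bottom[0]) & (z <= self.bulk_bottom[1])] = 2
        state[in_cyl & (z >= self.z_bottom) & (z <= self.z_top)] = 1
        return state


STATE_NAMES = ("bulk_top", "pore", "bulk_bottom", "elsewhere")


@dataclass
class OccupancyProfile:
    """Binned pore occupancy with its bulk reference density."""

    edges: np.ndarray  # (n_bins+1,) Å
    counts: np.ndarray  # (n_bins,) observations over all frames
    p_i: np.ndarray  # per-Å³ time-averaged density per bin
    p_sol: float  # per-Å³ bulk density
    bulk_counts: float
    n_frames: int
    bin_volume: float  # Å³
    region: PoreRegion

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


def bin_occupancy(
    traj: Trajectory, region: PoreRegion, bin_width: float = 0.5
) -> OccupancyProfile:
    """Histogram probe positions inside the pore cylinder into z-bins.

    Probe positions are the trajectory's per-"atom" coordinates (one probe
    per column; pass molecular centers of mass for multi-site probes).
    Densities are per Å³; the bulk density comes from the region's bulk
    slabs.  Zero bulk counts raise — the profile cannot be referenced.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    pos = traj.positions.reshape(-1, 3)
    if not np.all(np.isfinite(pos)):
        raise ValueError("trajectory contains non-finite probe positions")
    cx, cy = region.center_xy
    in_cyl = (pos[:, 0] - cx) ** 2 + (pos[:, 1] - cy) ** 2 <= region.cylinder_radius**2
    z = pos[:, 2]

    span = region.z_top - region.z_bottom
    n_bins = int(np.ceil(span / bin_width - 1e-9))
    edges = region.z_bottom + np.arange(n_bins + 1) * bin_width
    in_pore = in_cyl & (z >= edges[0]) & (z < edges[-1])
    counts, _ = np.histogram(z[in_pore], bins=edges)

    area_cyl = np.pi * region.cylinder_radius**2
    if region.bulk_in_cylinder:
        bulk_mask = in_cyl
        area_bulk = area_cyl
    else:
        if traj.box is None:
            raise ValueError("bulk_in_cylinder=False requires a trajectory box")
        bulk_mask = np.ones(z.shape, dtype=bool)
        area_bulk = float(traj.box[0][0] * traj.box[0][1])
    bulk_height = 0.0
    bulk_counts = 0.0
    for lo, hi in (region.bulk_bottom, region.bulk_top):
        bulk_counts += float(np.count_nonzero(bulk_mask & (z >= lo) & (z <= hi)))
        bulk_height += hi - lo
    if bulk_counts == 0:
        raise ValueError("no probe observations in the bulk slabs; cannot reference")

    n_frames = traj.n_frames
    bin_volume = area_cyl * bin_width
    p_i = counts / (n_frames * bin_volume)
    p_sol = bulk_counts / (n_frames * area_bulk * bulk_height)
    return OccupancyProfile(
        edges=edges,
        counts=counts.astype(float),
        p_i=p_i,
        p_sol=p_sol,
        bulk_counts=bulk_counts,
        n_frames=n_frames,
        bin_volume=bin_volume,
        region=region,
    )


def free_energy_from_occupancy(
    profile: OccupancyProfile, temperature: float = T_DEFAULT
) -> Profile1D:
    """Boltzmann inversion ΔG(z) = −RT ln(p_i/p_sol), kcal/mol.

    Zero-count bins are reported as lower bounds (the free energy a single
    half-count would imply) and flagged — they are never interpolated.
    Per-bin errors are the Poisson propagation RT·√(1/n_i + 1/n_bulk).
    """
    if profile.p_sol <= 0:
        raise ValueError("bulk density must be positive")
    rt = RT(temperature)
    counts = profile.counts
    with np.errstate(divide="ignore"):
        dg = -rt * np.log(profile.p_i / profile.p_sol)
    zero = counts == 0
    if zero.any():
        p_bound = 0.5 / (profile.n_frames * profile.bin_volume)
        dg = np.where(zero, -rt * np.log(p_bound / profile.p_sol), dg)
    errors = rt * np.sqrt(
        np.where(zero, np.nan, 1.0 / np.maximum(counts, 1)) + 1.0 / profile.bulk_counts
    )
    return Profile1D(
        z=profile.centers,
        values=dg,
        errors=errors,
        flags=zero,
        label=f"occupancy inversion (cylinder r={profile.region.cylinder_radius} Å)",
    )


def occupancy_free_energy(
    traj: Trajectory,
    region: PoreRegion,
    bin_width: float = 0.5,
    temperature: float = T_DEFAULT,
) -> Profile1D:
    """Convenience: bin occupancy then invert to a free-energy profile."""
    return free_energy_from_occupancy(bin_occupancy(traj, region, bin_width), temperature)


def convergence_check(
    traj: Trajectory,
    region: PoreRegion,
    checkpoints: list[float],
    bin_width: float = 0.5,
    temperature: float = T_DEFAULT,
) -> pd.DataFrame:
    """Drift of the free-energy profile at intermediate time fractions.

    For each checkpoint fraction f of the trajectory, the profile from the
    first f·n_frames frames is compared with the full-trajectory profile
    over bins valid in both: max-abs and RMS deviation (kcal/mol) and the
    shift of the barrier location (Å).
    """
    if len(checkpoints) < 2:
        raise ValueError("need at least two checkpoints")
    full = occupancy_free_energy(traj, region, bin_width, temperature)
    rows = []
    for f in checkpoints:
        if not 0 < f <= 1:
            raise ValueError(f"checkpoint fraction {f} outside (0, 1]")
        n = max(1, int(round(f * traj.n_frames)))
        if n > traj.n_frames:
            raise ValueError("checkpoint beyond trajectory length")
        part = occupancy_free_energy(traj.slice_frames(0, n), region, bin_width, temperature)
        both = full.valid & part.valid
        if not both.any():
            raise ValueError(f"no overlapping valid bins at checkpoint {f}")
        diff = part.values[both] - full.values[both]
        z_full = full.z[both][np.argmax(full.values[both])]
        z_part = part.z[both][np.argmax(part.values[both])]
        rows.append(
            {
                "fraction": f,
                "n_frames": n,
                "max_abs_dev": float(np.max(np.abs(diff))),
                "rms_dev": float(np.sqrt(np.mean(diff**2))),
                "barrier_shift": float(abs(z_part - z_full)),
            }
        )
    return pd.DataFrame(rows)


def symmetry_check(
    traj: Trajectory,
    region: PoreRegion,
    n_fold: int = 4,
    grid_n: int = 16,
) -> float:
    """Rotational-asymmetry score of the in-pore (x, y) occupancy.

    The occupancy of the pore cylinder is histogrammed onto a square grid
    about the axis and compared with its k·(360°/n_fold) rotations:
    score = max_k RMS(rotated − original) / mean occupancy.  A fourfold-
    symmetric channel scores ≈ 0 (within counting noise); occupancy piled
    into one quadrant scores ≳ 1.
    """
    if 360 % (360 // n_fold) != 0 or n_fold < 2:
        raise ValueError("n_fold must be >= 2")
    if grid_n % 2 != 0:
        raise ValueError("grid_n must be even so rotations map bins onto bins")
    pos = traj.positions.reshape(-1, 3)
    cx, cy = region.center_xy
    r = region.cylinder_radius
    mask = (
        ((pos[:, 0] - cx) ** 2 + (pos[:, 1] - cy) ** 2 <= r**2)
        & (pos[:, 2] >= region.z_bottom)
        & (pos[:, 2] <= region.z_top)
    )
    if not mask.any():
        raise ValueError("no occupancy inside the pore region")
    H, _, _ = np.histogram2d(
        pos[mask, 0] - cx,
        pos[mask, 1] - cy,
        bins=grid_n,
        range=[[-r, r], [-r, r]],
    )
    if n_fold != 4:
        raise NotImplementedError("only fourfold rotation implemented on a square grid")
    mean = H.mean()
    score = 0.0
    rot = H
    for _ in range(n_fold - 1):
        rot = np.rot90(rot)
        score = max(score, float(np.sqrt(np.mean((rot - H) ** 2)) / mean))
    return score


@dataclass(frozen=True)
class EventRecord:
    """One permeation event of one ligand."""

    ligand: int
    type: str  # "entry", "exit", "full_crossing"
    direction: str  # "+z" or "-z"
    frame_start: int
    frame_end: int


@dataclass
class EventCounts:
    events: list[EventRecord]
    cumulative_entries: np.ndarray  # entries committed up to each frame
    n_entries: int
    n_crossings: int
    n_unique_entrants: int  # distinct ligands that entered at least once


def count_events(traj: Trajectory, region: PoreRegion, debounce: int = 1) -> EventCounts:
    """Count pore entries, exits and full crossings per ligand.

    Each ligand's track is classified per frame into {bulk_top, pore,
    bulk_bottom, elsewhere}; a state change must persist for ``debounce``
    consecutive frames to commit (default 1 = every visit counts).  An
    entry is a committed transition into the pore from either bulk slab; a
    full crossing is an entry from one bulk slab followed by a committed
    exit into the opposite slab.  Crossing direction follows the axis:
    top→bottom is "−z".
    """
    if debounce < 1:
        raise ValueError("debounce must be >= 1 frame")
    if not np.all(np.isfinite(traj.positions)):
        raise ValueError("broken ligand track: non-finite positions")
    states = region.classify(traj.positions)  # (n_frames, n_ligands)
    n_frames, n_lig = states.shape
    events: list[EventRecord] = []
    cumulative = np.zeros(n_frames, dtype=int)
    entrants: set[int] = set()
    for lig in range(n_lig):
        s = states[:, lig]
        confirmed = int(s[0])
        origin: int | None = confirmed if confirmed in (0, 2) else None
        cand = confirmed
        run = 0
        entry_frame = 0
        for f in range(1, n_frames):
            if s[f] == cand:
                run += 1
            else:
                cand = int(s[f])
                run = 1
            if cand != confirmed and run >= debounce:
                prev, confirmed = confirmed, cand
                commit_frame = f - debounce + 1
                if confirmed == 1 and prev in (0, 2):
                    direction = "-z" if prev == 0 else "+z"
                    events.append(
                        EventRecord(lig, "entry", direction, commit_frame, f)
                    )
                    cumulative[f:] += 1
                    entrants.add(lig)
                    origin = prev
                    entry_frame = commit_frame
                elif prev == 1 and confirmed in (0, 2):
                    direction = "-z" if confirmed == 2 else "+z"
                    if origin is not None and confirmed != origin:
                        events.append(
                            EventRecord(lig, "full_crossing", direction, entry_frame, f)
                        )
                    else:
                        events.append(EventRecord(lig, "exit", direction, entry_frame, f))
                    origin = confirmed
                elif confirmed in (0, 2):
                    origin = confirmed
                elif confirmed == 1:
                    # entered the pore from "elsewhere": not a counted entry,
                    # and it cannot seed a crossing
                    origin = None
    n_entries = sum(1 for e in events if e.type == "entry")
    n_crossings = sum(1 for e in events if e.type == "full_crossing")
    return EventCounts(
        events=events,
        cumulative_entries=cumulative,
        n_entries=n_entries,
        n_crossings=n_crossings,
        n_unique_entrants=len(entrants),
    )
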