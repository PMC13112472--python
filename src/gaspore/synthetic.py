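"""Synthetic systems with analytic ground truth.

Every input class the pipeline consumes can be generated here: channel-shaped
atom arrangements with known open radii, host-structure ensembles with
Gaussian thermal jitter, flooding trajectories of non-interacting gas probes
Boltzmann-sampled from an analytic potential, harmonically biased umbrella
window samples, and scripted trajectories with known permeation-event counts.
``oracle_profile`` is the deterministic quadrature reference that all
estimator-recovery tests compare against; it shares no code with the
estimators.

Samplers use Metropolis Monte Carlo: only equilibrium occupancies matter to
the estimators under test, so no integrator or timestep enters.  Probes do
not interact with each other (an idealization of a flooded box; real gas
molecules at high concentration do).  All samplers are reproducible under a
fixed seed; the first 10% of each chain is discarded as burn-in by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import RT, T_DEFAULT
from .core import Atom, Structure, Trajectory
from .grids import Profile1D
from .potentials import PotentialSpec
from .wham import UmbrellaWindow, WindowSet

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelRing",
    "ChannelSpec",
    "ResidueRing",
    "make_channel_structure",
    "make_channel_protein",
    "jittered_host_frames",
    "sample_flooding_trajectory",
    "sample_umbrella_windows",
    "scripted_crossing_trajectory",
    "oracle_profile",
]


# ---------------------------------------------------------------------------
# Channel-shaped structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelRing:
    """A ring of identical atoms at height ``z``: centers on a circle of
    ``ring_radius`` so the open pore radius at the ring plane is
    ring_radius − atom_vdw (up to ring discretization)."""

    z: float
    ring_radius: float
    n_atoms: int
    atom_vdw: float


@dataclass(frozen=True)
class ChannelSpec:
    rings: tuple[ChannelRing, ...]

    def __post_init__(self) -> None:
        if not self.rings:
            raise ValueError("ChannelSpec needs at least one ring")
        zs = [r.z for r in self.rings]
        if list(zs) != sorted(zs):
            raise ValueError("rings must be sorted by z")
        for r in self.rings:
            if r.n_atoms < 8:
                raise ValueError(
                    f"ring at z={r.z} has {r.n_atoms} atoms; need >= 8 to approximate a circle"
                )
            if r.ring_radius <= r.atom_vdw:
                raise ValueError(
                    f"ring at z={r.z}: ring_radius {r.ring_radius} <= atom_vdw {r.atom_vdw} leaves no pore"
                )


def make_channel_structure(spec: ChannelSpec) -> Structure:
    """Place atoms uniformly on each ring of the spec, axis = +z through (0,0)."""
    atoms: list[Atom] = []
    for ri, ring in enumerate(spec.rings):
        angles = 2 * np.pi * np.arange(ring.n_atoms) / ring.n_atoms
        for ai, th in enumerate(angles):
            atoms.append(
                Atom(
                    name="C",
                    element="C",
                    residue_name="RNG",
                    residue_id=ri + 1,
                    chain="A",
                    position=np.array(
                        [ring.ring_radius * math.cos(th), ring.ring_radius * math.sin(th), ring.z]
                    ),
                    vdw_radius=ring.atom_vdw,
                )
            )
    return Structure(atoms=atoms)


@dataclass(frozen=True)
class ResidueRing:
    """A ring of simplified residues around the pore at height ``z``.

    Each residue contributes backbone atoms (N, CA, C, O) near
    ``backbone_radius``, a CB at ``cb_radius``, and optional side-chain
    atoms projecting further toward the axis, given as (atom_name,
    distance-from-axis) pairs.  Used to build truncation-mutagenesis
    fixtures whose bulky side chains constrict a channel.
    """

    z: float
    residue_name: str
    residue_id: int
    n_residues: int = 4
    backbone_radius: float = 9.0
    cb_radius: float = 7.0
    sidechain: tuple[tuple[str, float], ...] = ()
    vdw: float = 1.7


def make_channel_protein(rings: Sequence[ResidueRing]) -> Structure:
    """Build a pseudo-protein channel from residue rings (axis = +z)."""
    atoms: list[Atom] = []
    chains = "ABCDEFGHIJKLMNOP"
    for ring in rings:
        for m in range(ring.n_residues):
            th = 2 * np.pi * m / ring.n_residues
            chain = chains[m % len(chains)]

            def place(name: str, radius: float, dth: float = 0.0, dz: float = 0.0) -> None:
                a = th + dth
                atoms.append(
                    Atom(
                        name=name,
                        element=name[0] if name[0] in "NCOS" else "C",
                        residue_name=ring.residue_name,
                        residue_id=ring.residue_id,
                        chain=chain,
                        position=np.array(
                            [radius * math.cos(a), radius * math.sin(a), ring.z + dz]
                        ),
                        vdw_radius=ring.vdw,
                    )
                )

            # slight angular/axial offsets keep bonded atoms non-collinear
            place("N", ring.backbone_radius, dth=+0.12, dz=+0.9)
            place("CA", ring.backbone_radius, dz=+0.45)
            place("C", ring.backbone_radius, dth=-0.12, dz=+1.0)
            place("O", ring.backbone_radius + 0.5, dth=-0.18, dz=+1.3)
            place("CB", ring.cb_radius, dz=0.0)
            for k, (name, radius) in enumerate(ring.sidechain):
                place(name, radius, dth=0.06 * (k + 1), dz=-0.35 * (k + 1))
    return Structure(atoms=atoms)


# ---------------------------------------------------------------------------
# Host-frame jitter
# ---------------------------------------------------------------------------


def jittered_host_frames(
    structure: Structure, sigma: float, n_frames: int, seed: int = 0
) -> Trajectory:
    """An ensemble of host conformations: i.i.d. Gaussian displacement of
    every atom in every frame (sigma = 0 gives identical frames)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    base = structure.positions
    noise = rng.normal(0.0, sigma, size=(n_frames, *base.shape)) if sigma > 0 else 0.0
    positions = np.broadcast_to(base, (n_frames, *base.shape)) + noise
    return Trajectory(positions=np.ascontiguousarray(positions, dtype=float))


# ---------------------------------------------------------------------------
# Metropolis samplers
# ---------------------------------------------------------------------------


def _metropolis(
    u_of_x,
    x0: np.ndarray,
    n_record: int,
    rng: np.random.Generator,
    proposal_width: float,
    burn_in_fraction: float,
    stride: int,
) -> tuple[np.ndarray, float]:
    """Vectorized Metropolis over independent chains.

    ``x0`` is (n_chains, d); returns (n_record, n_chains, d) samples and the
    post-burn-in acceptance rate.  The proposal width is auto-tuned during
    burn-in toward ~40% acceptance.
    """
    x = np.array(x0, dtype=float)
    u = u_of_x(x)
    n_chains = x.shape[0]
    total_record_steps = n_record * stride
    burn = max(50, int(round(burn_in_fraction * total_record_steps / max(1 - burn_in_fraction, 1e-9))))
    w = proposal_width
    out = np.empty((n_record, *x.shape))
    accepted = 0
    proposed = 0
    tune_acc = 0
    tune_n = 0
    rec = 0
    step_in_stride = 0
    for step in range(burn + total_record_steps):
        prop = x + rng.normal(0.0, w, size=x.shape)
        u_new = u_of_x(prop)
        # exp(-(inf - finite)) = 0 -> rejected; suppress overflow warnings
        with np.errstate(over="ignore", invalid="ignore"):
            ratio = np.exp(np.clip(-(u_new - u), -700, 0))
        acc = rng.random(n_chains) < ratio
        x[acc] = prop[acc]
        u[acc] = u_new[acc]
        if step < burn:
            tune_acc += int(acc.sum())
            tune_n += n_chains
            if tune_n >= 50 * n_chains:
                rate = tune_acc / tune_n
                if rate < 0.25:
                    w *= 0.75
                elif rate > 0.55:
                    w *= 1.3
                tune_acc = tune_n = 0
        else:
            accepted += int(acc.sum())
            proposed += n_chains
            step_in_stride += 1
            if step_in_stride == stride:
                out[rec] = x
                rec += 1
                step_in_stride = 0
    rate = accepted / max(proposed, 1)
    if not (0.1 <= rate <= 0.9):
        logger.warning(
            "Metropolis acceptance rate %.3f outside [0.1, 0.9] after auto-tuning "
            "(proposal width %.3f)",
            rate,
            w,
        )
    return out, rate


def sample_flooding_trajectory(
    potential: PotentialSpec,
    n_ligands: int,
    n_frames: int,
    temperature: float = T_DEFAULT,
    seed: int = 0,
    proposal_width: float = 0.8,
    burn_in_fraction: float = 0.1,
    stride: int = 1,
) -> Trajectory:
    """Equilibrium positions of ``n_ligands`` independent probes in the
    potential's box, asymptotically Boltzmann-distributed ∝ e^(−U/RT).

    Each trajectory "atom" is one probe; frames are successive Metropolis
    sweeps after burn-in.  Reproducible per seed.
    """
    if n_ligands < 1:
        raise ValueError("n_ligands must be >= 1")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    rt = RT(temperature)
    half = potential.lateral_extent / 2
    lo, hi = potential.z_range
    x0 = np.column_stack(
        [
            rng.uniform(-half, half, n_ligands),
            rng.uniform(-half, half, n_ligands),
            rng.uniform(lo, hi, n_ligands),
        ]
    )

    def u_of_x(x: np.ndarray) -> np.ndarray:
        return potential.u(x) / rt

    samples, _ = _metropolis(
        u_of_x, x0, n_frames, rng, proposal_width, burn_in_fraction, stride
    )
    box = np.array([potential.lateral_extent, potential.lateral_extent, hi - lo])
    return Trajectory(
        positions=samples,
        times=0.001 * np.arange(n_frames, dtype=float),
        box=box,
        ligand_ids=np.arange(n_ligands),
    )


def sample_umbrella_windows(
    potential: PotentialSpec,
    windows: WindowSet,
    n_samples: int,
    temperature: float = T_DEFAULT,
    seed: int = 0,
    proposal_width: float = 0.35,
    burn_in_fraction: float = 0.1,
    stride: int = 1,
    window_time_ns: float = 3.0,
) -> WindowSet:
    """Biased samples of the axial coordinate, one Metropolis chain per
    window under U_z(z) + ½k(z − z0)².  Chains start at their window centers
    (clipped into the domain).  Sample times span ``window_time_ns``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    rt = RT(temperature)
    z0 = np.array([w.z0 for w in windows.windows])
    k = np.array([w.k for w in windows.windows])
    lo, hi = potential.z_range
    x0 = np.clip(z0, lo, hi)[:, None]

    def u_of_x(x: np.ndarray) -> np.ndarray:
        z = x[:, 0]
        return (potential.u_z(z) + 0.5 * k * (z - z0) ** 2) / rt

    samples, _ = _metropolis(
        u_of_x, x0, n_samples, rng, proposal_width, burn_in_fraction, stride
    )
    times = (np.arange(n_samples) + 1) / n_samples * window_time_ns
    new_windows = [
        UmbrellaWindow(z0=w.z0, k=w.k, samples=samples[:, j, 0].copy(), times_ns=times.copy())
        for j, w in enumerate(windows.windows)
    ]
    return WindowSet(
        windows=new_windows,
        z_min=windows.z_min,
        z_max=windows.z_max,
        spacing=windows.spacing,
    )


# ---------------------------------------------------------------------------
# Scripted event trajectories
# ---------------------------------------------------------------------------

_STATES = ("bulk_top", "pore", "bulk_bottom", "elsewhere")


def scripted_crossing_trajectory(
    event_plan: Sequence[Sequence[tuple]],
    region,
    box: np.ndarray | None = None,
) -> Trajectory:
    """Trajectory whose permeation events are known by construction.

    ``event_plan`` holds one plan per ligand; each plan is a list of
    ``(state, n_frames)`` steps with state in {"bulk_top", "pore",
    "bulk_bottom", "elsewhere"} or ``((x, y, z), n_frames)`` explicit
    waypoints.  ``region`` is an occupancy PoreRegion providing the state
    geometry.  Ligands are padded with their final position to the longest
    plan; an empty plan yields a single static frame for that ligand.
    """
    rep = _state_points(region)
    n_lig = len(event_plan)
    if n_lig == 0:
        raise ValueError("event_plan must contain at least one ligand plan")
    tracks: list[np.ndarray] = []
    for plan in event_plan:
        pts: list[np.ndarray] = []
        for state, n in plan:
            if isinstance(state, str):
                if state not in rep:
                    raise ValueError(f"unknown state {state!r}; use one of {_STATES}")
                p = rep[state]
            else:
                p = np.asarray(state, dtype=float)
                if box is not None and (np.any(p < -np.asarray(box) / 2) or np.any(p > np.asarray(box) / 2)):
                    raise ValueError(f"waypoint {p} outside the simulation box {box}")
            pts.extend([p] * int(n))
        if not pts:
            pts = [rep["bulk_top"]]
        tracks.append(np.array(pts))
    n_frames = max(t.shape[0] for t in tracks)
    positions = np.empty((n_frames, n_lig, 3))
    for j, t in enumerate(tracks):
        positions[: t.shape[0], j] = t
        positions[t.shape[0] :, j] = t[-1]
    return Trajectory(
        positions=positions,
        times=0.001 * np.arange(n_frames, dtype=float),
        box=box,
        ligand_ids=np.arange(n_lig),
    )


def _state_points(region) -> dict[str, np.ndarray]:
    cx, cy = region.center_xy
    top_lo, top_hi = region.bulk_top
    bot_lo, bot_hi = region.bulk_bottom
    mid_pore = 0.5 * (region.z_bottom + region.z_top)
    return {
        "bulk_top": np.array([cx, cy, 0.5 * (top_lo + top_hi)]),
        "bulk_bottom": np.array([cx, cy, 0.5 * (bot_lo + bot_hi)]),
        "pore": np.array([cx, cy, mid_pore]),
        # radially outside the cylinder at pore height: neither pore nor bulk
        "elsewhere": np.array([cx + 3 * region.cylinder_radius, cy, mid_pore]),
    }


# ---------------------------------------------------------------------------
# Quadrature oracle
# ---------------------------------------------------------------------------


def oracle_profile(
    potential: PotentialSpec,
    z_edges: np.ndarray,
    temperature: float = T_DEFAULT,
    bulk_zranges: Sequence[tuple[float, float]] | None = None,
    points_per_bin: int = 400,
) -> Profile1D:
    """Exact Boltzmann free-energy profile by deterministic quadrature.

    ΔG(z bin) = −RT ln(⟨e^(−U_z/RT)⟩_bin / ⟨e^(−U_z/RT)⟩_bulk) with bin and
    bulk averages computed by dense midpoint quadrature of the axial
    potential.  Valid for the package's separable potentials (the lateral
    Boltzmann factor is z-independent and cancels in the ratio).  This
    routine shares no code with any estimator.
    """
    z_edges = np.asarray(z_edges, dtype=float)
    if z_edges.ndim != 1 or z_edges.size < 2:
        raise ValueError("z_edges must be a 1D array of at least 2 edges")
    rt = RT(temperature)

    def mean_boltzmann(lo: float, hi: float) -> float:
        n = max(points_per_bin, int(math.ceil((hi - lo) / 0.005)))
        z = lo + (np.arange(n) + 0.5) * (hi - lo) / n
        u = potential.u_z(z)
        w = np.where(np.isfinite(u), np.exp(-np.clip(u, -700 * rt, 700 * rt) / rt), 0.0)
        return float(np.mean(w))

    ranges = (
        potential.default_bulk_zranges() if bulk_zranges is None else tuple(bulk_zranges)
    )
    bulk_vals = []
    for lo, hi in ranges:
        bulk_vals.append(mean_boltzmann(lo, hi) * (hi - lo))
    total_len = sum(hi - lo for lo, hi in ranges)
    bulk_mean = sum(bulk_vals) / total_len
    if not np.isfinite(bulk_mean) or bulk_mean <= 0:
        raise ValueError("bulk region has vanishing Boltzmann weight")

    centers = 0.5 * (z_edges[:-1] + z_edges[1:])
    values = np.empty(centers.shape)
    flags = np.zeros(centers.shape, dtype=bool)
    for i, (lo, hi) in enumerate(zip(z_edges[:-1], z_edges[1:])):
        m = mean_boltzmann(lo, hi)
        if m <= 0:
            values[i] = np.inf
            flags[i] = True
        else:
            values[i] = -rt * math.log(m / bulk_mean)
    return Profile1D(z=centers, values=values, flags=flags, label="oracle quadrature profile")
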