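"""Implicit ligand sampling: 3D insertion free-energy maps.

A rigid gas probe is inserted on a regular grid over an ensemble of host
frames; at each insertion point the probe–host interaction energy E is
evaluated (Lennard-Jones with CHARMM-style switching between ``switch`` and
``cutoff``, plus cutoff-shifted Coulomb with Lorentz–Berthelot combining),
and the map is the Boltzmann average over frames, intra-cell subsites and
probe orientations:

    ΔG(cell) = −RT ln ⟨e^(−E/RT)⟩

with the vacuum reference p0 = 1.  Subtracting the bulk solvation value
ΔGsol (from a probe-in-solution map) converts insertion free energies into
bulk-referenced partitioning free energies.

Orientation quadrature uses a deterministic Fibonacci sphere by default so
maps are bit-reproducible without a seed.  Electrostatics are cutoff-shifted
rather than Ewald-summed: the probes this mapper is built for are neutral
with small partial charges, where the truncation error is negligible.  Maps
for probes with sizable partial charges (e.g. CO2) are computed on request
but trigger a warning — orientation-implicit sampling is unreliable for
polar ligands.
"""

from __future__ import annotations

import logging
from typing import Callable

import numpy as np
from scipy.special import logsumexp

from .constants import COULOMB_K, RT, T_DEFAULT
from .core import ProbeLigand, Trajectory
from .grids import FreeEnergyGrid, GridSpec, Profile1D
from .potentials import PotentialSpec
from .probes import HostParams

logger = logging.getLogger(__name__)

__all__ = [
    "lj_pair",
    "coulomb_pair",
    "probe_interaction_energy",
    "orientation_set",
    "ils_map",
    "field_map",
    "bulk_reference",
    "reference_grid",
    "project_profile",
    "segment_statistics",
]

#: Interaction energies are capped here (kcal/mol): Boltzmann factors are
#: floored at e^(−E_CAP/RT) and fully-capped cells are flagged in the map.
E_CAP = 100.0


def _switch_fn(r2: np.ndarray, switch: float, cutoff: float) -> np.ndarray:
    """CHARMM switching function on r² (1 below switch, 0 beyond cutoff)."""
    c2, s2 = cutoff**2, switch**2
    sw = ((c2 - r2) ** 2 * (c2 + 2 * r2 - 3 * s2)) / (c2 - s2) ** 3
    return np.where(r2 <= s2, 1.0, np.where(r2 >= c2, 0.0, sw))


def lj_pair(r: np.ndarray, epsilon: float, sigma: float) -> np.ndarray:
    """Plain 12-6 Lennard-Jones: 4ε[(σ/r)¹² − (σ/r)⁶]."""
    sr6 = (sigma / np.asarray(r, dtype=float)) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


def coulomb_pair(r: np.ndarray, q1: float, q2: float) -> np.ndarray:
    """Unshifted Coulomb energy k·q₁·q₂/r, kcal/mol."""
    return COULOMB_K * q1 * q2 / np.asarray(r, dtype=float)


def _site_energies(
    site_xyz: np.ndarray,  # (M, n_sites, 3) world coordinates
    host_xyz: np.ndarray,  # (n_atoms, 3)
    host: HostParams,
    probe: ProbeLigand,
    cutoff: float,
    switch: float,
    box: np.ndarray | None,
) -> np.ndarray:
    """Total probe–host energy for M poses, vectorized and E_CAP-capped."""
    eps_i = probe.epsilons  # (n_sites,)
    sig_i = probe.sigmas
    q_i = probe.charges
    # Lorentz–Berthelot combining per (site, atom)
    sig_ij = 0.5 * (sig_i[:, None] + host.sigma[None, :])  # (n_sites, n_atoms)
    eps_ij = np.sqrt(eps_i[:, None] * host.epsilon[None, :])
    qq = q_i[:, None] * host.charge[None, :]

    disp = site_xyz[:, :, None, :] - host_xyz[None, None, :, :]  # (M, ns, na, 3)
    if box is not None:
        disp -= box * np.round(disp / box)
    r2 = np.einsum("msad,msad->msa", disp, disp)
    c2 = cutoff**2
    within = r2 < c2
    r2_safe = np.where(r2 > 1e-12, r2, 1e-12)
    sr6 = (sig_ij[None] ** 2 / r2_safe) ** 3
    lj = 4.0 * eps_ij[None] * (sr6 * sr6 - sr6) * _switch_fn(r2, switch, cutoff)
    r = np.sqrt(r2_safe)
    coul = COULOMB_K * qq[None] * (1.0 / r - 1.0 / cutoff)
    e_pair = np.where(within, lj + coul, 0.0)
    # overlapping pair (r ~ 0) -> capped, no exception
    e_pair = np.where(r2 <= 1e-12, E_CAP, e_pair)
    e = e_pair.sum(axis=(1, 2))
    return np.minimum(e, E_CAP)


def _orientation_offsets(probe: ProbeLigand, orientations: np.ndarray) -> np.ndarray:
    """Site offsets (n_or, n_sites, 3) for each unit orientation.

    Each orientation is the world direction of the probe's local +z axis;
    the roll angle about it is fixed deterministically (immaterial for
    linear probes, documented for general ones).
    """
    local = probe.local_positions  # (n_sites, 3)
    out = np.empty((orientations.shape[0], local.shape[0], 3))
    for i, u in enumerate(orientations):
        out[i] = local @ _rotation_to(u).T
    return out


def _rotation_to(u: np.ndarray) -> np.ndarray:
    """A rotation matrix taking ẑ to unit vector u (deterministic roll)."""
    z = np.array([0.0, 0.0, 1.0])
    u = np.asarray(u, dtype=float)
    u = u / np.linalg.norm(u)
    c = float(np.dot(z, u))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z, u)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


def probe_interaction_energy(
    host_xyz: np.ndarray,
    host_params: HostParams,
    probe: ProbeLigand,
    position: np.ndarray,
    orientation: np.ndarray = (0.0, 0.0, 1.0),
    cutoff: float = 12.0,
    switch: float = 10.0,
    box: np.ndarray | None = None,
) -> float:
    """Probe–host interaction energy (kcal/mol) for one pose.

    ``orientation`` is the world direction of the probe's local +z axis.
    Overlapping pairs contribute the energy cap rather than raising.
    """
    host_xyz = np.asarray(host_xyz, dtype=float)
    offsets = _orientation_offsets(probe, np.asarray(orientation, dtype=float)[None, :])
    site_xyz = np.asarray(position, dtype=float)[None, :] + offsets[0]
    return float(
        _site_energies(site_xyz[None], host_xyz, host_params, probe, cutoff, switch, box)[0]
    )


def orientation_set(n: int, seed: int | None = None) -> np.ndarray:
    """(n, 3) unit orientations: a deterministic Fibonacci sphere when
    ``seed`` is None (n=1 gives +z), uniform random when a seed is given."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if seed is not None:
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def ils_map(
    frames: Trajectory,
    host_params: HostParams,
    probe: ProbeLigand,
    spec: GridSpec,
    temperature: float = T_DEFAULT,
    cutoff: float = 12.0,
    switch: float = 10.0,
    n_segments: int = 1,
    orientations: np.ndarray | None = None,
    chunk_pairs: int = 4_000_000,
) -> FreeEnergyGrid:
    """Insertion free-energy map over an ensemble of host frames.

    Per cell, ΔG = −RT ln of the arithmetic mean of Boltzmann factors over
    (frames × subsites × orientations).  When ``n_segments`` > 1 the frames
    are partitioned into contiguous segments and per-segment maps are kept
    on the returned grid for block-error statistics.
    """
    if frames.n_frames < 1:
        raise ValueError("need at least one frame")
    if n_segments < 1 or n_segments > frames.n_frames:
        raise ValueError("n_segments must be in [1, n_frames]")
    if np.abs(probe.charges).max() > 0.1:
        logger.warning(
            "probe %s carries sizable partial charges; orientation-implicit "
            "free-energy maps are unreliable for polar ligands — prefer "
            "explicit-ligand or umbrella-sampling estimates",
            probe.name,
        )
    rt = RT(temperature)
    centers = spec.cell_centers().reshape(-1, 3)  # (n_cells, 3)
    sub = spec.subsite_offsets()  # (n_sub, 3)
    n_cells, n_sub = centers.shape[0], sub.shape[0]
    positions = (centers[:, None, :] + sub[None, :, :]).reshape(-1, 3)
    if orientations is None:
        orientations = orientation_set(spec.n_orientations)
    offsets = _orientation_offsets(probe, orientations)  # (n_or, n_sites, 3)
    n_or, n_sites = offsets.shape[0], offsets.shape[1]
    # all poses for one frame: (n_pos * n_or, n_sites, 3)
    site_xyz = (
        positions[:, None, None, :] + offsets[None, :, :, :]
    ).reshape(-1, n_sites, 3)

    n_atoms = frames.n_atoms
    chunk = max(1, chunk_pairs // max(1, n_sites * n_atoms))
    seg_edges = np.linspace(0, frames.n_frames, n_segments + 1).astype(int)
    seg_sums = np.zeros((n_segments, n_cells))
    seg_counts = np.zeros(n_segments)
    for s in range(n_segments):
        for f in range(seg_edges[s], seg_edges[s + 1]):
            host_xyz = frames.frame(f)
            box = None if frames.box is None else frames.box[f]
            e = np.empty(site_xyz.shape[0])
            for start in range(0, site_xyz.shape[0], chunk):
                stop = min(start + chunk, site_xyz.shape[0])
                e[start:stop] = _site_energies(
                    site_xyz[start:stop], host_xyz, host_params, probe, cutoff, switch, box
                )
            boltz = np.exp(-e / rt)  # e already capped at E_CAP
            seg_sums[s] += boltz.reshape(n_cells, n_sub * n_or).sum(axis=1)
            seg_counts[s] += n_sub * n_or
    floor = np.exp(-E_CAP / rt)
    with np.errstate(divide="ignore"):
        seg_means = seg_sums / seg_counts[:, None]
        seg_maps = -rt * np.log(np.maximum(seg_means, floor))
    total_mean = seg_sums.sum(axis=0) / seg_counts.sum()
    values = -rt * np.log(np.maximum(total_mean, floor))
    capped = total_mean <= floor * (1 + 1e-9)
    return FreeEnergyGrid(
        spec=spec,
        values=values.reshape(spec.shape),
        capped=capped.reshape(spec.shape),
        segments=seg_maps.reshape(n_segments, *spec.shape) if n_segments > 1 else None,
    )


def field_map(
    potential: PotentialSpec | Callable[[np.ndarray], np.ndarray],
    spec: GridSpec,
    temperature: float = T_DEFAULT,
) -> FreeEnergyGrid:
    """Insertion map of a point probe in a fixed analytic field.

    The frozen-field counterpart of :func:`ils_map`: the "host" is an
    external potential U(x, y, z) evaluated at each subsite, so
    ΔG(cell) = −RT ln ⟨e^(−U/RT)⟩ over subsites.  Used to cross-validate
    the grid machinery against occupancy- and umbrella-based estimators on
    the same synthetic potential.
    """
    rt = RT(temperature)
    u_fn = potential.u if isinstance(potential, PotentialSpec) else potential
    centers = spec.cell_centers().reshape(-1, 3)
    sub = spec.subsite_offsets()
    pos = centers[:, None, :] + sub[None, :, :]
    u = np.asarray(u_fn(pos.reshape(-1, 3)), dtype=float).reshape(pos.shape[:2])
    u = np.minimum(np.where(np.isfinite(u), u, E_CAP), E_CAP)
    boltz = np.exp(-u / rt)
    mean = boltz.mean(axis=1)
    floor = np.exp(-E_CAP / rt)
    values = -rt * np.log(np.maximum(mean, floor))
    return FreeEnergyGrid(
        spec=spec,
        values=values.reshape(spec.shape),
        capped=(mean <= floor * (1 + 1e-9)).reshape(spec.shape),
    )


def bulk_reference(
    grid: FreeEnergyGrid,
    bulk_box: tuple[tuple[float, float], tuple[float, float], tuple[float, float]],
    temperature: float = T_DEFAULT,
) -> float:
    """Bulk solvation free energy ΔGsol = −RT ln⟨e^(−ΔG/RT)⟩ over the grid
    cells whose centers lie inside the given (x, y, z) sub-box."""
    rt = RT(temperature)
    centers = grid.spec.cell_centers()
    mask = np.ones(grid.spec.shape, dtype=bool)
    for ax, (lo, hi) in enumerate(bulk_box):
        c = centers[..., ax]
        mask &= (c >= lo) & (c <= hi)
    mask &= ~grid.capped
    if not mask.any():
        raise ValueError("bulk sub-box contains no grid cells")
    g = grid.values[mask]
    return float(-rt * logsumexp(-g / rt, b=1.0 / g.size))


def reference_grid(
    grid: FreeEnergyGrid,
    bulk_box: tuple[tuple[float, float], tuple[float, float], tuple[float, float]],
    temperature: float = T_DEFAULT,
) -> FreeEnergyGrid:
    """Subtract the bulk reference from a map, recording it on the result."""
    ref = bulk_reference(grid, bulk_box, temperature)
    out = grid.shifted(-ref)
    out.reference = ref
    return out


def project_profile(
    grid: FreeEnergyGrid,
    axis_radius: float = 5.0,
    temperature: float = T_DEFAULT,
    axis_center: tuple[float, float] | None = None,
    mode: str = "boltzmann",
) -> Profile1D:
    """Collapse a 3D map to a 1D pore-axis profile.

    Per z-layer, either the Boltzmann-weighted mean over the (x, y) cells
    within ``axis_radius`` of the pore axis (default) or the plain minimum
    over those cells (``mode="min"``).  Segment maps, when present, are
    projected the same way and their sample SD across segments is attached
    as the per-bin error.
    """
    if mode not in ("boltzmann", "min"):
        raise ValueError("mode must be 'boltzmann' or 'min'")
    spec = grid.spec
    xs, ys = spec.axis_centers(0), spec.axis_centers(1)
    if axis_center is None:
        axis_center = (float(xs.mean()), float(ys.mean()))
    x0, y0 = axis_center
    r2 = (xs[:, None] - x0) ** 2 + (ys[None, :] - y0) ** 2
    mask = r2 <= axis_radius**2
    if not mask.any():
        raise ValueError(
            f"no grid cells within axis_radius {axis_radius} of axis center {axis_center}"
        )
    rt = RT(temperature)

    def collapse(vol: np.ndarray) -> np.ndarray:
        layer = vol[mask, :]  # (n_inradius, nz)
        if mode == "min":
            return layer.min(axis=0)
        return -rt * logsumexp(-layer / rt, axis=0, b=1.0 / layer.shape[0])

    values = collapse(grid.values)
    errors = None
    if grid.segments is not None:
        seg_profiles = np.stack([collapse(s) for s in grid.segments])
        errors = seg_profiles.std(axis=0, ddof=1)
    capped_all = np.all(grid.capped[mask, :], axis=0)
    return Profile1D(
        z=spec.axis_centers(2),
        values=values,
        errors=errors,
        flags=capped_all,
        label=f"ILS profile ({mode}, axis_radius={axis_radius} Å)",
    )


def segment_statistics(segments: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
    """Unweighted mean and sample SD across segment maps/profiles.

    ``segments`` stacks per-segment arrays along axis 0.  With a single
    segment the SD is undefined and returned as None.
    """
    segments = np.asarray(segments, dtype=float)
    if segments.ndim < 1 or segments.shape[0] < 1:
        raise ValueError("need at least one segment")
    mean = segments.mean(axis=0)
    if segments.shape[0] < 2:
        return mean, None
    return mean, segments.std(axis=0, ddof=1)
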