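"""HOLE-style pore-radius profiling, alanine truncation, and side-chain
dihedral series.

The pore radius at axial position z is the radius of the largest sphere
centered on the slice plane that overlaps no atom's van der Waals sphere:

    r(z) = max_{(x,y)} min_i ( |p − a_i| − vdw_i ),   p = (x, y, z)

found per slice by a deterministic multi-start local search (5×5 coarse
grid about the axis plus the previous slice's center, refined by
Nelder–Mead).  The axis is fixed parallel to +z — the channels profiled
here sit on a symmetry axis, so the full adaptive axis search of HOLE is
not needed.  Hydrogens are excluded by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .core import Structure, Trajectory, select

logger = logging.getLogger(__name__)

__all__ = [
    "PoreProfile",
    "pore_profile",
    "average_profile",
    "truncate_to_alanine",
    "DihedralSeries",
    "chi_dihedrals",
    "dihedral_angle",
]


@dataclass
class PoreProfile:
    """Per-slice maximal-sphere radius, sphere center, and cap flags."""

    z: np.ndarray
    radius: np.ndarray
    center_xy: np.ndarray  # (n, 2)
    capped: np.ndarray  # True where no atom constrained the sphere (r = R_max)
    radius_sd: np.ndarray | None = None  # for trajectory averages

    def min_radius(self) -> tuple[float, float]:
        """(z, r) at the tightest constriction (uncapped slices)."""
        m = ~self.capped
        if not m.any():
            raise ValueError("all slices are unconstrained")
        i = int(np.argmin(np.where(m, self.radius, np.inf)))
        return float(self.z[i]), float(self.radius[i])


def _max_inscribed(
    xyz: np.ndarray,
    radii: np.ndarray,
    z: float,
    seed_xy: np.ndarray,
    axis_xy: np.ndarray,
    r_max: float,
    coarse_half: float = 2.0,
) -> tuple[float, np.ndarray, bool]:
    """Largest clearance on the slice plane at height z."""
    near = np.abs(xyz[:, 2] - z) <= r_max + radii.max() + 1.0 if xyz.size else np.zeros(0, bool)
    pts = xyz[near]
    rads = radii[near]
    if pts.shape[0] == 0:
        return r_max, axis_xy.copy(), True

    def clearance(xy: np.ndarray) -> float:
        d = np.sqrt(
            (pts[:, 0] - xy[0]) ** 2 + (pts[:, 1] - xy[1]) ** 2 + (pts[:, 2] - z) ** 2
        )
        return float(np.min(d - rads))

    # deterministic multi-start: coarse grid about the axis + previous center
    g = np.linspace(-coarse_half, coarse_half, 5)
    starts = [axis_xy + np.array([gx, gy]) for gx in g for gy in g]
    starts.append(seed_xy.copy())
    starts.sort(key=lambda s: -clearance(s))
    best_val = -np.inf
    best_xy = axis_xy.copy()
    for s in starts[:3]:
        res = minimize(
            lambda xy: -clearance(xy),
            s,
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 400},
        )
        if -res.fun > best_val:
            best_val = -res.fun
            best_xy = res.x
    if best_val >= r_max:
        return r_max, best_xy, True
    return max(best_val, 0.0), best_xy, False


def pore_profile(
    structure: Structure,
    axis_center: tuple[float, float] = (0.0, 0.0),
    z_range: tuple[float, float] | None = None,
    z_step: float = 0.25,
    r_max: float = 10.0,
    heavy_only: bool = True,
    positions: np.ndarray | None = None,
) -> PoreProfile:
    """Maximal-sphere radius profile along the +z axis.

    Atom vdW radii come from the structure; slices with no atoms in range
    are capped at ``r_max`` and flagged.  ``positions`` optionally overrides
    the structure's coordinates (same atom order) for per-frame profiling.
    """
    if z_step <= 0:
        raise ValueError("z_step must be positive")
    xyz = structure.positions if positions is None else np.asarray(positions, float)
    radii = structure.vdw_radii
    if heavy_only:
        keep = np.array([a.element.upper() != "H" for a in structure.atoms], dtype=bool)
        xyz, radii = xyz[keep], radii[keep]
    if xyz.size and np.any(radii <= 0):
        raise ValueError("pore profiling requires positive vdW radii on all atoms")
    if z_range is None:
        if xyz.shape[0] == 0:
            raise ValueError("z_range is required for an empty structure")
        z_range = (float(xyz[:, 2].min()), float(xyz[:, 2].max()))
    lo, hi = z_range
    n = int(np.floor((hi - lo) / z_step + 1e-9)) + 1
    zs = lo + np.arange(n) * z_step
    axis_xy = np.asarray(axis_center, dtype=float)
    seed = axis_xy.copy()
    radius = np.empty(n)
    centers = np.empty((n, 2))
    capped = np.zeros(n, dtype=bool)
    for i, z in enumerate(zs):
        r, c, cap = _max_inscribed(xyz, radii, z, seed, axis_xy, r_max)
        radius[i], centers[i], capped[i] = r, c, cap
        if i and np.linalg.norm(centers[i] - centers[i - 1]) > max(4 * z_step, 1.0):
            logger.warning(
                "pore center jumped %.2f Å between z=%.2f and z=%.2f",
                float(np.linalg.norm(centers[i] - centers[i - 1])),
                zs[i - 1],
                z,
            )
        seed = c
    return PoreProfile(z=zs, radius=radius, center_xy=centers, capped=capped)


def average_profile(
    traj: Trajectory,
    structure: Structure,
    frame_range: tuple[int, int] | None = None,
    **kwargs,
) -> PoreProfile:
    """Per-frame profiles averaged over ``frame_range`` with per-slice SD."""
    lo, hi = (0, traj.n_frames) if frame_range is None else frame_range
    if not (0 <= lo < hi <= traj.n_frames):
        raise ValueError(f"frame range {frame_range} outside trajectory of {traj.n_frames} frames")
    profiles = [
        pore_profile(structure, positions=traj.frame(f), **kwargs) for f in range(lo, hi)
    ]
    rad = np.stack([p.radius for p in profiles])
    return PoreProfile(
        z=profiles[0].z,
        radius=rad.mean(axis=0),
        center_xy=np.stack([p.center_xy for p in profiles]).mean(axis=0),
        capped=np.stack([p.capped for p in profiles]).all(axis=0),
        radius_sd=rad.std(axis=0, ddof=1) if len(profiles) > 1 else np.zeros(rad.shape[1]),
    )


# ---------------------------------------------------------------------------
# Alanine truncation
# ---------------------------------------------------------------------------

_BACKBONE_KEEP = {"N", "CA", "C", "O", "OXT", "OT1", "OT2", "H", "HN", "HA", "HT1", "HT2", "HT3"}


def truncate_to_alanine(structure: Structure, residues) -> Structure:
    """Truncate the selected residues' side chains to Cβ (alanine).

    ``residues`` is a selection expression (e.g. ``"resid 79 75 200"``) or an
    iterable of residue ids / (chain, resid) pairs.  Side-chain atoms beyond
    Cβ are removed, the residue is renamed ALA, and every retained atom keeps
    its exact position and order.  Glycine (no Cβ) and proline (backbone-
    bonded side chain) are rejected by name.  Already-alanine residues pass
    through unchanged.
    """
    targets = _resolve_residues(structure, residues)
    by_res: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(structure.atoms):
        by_res.setdefault((a.chain, a.residue_id), []).append(i)
    for key in targets:
        if key not in by_res:
            raise ValueError(f"residue {key} not found in structure")
        names = {structure.atoms[i].name for i in by_res[key]}
        resname = structure.atoms[by_res[key][0]].residue_name
        if resname in ("GLY", "PRO"):
            raise ValueError(
                f"cannot truncate {resname} {key[1]} (chain {key[0]}) to alanine"
            )
        if "CB" not in names:
            raise ValueError(
                f"residue {resname} {key[1]} (chain {key[0]}) has no CB atom"
            )
    out = structure.copy()
    kept = []
    for a in out.atoms:
        key = (a.chain, a.residue_id)
        if key in targets:
            if a.name != "CB" and a.name not in _BACKBONE_KEEP:
                continue
            a.residue_name = "ALA"
        kept.append(a)
    out.atoms = kept
    return out


def _resolve_residues(structure: Structure, residues) -> set[tuple[str, int]]:
    if isinstance(residues, str):
        idx = select(structure, residues)
        if not idx:
            raise ValueError(f"selection {residues!r} matches no atoms")
        return {(structure.atoms[i].chain, structure.atoms[i].residue_id) for i in idx}
    targets: set[tuple[str, int]] = set()
    for item in residues:
        if isinstance(item, int):
            found = {
                (a.chain, a.residue_id)
                for a in structure.atoms
                if a.residue_id == item
            }
            if not found:
                raise ValueError(f"residue id {item} not found")
            targets |= found
        else:
            chain, resid = item
            targets.add((str(chain), int(resid)))
    return targets


# ---------------------------------------------------------------------------
# Side-chain dihedrals
# ---------------------------------------------------------------------------


@dataclass
class DihedralSeries:
    """χ1/χ2 time series of one residue, degrees in (−180, 180]."""

    chain: str
    residue_id: int
    residue_name: str
    chi1: np.ndarray
    chi2: np.ndarray | None
    times_ns: np.ndarray


#: Atom-name preferences for the third/fourth chi atoms across residue types
#: (e.g. Trp χ2 is defined on Cδ1).
_CHI1_GAMMA = ("CG", "CG1", "OG", "OG1", "SG")
_CHI2_DELTA = ("CD", "CD1", "SD", "OD1", "ND1")


def dihedral_angle(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral (degrees, (−180, 180]) by the atan2 construction.

    Accepts single points or (n, 3) stacks; fully vectorized.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    return np.where(ang <= -180.0, ang + 360.0, ang)


def chi_dihedrals(
    traj: Trajectory, structure: Structure, residue: tuple[str, int] | int
) -> DihedralSeries:
    """χ1 (N−Cα−Cβ−Cγ) and χ2 (Cα−Cβ−Cγ−Cδ) series of one residue.

    ``residue`` is (chain, resid) or a bare resid (which must be unique).
    χ2 is None for residues without a δ atom; a missing defining atom for
    χ1 raises, naming it.
    """
    if isinstance(residue, int):
        keys = {
            (a.chain, a.residue_id) for a in structure.atoms if a.residue_id == residue
        }
        if len(keys) != 1:
            raise ValueError(
                f"resid {residue} matches {len(keys)} residues; pass (chain, resid)"
            )
        chain, resid = keys.pop()
    else:
        chain, resid = residue
    idx_of: dict[str, int] = {}
    resname = None
    for i, a in enumerate(structure.atoms):
        if a.chain == chain and a.residue_id == resid:
            idx_of.setdefault(a.name, i)
            resname = a.residue_name
    if resname is None:
        raise ValueError(f"residue (chain {chain}, resid {resid}) not found")

    def need(name: str) -> int:
        if name not in idx_of:
            raise ValueError(
                f"residue {resname} {resid} (chain {chain}) is missing atom {name!r}"
            )
        return idx_of[name]

    def first_of(options) -> int | None:
        for nm in options:
            if nm in idx_of:
                return idx_of[nm]
        return None

    i_n, i_ca, i_cb = need("N"), need("CA"), need("CB")
    i_g = first_of(_CHI1_GAMMA)
    if i_g is None:
        raise ValueError(
            f"residue {resname} {resid} (chain {chain}) is missing a gamma atom "
            f"(one of {_CHI1_GAMMA})"
        )
    P = traj.positions
    chi1 = dihedral_angle(P[:, i_n], P[:, i_ca], P[:, i_cb], P[:, i_g])
    i_d = first_of(_CHI2_DELTA)
    chi2 = None
    if i_d is not None:
        chi2 = dihedral_angle(P[:, i_ca], P[:, i_cb], P[:, i_g], P[:, i_d])
    return DihedralSeries(
        chain=chain,
        residue_id=resid,
        residue_name=resname,
        chi1=chi1,
        chi2=chi2,
        times_ns=traj.times.copy(),
    )
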