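"""Shared fixtures: small structures, channel specs, and geometric oracles.

All fixtures are generated programmatically; nothing is read from disk
except files the tests themselves write to tmp_path.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaspore.core import Atom, Structure
from gaspore.synthetic import ChannelRing, ChannelSpec, ResidueRing, make_channel_protein


def dense_grid_pore_radius(
    xyz: np.ndarray, radii: np.ndarray, z: float, half: float = 2.0, step: float = 0.02
) -> float:
    """Independent maximal-inscribed-sphere oracle: brute-force search of the
    slice plane on a dense grid about the pore axis.  Deliberately naive — no
    optimizer.  The search stays near the axis (|x|,|y| <= half) because the
    pore sphere is the local maximum there; far off-axis the clearance grows
    again outside the channel wall."""
    g = np.arange(-half, half + step / 2, step)
    X, Y = np.meshgrid(g, g, indexing="ij")
    dmin = np.full(X.shape, np.inf)
    for (ax, ay, az), r in zip(xyz, radii):
        d = np.sqrt((X - ax) ** 2 + (Y - ay) ** 2 + (z - az) ** 2) - r
        np.minimum(dmin, d, out=dmin)
    return float(dmin.max())


@pytest.fixture
def single_ring_spec() -> ChannelSpec:
    return ChannelSpec(rings=(ChannelRing(z=0.0, ring_radius=5.0, n_atoms=24, atom_vdw=1.7),))


@pytest.fixture
def hourglass_spec() -> ChannelSpec:
    return ChannelSpec(
        rings=(
            ChannelRing(z=-10.0, ring_radius=6.0, n_atoms=24, atom_vdw=1.7),
            ChannelRing(z=0.0, ring_radius=3.0, n_atoms=24, atom_vdw=1.7),
            ChannelRing(z=10.0, ring_radius=6.0, n_atoms=24, atom_vdw=1.7),
        )
    )


@pytest.fixture
def channel_protein() -> Structure:
    """Tetramer-like pseudo-protein: bulky rings of TRP 79, LEU 75, LEU 200
    constrict an otherwise wide channel (backbone at 9 Å from the axis)."""
    return make_channel_protein(
        [
            ResidueRing(
                z=-7.0,
                residue_name="LEU",
                residue_id=200,
                cb_radius=7.0,
                sidechain=(("CG", 5.5), ("CD1", 4.3), ("CD2", 5.0)),
            ),
            ResidueRing(
                z=0.0,
                residue_name="TRP",
                residue_id=79,
                cb_radius=7.0,
                sidechain=(("CG", 5.8), ("CD1", 4.6), ("CD2", 5.2), ("NE1", 3.8), ("CE2", 4.2)),
            ),
            ResidueRing(
                z=7.0,
                residue_name="LEU",
                residue_id=75,
                cb_radius=7.0,
                sidechain=(("CG", 5.5), ("CD1", 4.3), ("CD2", 5.0)),
            ),
        ]
    )


def make_trp_residue(chain: str = "A", resid: int = 79, offset=(0.0, 0.0, 0.0)) -> list[Atom]:
    """One tryptophan with idealized (non-planar-backbone) coordinates."""
    coords = {
        "N": (1.458, 0.0, 0.0),
        "CA": (0.0, 0.0, 0.0),
        "C": (-0.55, 1.42, 0.0),
        "O": (-1.75, 1.60, 0.2),
        "CB": (-0.54, -0.78, -1.20),
        "CG": (-0.20, -2.24, -1.22),
        "CD1": (0.93, -2.79, -0.70),
        "CD2": (-1.02, -3.30, -1.77),
        "NE1": (0.87, -4.15, -0.89),
        "CE2": (-0.30, -4.49, -1.56),
        "CE3": (-2.30, -3.39, -2.37),
        "CZ2": (-0.81, -5.74, -1.95),
        "CZ3": (-2.80, -4.63, -2.76),
        "CH2": (-2.06, -5.77, -2.55),
    }
    off = np.asarray(offset, dtype=float)
    return [
        Atom(
            name=name,
            element=name[0],
            residue_name="TRP",
            residue_id=resid,
            chain=chain,
            position=np.array(p) + off,
            vdw_radius=1.7 if name[0] == "C" else 1.55,
        )
        for name, p in coords.items()
    ]


@pytest.fixture
def trp_structure() -> Structure:
    """Four chains, each with one Trp79 plus a Gly80 (CA only) neighbour."""
    atoms: list[Atom] = []
    for i, chain in enumerate("ABCD"):
        atoms.extend(make_trp_residue(chain=chain, resid=79, offset=(10.0 * i, 0, 0)))
        atoms.append(
            Atom(
                name="CA",
                element="C",
                residue_name="GLY",
                residue_id=80,
                chain=chain,
                position=np.array([10.0 * i + 3.0, 0.0, 0.0]),
                vdw_radius=1.7,
            )
        )
    return Structure(atoms=atoms)
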