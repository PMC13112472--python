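"""Domain types shared across the pipeline: atoms, structures, trajectories,
rigid probe ligands, and atom selections.

Conventions: the pore axis is +z; z = 0 is placed at the host's center of
mass when structures are prepared for profiling.  Coordinates are Å.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "ProbeLigand",
    "ProbeSite",
    "VDW_RADII",
    "vdw_radius_for_element",
    "select",
]

#: Bondi-style van der Waals radii (Å) by element symbol.  Used by pore
#: profiling when a structure does not carry per-atom radii.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}


def vdw_radius_for_element(element: str, table: dict[str, float] | None = None) -> float:
    """Look up a vdW radius for an element symbol; raises KeyError naming it."""
    tab = VDW_RADII if table is None else table
    key = element.strip().upper()
    if key not in tab:
        raise KeyError(f"no van der Waals radius for element {element!r}")
    return tab[key]


@dataclass
class Atom:
    """A named atom of the host structure."""

    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str
    position: np.ndarray  # (3,) Å
    vdw_radius: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("Atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"Atom {self.name} has non-finite position")


@dataclass
class Structure:
    """An ordered collection of atoms, optionally with an orthorhombic box."""

    atoms: list[Atom]
    box: np.ndarray | None = None  # (3,) Å or None

    def __post_init__(self) -> None:
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,):
                raise ValueError("box must be an orthorhombic 3-vector")

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array (a copy)."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @positions.setter
    def positions(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("positions shape mismatch")
        for a, p in zip(self.atoms, xyz):
            a.position = p.copy()

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def copy(self) -> "Structure":
        return Structure(
            atoms=[replace(a, position=a.position.copy()) for a in self.atoms],
            box=None if self.box is None else self.box.copy(),
        )

    def subset(self, indices: Sequence[int]) -> "Structure":
        return Structure(
            atoms=[replace(self.atoms[i], position=self.atoms[i].position.copy()) for i in indices],
            box=None if self.box is None else self.box.copy(),
        )

    def center_of_mass(self) -> np.ndarray:
        """Unweighted geometric center (all atoms treated with unit mass)."""
        return self.positions.mean(axis=0)


@dataclass
class Trajectory:
    """Ordered frames of coordinates.

    ``positions`` has shape (n_frames, n_atoms, 3); ``times`` is ns per
    frame, strictly increasing; ``box`` is an optional per-frame (n_frames, 3)
    orthorhombic box (or a single (3,) box broadcast to all frames).
    """

    positions: np.ndarray
    times: np.ndarray | None = None
    box: np.ndarray | None = None
    ligand_ids: np.ndarray | None = None  # per-"atom" ligand identity, for probe trajectories

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
        n = self.positions.shape[0]
        if self.times is None:
            self.times = np.arange(n, dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (n,):
                raise ValueError("times length must equal n_frames")
            if n > 1 and not np.all(np.diff(self.times) > 0):
                raise ValueError("times must be strictly increasing")
        if self.box is not None:
            box = np.asarray(self.box, dtype=float)
            if box.shape == (3,):
                box = np.broadcast_to(box, (n, 3)).copy()
            if box.shape != (n, 3):
                raise ValueError("box must be (3,) or (n_frames, 3)")
            self.box = box

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.positions[i]

    def slice_frames(self, start: int, stop: int) -> "Trajectory":
        return Trajectory(
            positions=self.positions[start:stop].copy(),
            times=self.times[start:stop].copy(),
            box=None if self.box is None else self.box[start:stop].copy(),
            ligand_ids=self.ligand_ids,
        )

    @staticmethod
    def concatenate(a: "Trajectory", b: "Trajectory") -> "Trajectory":
        """Append b's frames after a's, shifting b's times to stay increasing."""
        if a.n_atoms != b.n_atoms:
            raise ValueError("atom count mismatch between trajectories")
        dt = a.times[-1] - b.times[0] + (
            a.times[1] - a.times[0] if a.n_frames > 1 else 1.0
        )
        box = None
        if a.box is not None and b.box is not None:
            box = np.concatenate([a.box, b.box])
        return Trajectory(
            positions=np.concatenate([a.positions, b.positions]),
            times=np.concatenate([a.times, b.times + dt]),
            box=box,
            ligand_ids=a.ligand_ids,
        )


@dataclass(frozen=True)
class ProbeSite:
    """One interaction site of a rigid probe molecule."""

    label: str
    epsilon: float  # kcal/mol
    sigma: float  # Å
    charge: float  # e
    local_position: tuple[float, float, float]  # Å, in the probe frame


@dataclass(frozen=True)
class ProbeLigand:
    """Rigid small-molecule probe (e.g. O2, CO2) with LJ sites and charges."""

    name: str
    sites: tuple[ProbeSite, ...]
    rigid: bool = True

    @property
    def net_charge(self) -> float:
        return float(sum(s.charge for s in self.sites))

    @property
    def local_positions(self) -> np.ndarray:
        return np.array([s.local_position for s in self.sites], dtype=float)

    @property
    def epsilons(self) -> np.ndarray:
        return np.array([s.epsilon for s in self.sites], dtype=float)

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([s.sigma for s in self.sites], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([s.charge for s in self.sites], dtype=float)


# ---------------------------------------------------------------------------
# Atom selection mini-language
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|\S+")

_FIELDS = {
    "resname": lambda a: a.residue_name,
    "resid": lambda a: a.residue_id,
    "chain": lambda a: a.chain,
    "name": lambda a: a.name,
    "element": lambda a: a.element,
}


class _SelParser:
    """Recursive-descent parser for expressions like
    ``resname TRP and resid 79`` or ``name CA or (chain A and not element H)``.
    """

    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ValueError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self):
        node = self.parse_or()
        if self.peek() is not None:
            raise ValueError(f"unexpected token {self.peek()!r} in selection")
        return node

    def parse_or(self):
        left = self.parse_and()
        while self.peek() == "or":
            self.next()
            right = self.parse_and()
            left = ("or", left, right)
        return left

    def parse_and(self):
        left = self.parse_not()
        while self.peek() == "and":
            self.next()
            right = self.parse_not()
            left = ("and", left, right)
        return left

    def parse_not(self):
        if self.peek() == "not":
            self.next()
            return ("not", self.parse_not())
        return self.parse_atom()

    def parse_atom(self):
        tok = self.next()
        if tok == "(":
            node = self.parse_or()
            if self.next() != ")":
                raise ValueError("unbalanced parentheses in selection")
            return node
        if tok not in _FIELDS:
            raise ValueError(f"unknown selection field {tok!r}")
        values = []
        while self.peek() is not None and self.peek() not in (
            "and",
            "or",
            "not",
            "(",
            ")",
        ):
            values.append(self.next())
        if not values:
            raise ValueError(f"selection field {tok!r} needs at least one value")
        return ("match", tok, values)


def _eval_sel(node, atom: Atom) -> bool:
    op = node[0]
    if op == "match":
        _, fld, values = node
        got = _FIELDS[fld](atom)
        if fld == "resid":
            return any(int(v) == got for v in values)
        return any(str(v).upper() == str(got).upper() for v in values)
    if op == "and":
        return _eval_sel(node[1], atom) and _eval_sel(node[2], atom)
    if op == "or":
        return _eval_sel(node[1], atom) or _eval_sel(node[2], atom)
    if op == "not":
        return not _eval_sel(node[1], atom)
    raise AssertionError(op)


def select(structure: Structure, expression: str) -> list[int]:
    """Evaluate a selection expression and return matching atom indices
    in structure order.

    Supported fields: ``resname``, ``resid``, ``chain``, ``name``,
    ``element``; combinators ``and``, ``or``, ``not``, parentheses.  A field
    followed by several values matches any of them.  An empty match returns
    an empty list; an unknown field raises ValueError.
    """
    tokens = _TOKEN_RE.findall(expression)
    if not tokens:
        raise ValueError("empty selection expression")
    tree = _SelParser(tokens).parse()
    return [i for i, a in enumerate(structure.atoms) if _eval_sel(tree, a)]
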