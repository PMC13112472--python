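"""Readers and writers for every on-disk format the pipeline touches.

Formats: PDB (structures), concatenated multi-frame XYZ (trajectories,
with time and optional orthorhombic box on the comment line), OpenDX
scalar fields (3D free-energy maps, z fastest-varying), and TSV with
``#`` header comments (1D profiles, umbrella-window samples, host
nonbonded parameters).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .core import Atom, Structure, Trajectory, vdw_radius_for_element
from .grids import FreeEnergyGrid, GridSpec, Profile1D

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_dx",
    "write_dx",
    "read_profile_tsv",
    "write_profile_tsv",
    "read_window_samples",
    "write_window_samples",
    "read_host_params",
    "write_host_params",
]

_TWO_LETTER_ELEMENTS = {"CL", "BR", "NA", "MG", "ZN", "FE", "CA", "MN", "CU", "SE"}


def _infer_element(name: str, resname: str) -> str:
    """Infer an element symbol from a PDB atom name."""
    stripped = name.strip()
    alpha = "".join(c for c in stripped if c.isalpha()).upper()
    if not alpha:
        return ""
    # Calcium ions vs. alpha-carbons: only trust two-letter symbols when the
    # atom name is exactly the symbol (ions) or clearly halogen-prefixed.
    if alpha[:2] in _TWO_LETTER_ELEMENTS and (
        stripped.upper() == alpha[:2] or alpha[:2] in ("CL", "BR", "SE")
    ):
        if not (alpha[:2] == "CA" and resname.strip().upper() != "CA"):
            return alpha[:2]
    return alpha[0]


def read_pdb(path: str | Path, vdw_table: dict[str, float] | None = None) -> Structure:
    """Parse ATOM/HETATM records into a Structure.

    Coordinates are taken at the format's printed precision (0.001 Å);
    occupancy and B-factor are ignored.  The element comes from columns
    77–78 when present, else is inferred from the atom name; each atom is
    assigned a vdW radius from the bundled element table (or ``vdw_table``).
    A malformed record raises ValueError with its line number; an element
    absent from the radius table raises KeyError naming the atom.
    """
    path = Path(path)
    atoms: list[Atom] = []
    box = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "CRYST1":
                try:
                    box = np.array(
                        [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                    )
                except ValueError as e:
                    raise ValueError(f"{path}:{lineno}: malformed CRYST1 record: {e}")
                continue
            if rec not in ("ATOM", "HETATM"):
                continue
            try:
                name = line[12:16].strip()
                resname = line[17:21].strip()
                chain = line[21].strip() or "A"
                resid = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError) as e:
                raise ValueError(f"{path}:{lineno}: malformed {rec} record: {e}")
            element = line[76:78].strip().upper() if len(line) >= 78 else ""
            if not element:
                element = _infer_element(name, resname)
            try:
                radius = vdw_radius_for_element(element, vdw_table)
            except KeyError:
                raise KeyError(
                    f"{path}:{lineno}: atom {name!r} (residue {resname} {resid}): "
                    f"no vdW radius for element {element!r}"
                )
            atoms.append(
                Atom(
                    name=name,
                    element=element,
                    residue_name=resname,
                    residue_id=resid,
                    chain=chain,
                    position=np.array([x, y, z]),
                    vdw_radius=radius,
                )
            )
    return Structure(atoms=atoms, box=box)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure as PDB; occupancy/B-factor are emitted as 1.00/0.00."""
    path = Path(path)
    with open(path, "w") as fh:
        if structure.box is not None:
            a, b, c = structure.box
            fh.write(
                f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
        for i, atom in enumerate(structure.atoms, start=1):
            name = atom.name
            # PDB alignment: 1-letter elements start in column 14
            if len(name) < 4 and len(atom.element) == 1:
                name = f" {name}"
            x, y, z = atom.position
            fh.write(
                f"ATOM  {i % 100000:5d} {name:<4.4s} {atom.residue_name:<3.3s} "
                f"{atom.chain[:1]}{atom.residue_id:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{atom.element:>2.2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Multi-frame XYZ trajectories
# ---------------------------------------------------------------------------


def read_xyz_trajectory(path: str | Path) -> Trajectory:
    """Read concatenated XYZ blocks with constant atom count.

    The comment line may carry ``t= <ns>`` and ``box= Lx Ly Lz``; when
    absent, frame times default to 0, 1, 2, … ns and the box to None.
    """
    path = Path(path)
    frames: list[np.ndarray] = []
    times: list[float] = []
    boxes: list[np.ndarray] = []
    n_atoms = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError:
            raise ValueError(f"{path}: expected atom count at line {i + 1}")
        if n_atoms is None:
            n_atoms = count
        elif count != n_atoms:
            raise ValueError(
                f"{path}: atom count changed from {n_atoms} to {count} at line {i + 1}"
            )
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        t, box = _parse_xyz_comment(comment)
        coords = np.empty((count, 3))
        for j in range(count):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed atom line {i + 3 + j}")
            coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(coords)
        times.append(t)
        if box is not None:
            boxes.append(box)
        i += 2 + count
    if not frames:
        raise ValueError(f"{path}: empty trajectory file")
    times_arr = np.array(times)
    if np.all(np.isnan(times_arr)):
        times_arr = np.arange(len(frames), dtype=float)
    elif np.any(np.isnan(times_arr)):
        raise ValueError(f"{path}: times present on some frames but not all")
    box_arr = np.array(boxes) if len(boxes) == len(frames) else None
    return Trajectory(positions=np.array(frames), times=times_arr, box=box_arr)


def _parse_xyz_comment(comment: str) -> tuple[float, np.ndarray | None]:
    t = float("nan")
    box = None
    toks = comment.split()
    for k, tok in enumerate(toks):
        if tok == "t=" and k + 1 < len(toks):
            t = float(toks[k + 1])
        elif tok == "box=" and k + 3 < len(toks):
            box = np.array([float(toks[k + 1]), float(toks[k + 2]), float(toks[k + 3])])
    return t, box


def write_xyz_trajectory(
    traj: Trajectory, path: str | Path, names: list[str] | None = None
) -> None:
    path = Path(path)
    n = traj.n_atoms
    if names is None:
        names = ["X"] * n
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{n}\n")
            comment = f"t= {traj.times[f]:.6f} ns"
            if traj.box is not None:
                bx, by, bz = traj.box[f]
                comment += f" box= {bx:.6f} {by:.6f} {bz:.6f}"
            fh.write(comment + "\n")
            for name, (x, y, z) in zip(names, traj.positions[f]):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# OpenDX scalar fields
# ---------------------------------------------------------------------------


def write_dx(grid: FreeEnergyGrid, path: str | Path, comment: str = "") -> None:
    """Write a FreeEnergyGrid as an OpenDX scalar field.

    Grid positions are the cell centers; data order is z fastest-varying
    (standard DX row-major over (x, y, z) indices), stated in the header.
    """
    spec = grid.spec
    nx, ny, nz = spec.shape
    d = spec.cell_spacing
    ox, oy, oz = (spec.origin[i] + d / 2 for i in range(3))
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# OpenDX scalar field, kcal/mol; data order: z fastest-varying\n")
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
        fh.write(f"delta {d:.6f} 0.000000 0.000000\n")
        fh.write(f"delta 0.000000 {d:.6f} 0.000000\n")
        fh.write(f"delta 0.000000 0.000000 {d:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
        )
        flat = grid.values.ravel(order="C")  # z fastest
        for start in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.10g}" for v in flat[start : start + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "field" class field\n')


def read_dx(path: str | Path) -> FreeEnergyGrid:
    path = Path(path)
    counts = None
    origin = None
    deltas = []
    values: list[float] = []
    n_items = None
    with open(path) as fh:
        in_data = False
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if in_data:
                if s.startswith("attribute") or s.startswith("object"):
                    in_data = False
                    continue
                values.extend(float(tok) for tok in s.split())
                continue
            if s.startswith("object 1"):
                counts = tuple(int(t) for t in s.split()[-3:])
            elif s.startswith("origin"):
                origin = np.array([float(t) for t in s.split()[1:4]])
            elif s.startswith("delta"):
                deltas.append(np.array([float(t) for t in s.split()[1:4]]))
            elif "data follows" in s:
                n_items = int(s.split()[-3])
                in_data = True
    if counts is None or origin is None or len(deltas) != 3:
        raise ValueError(f"{path}: not a recognizable OpenDX scalar field")
    D = np.array(deltas)
    if not np.allclose(D, np.diag(np.diag(D))):
        raise ValueError(f"{path}: non-axis-aligned grid not supported")
    spac = np.diag(D)
    if not np.allclose(spac, spac[0]):
        raise ValueError(f"{path}: non-uniform grid spacing not supported")
    if n_items is not None and len(values) != n_items:
        raise ValueError(
            f"{path}: expected {n_items} data items, found {len(values)}"
        )
    nx, ny, nz = counts
    if len(values) != nx * ny * nz:
        raise ValueError(f"{path}: data length does not match grid counts")
    d = float(spac[0])
    spec = GridSpec(
        origin=tuple(origin - d / 2),
        extent=(nx * d, ny * d, nz * d),
        cell_spacing=d,
    )
    vals = np.array(values).reshape(nx, ny, nz, order="C")
    return FreeEnergyGrid(spec=spec, values=vals)


# ---------------------------------------------------------------------------
# TSV: profiles, umbrella-window samples, host nonbonded parameters
# ---------------------------------------------------------------------------


def write_profile_tsv(profile: Profile1D, path: str | Path, header: str = "") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        if profile.label:
            fh.write(f"# {profile.label}\n")
        cols = ["z", "value"]
        if profile.errors is not None:
            cols.append("error")
        cols.append("flag")
        fh.write("# " + "\t".join(cols) + "\n")
        for i in range(len(profile.z)):
            row = [f"{profile.z[i]:.6f}", f"{profile.values[i]:.10g}"]
            if profile.errors is not None:
                row.append(f"{profile.errors[i]:.10g}")
            row.append("1" if profile.flags[i] else "0")
            fh.write("\t".join(row) + "\n")


def read_profile_tsv(path: str | Path) -> Profile1D:
    path = Path(path)
    rows = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            rows.append(s.split("\t"))
    if not rows:
        raise ValueError(f"{path}: empty profile file")
    arr = np.array(rows, dtype=float)
    errors = arr[:, 2] if arr.shape[1] >= 4 else None
    flags = arr[:, -1].astype(bool)
    return Profile1D(z=arr[:, 0], values=arr[:, 1], errors=errors, flags=flags)


def write_window_samples(
    times_ns: np.ndarray, values: np.ndarray, path: str | Path, header: str = ""
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        fh.write("# time_ns\tvalue\n")
        for t, v in zip(times_ns, values):
            fh.write(f"{t:.6f}\t{v:.8f}\n")


def read_window_samples(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    t, v = [], []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            t.append(float(parts[0]))
            v.append(float(parts[1]))
    if not t:
        raise ValueError(f"{path}: no samples")
    return np.array(t), np.array(v)


def write_host_params(
    epsilon: np.ndarray, sigma: np.ndarray, charge: np.ndarray, path: str | Path
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# atom_index\tepsilon_kcal_mol\tsigma_A\tcharge_e\n")
        for i, (e, s, q) in enumerate(zip(epsilon, sigma, charge)):
            fh.write(f"{i}\t{e:.6f}\t{s:.6f}\t{q:.6f}\n")


def read_host_params(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    path = Path(path)
    rows = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            rows.append([float(x) for x in s.split()])
    if not rows:
        raise ValueError(f"{path}: no parameter rows")
    arr = np.array(rows)
    order = np.argsort(arr[:, 0])
    arr = arr[order]
    return arr[:, 1], arr[:, 2], arr[:, 3]
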