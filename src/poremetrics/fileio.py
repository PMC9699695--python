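"""Structure and trajectory I/O.

Supported formats:

* GRO (fixed columns, free-format box line); coordinates already in nm.
* PDB ATOM/HETATM subset; Angstrom converted to nm; box from CRYST1.
* Concatenated-GRO trajectory dialect: GRO frames appended back to back,
  frame time in ns embedded in the title line as ``t= <ns>``.  This is
  the package's portable plain-text trajectory format.

Tabular results are written as TSV with ``#``-prefixed header comments
(pandas-readable).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import IO, Iterator, Sequence

import numpy as np
import pandas as pd

from .structures import Atom, Frame, MolecularSystem
from .units import ANGSTROM_TO_NM


class ParseError(ValueError):
    """Malformed structure/trajectory file; message names the line."""


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

def _parse_gro_time(title: str) -> float | None:
    if "t=" in title:
        try:
            return float(title.split("t=")[1].split()[0])
        except (IndexError, ValueError):
            return None
    return None


def _read_gro_block(lines: list[str], offset: int) -> tuple[list[Atom], Frame]:
    """Parse one GRO frame starting at ``lines[offset]``; offset is used
    only for error messages (1-based line numbers)."""
    title = lines[0]
    try:
        n_atoms = int(lines[1].strip())
    except (IndexError, ValueError):
        raise ParseError(f"line {offset + 2}: expected atom count, got "
                         f"{lines[1]!r}" if len(lines) > 1 else
                         f"line {offset + 2}: missing atom count")
    if len(lines) < n_atoms + 3:
        raise ParseError(f"line {offset + 1}: frame truncated; expected "
                         f"{n_atoms} atom lines plus a box line")
    atoms: list[Atom] = []
    positions = np.empty((n_atoms, 3))
    for i in range(n_atoms):
        ln = lines[2 + i]
        lineno = offset + 3 + i
        try:
            resid = int(ln[0:5])
            resname = ln[5:10].strip()
            name = ln[10:15].strip()
            positions[i, 0] = float(ln[20:28])
            positions[i, 1] = float(ln[28:36])
            positions[i, 2] = float(ln[36:44])
        except (ValueError, IndexError):
            raise ParseError(f"line {lineno}: malformed GRO fixed columns: {ln!r}")
        atoms.append(Atom(name=name, residue_name=resname, residue_id=resid))
    box_fields = lines[2 + n_atoms].split()
    if len(box_fields) < 3:
        raise ParseError(f"line {offset + n_atoms + 3}: missing or malformed "
                         f"GRO box line")
    box = np.array([float(x) for x in box_fields[:3]])
    time = _parse_gro_time(title)
    return atoms, Frame(time=0.0 if time is None else time,
                        positions=positions, box=box)


def read_gro(path: str | Path) -> tuple[MolecularSystem, Frame]:
    """Read a single-frame GRO file into a system plus coordinates."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: too short to be a GRO file (needs title, "
                         f"atom count, box line)")
    atoms, frame = _read_gro_block(lines, 0)
    return MolecularSystem(atoms), frame


def write_gro(path_or_handle: str | Path | IO[str], system: MolecularSystem,
              frame: Frame, title: str | None = None) -> None:
    """Write one GRO frame (3-decimal nm precision, the format's limit)."""
    if frame.n_atoms != system.n_atoms:
        raise ValueError("frame atom count does not match system")
    own = isinstance(path_or_handle, (str, Path))
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        fh.write((title or f"poremetrics t= {frame.time:.6f}") + "\n")
        fh.write(f"{system.n_atoms:5d}\n")
        for i, atom in enumerate(system.atoms):
            x, y, z = frame.positions[i]
            fh.write(f"{atom.residue_id % 100000:5d}{atom.residue_name:<5.5s}"
                     f"{atom.name:>5.5s}{(i + 1) % 100000:5d}"
                     f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
        fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path) -> tuple[MolecularSystem, Frame]:
    """Read ATOM/HETATM records of a PDB file; Angstrom -> nm.

    The box is taken from CRYST1 when present; otherwise the bounding box
    plus a 1 nm margin is used.
    """
    atoms: list[Atom] = []
    coords: list[tuple[float, float, float]] = []
    box = None
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        rec = ln[:6]
        if rec == "CRYST1":
            try:
                box = np.array([float(ln[6:15]), float(ln[15:24]),
                                float(ln[24:33])]) * ANGSTROM_TO_NM
            except ValueError:
                raise ParseError(f"line {lineno}: malformed CRYST1 record")
        elif rec in ("ATOM  ", "HETATM"):
            try:
                name = ln[12:16].strip()
                resname = ln[17:21].strip()
                chain = ln[21].strip()
                resid = int(ln[22:26])
                xyz = (float(ln[30:38]), float(ln[38:46]), float(ln[46:54]))
            except (ValueError, IndexError):
                raise ParseError(f"line {lineno}: malformed PDB atom record: {ln!r}")
            atoms.append(Atom(name=name, residue_name=resname,
                              residue_id=resid, chain=chain))
            coords.append(xyz)
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    positions = np.array(coords) * ANGSTROM_TO_NM
    if box is None:
        box = positions.max(axis=0) - positions.min(axis=0) + 1.0
    return MolecularSystem(atoms), Frame(time=0.0, positions=positions, box=box)


def read_structure(path: str | Path, format: str | None = None
                   ) -> tuple[MolecularSystem, Frame]:
    """Read a GRO or PDB structure; format inferred from the suffix."""
    fmt = (format or Path(path).suffix.lstrip(".")).lower()
    if fmt == "gro":
        return read_gro(path)
    if fmt == "pdb":
        return read_pdb(path)
    raise ValueError(f"unsupported structure format {fmt!r} (use gro or pdb)")


# ---------------------------------------------------------------------------
# Concatenated-GRO trajectories
# ---------------------------------------------------------------------------

def read_trajectory(path: str | Path) -> Iterator[Frame]:
    """Iterate over the frames of a concatenated-GRO trajectory.

    Yields frames in file order.  An empty file yields nothing.  Frames
    lacking a ``t=`` stamp get their 0-based frame index as the time.
    A change of atom count mid-file raises with the offending frame index.
    """
    lines = Path(path).read_text().splitlines()
    pos = 0
    frame_index = 0
    n_atoms_ref = None
    while pos < len(lines):
        if not lines[pos].strip() and pos == len(lines) - 1:
            break
        remaining = lines[pos:]
        if len(remaining) < 3:
            raise ParseError(f"frame {frame_index}: truncated trailing frame")
        _, frame = _read_gro_block(remaining, pos)
        if n_atoms_ref is None:
            n_atoms_ref = frame.n_atoms
        elif frame.n_atoms != n_atoms_ref:
            raise ParseError(
                f"frame {frame_index}: atom count changed from {n_atoms_ref} "
                f"to {frame.n_atoms}")
        if _parse_gro_time(remaining[0]) is None:
            frame = Frame(time=float(frame_index), positions=frame.positions,
                          box=frame.box)
        yield frame
        pos += frame.n_atoms + 3
        frame_index += 1


def write_trajectory(path: str | Path, system: MolecularSystem,
                     frames: Sequence[Frame]) -> None:
    with open(path, "w") as fh:
        for frame in frames:
            write_gro(fh, system, frame)


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def write_tsv(path: str | Path, df: pd.DataFrame, comments: Sequence[str] = ()) -> None:
    """Write a TSV with '#' header comments."""
    os.makedirs(Path(path).parent, exist_ok=True)
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
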