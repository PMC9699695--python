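"""Ion permeation counting and pore water-column continuity.

Permeation uses a full-traversal criterion: an ion must enter the
membrane slab through one face and exit through the other to count as
one event.  Ions that dither back and forth across a single face, or
enter and leave on the same side (rebounds), contribute nothing.  The
slab is bounded by the per-leaflet mean phosphate planes, held fixed
over the analysis window; z series are unwrapped across the periodic
box before counting so wrap jumps are not mistaken for traversals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .structures import Frame, MolecularSystem


@dataclass(frozen=True)
class SlabBoundaries:
    """Membrane slab along z: mean phosphate planes of the two leaflets."""

    z_low: float
    z_high: float
    sd_low: float = 0.0
    sd_high: float = 0.0

    def __post_init__(self) -> None:
        if not self.z_low < self.z_high:
            raise ValueError(f"z_low must be < z_high, got "
                             f"({self.z_low}, {self.z_high})")


@dataclass(frozen=True)
class PermeationEvent:
    ion: int
    species: str
    direction: str        # "up" (low -> high face) or "down"
    entry_frame: int
    exit_frame: int

    def __post_init__(self) -> None:
        if self.exit_frame <= self.entry_frame:
            raise ValueError("exit_frame must be after entry_frame")


def slab_boundaries(frame: Frame, system: MolecularSystem) -> SlabBoundaries:
    """Per-leaflet mean headgroup-reference z (phosphate planes).

    Requires leaflet labels; reports the standard deviation of each
    plane so deformed membranes can be recognized.
    """
    zs = {"inner": [], "outer": []}
    for ridx in system.lipid_residues():
        leaflet = system.leaflet[ridx]
        if leaflet in zs:
            zs[leaflet].append(
                frame.positions[system.headgroup_reference_index(ridx), 2])
    for tag, vals in zs.items():
        if not vals:
            raise ValueError(f"leaflet {tag!r} holds no lipids; assign "
                             f"leaflets first")
    lo, hi = np.array(zs["inner"]), np.array(zs["outer"])
    return SlabBoundaries(z_low=float(lo.mean()), z_high=float(hi.mean()),
                          sd_low=float(lo.std()), sd_high=float(hi.std()))


def unwrap_z(z: np.ndarray, lz: float) -> np.ndarray:
    """Remove periodic wrap jumps from a z series (threshold Lz/2)."""
    z = np.asarray(z, dtype=float)
    jumps = np.diff(z)
    corrections = -np.cumsum(np.round(jumps / lz)) * lz
    out = z.copy()
    out[1:] += corrections
    return out


def _crossings(z0: float, z1: float, boundaries: SlabBoundaries, lz: float):
    """Yield (position, face) for every slab-face plane crossed by the
    segment z0 -> z1 (unwrapped), in traversal order.  Faces are the
    periodic images z_low + k*Lz ('low') and z_high + k*Lz ('high').

    A plane p is crossed iff the side classification ``z >= p`` differs
    between the endpoints, i.e. min(z0,z1) < p <= max(z0,z1); this keeps
    samples landing exactly on a plane consistent across segments.
    """
    if z1 == z0:
        return
    lo, hi = min(z0, z1), max(z0, z1)
    planes = []
    for base, face in ((boundaries.z_low, "low"), (boundaries.z_high, "high")):
        k = np.ceil((lo - base) / lz)
        p = base + k * lz
        if p == lo:
            p += lz
        while p <= hi:
            planes.append((p, face))
            p += lz
    planes.sort(reverse=bool(z1 < z0))
    yield from planes


def permeation_events(z_series: np.ndarray, boundaries: SlabBoundaries,
                      lz: float,
                      species: Sequence[str] | None = None
                      ) -> tuple[list[PermeationEvent], pd.DataFrame]:
    """Count complete slab traversals per ion.

    Parameters
    ----------
    z_series : (n_ions, n_frames) wrapped z coordinates in nm.
    boundaries : fixed slab faces (mean leaflet phosphate planes).
    lz : box length along z, for unwrapping.
    species : per-ion species labels (defaults to "ION").

    Returns the event list and a cumulative per-frame count table with
    one column per (species, direction).

    State machine per ion: outside/inside the slab, remembering the
    entry face; exiting through the opposite face records one event,
    exiting through the entry face (rebound) records nothing.
    """
    z_series = np.atleast_2d(np.asarray(z_series, dtype=float))
    if not np.all(np.isfinite(z_series)):
        bad = np.argwhere(~np.isfinite(z_series))[0]
        raise ValueError(f"non-finite z for ion {bad[0]} at frame {bad[1]}")
    n_ions, n_frames = z_series.shape
    labels = list(species) if species is not None else ["ION"] * n_ions
    events: list[PermeationEvent] = []
    for ion in range(n_ions):
        z = unwrap_z(z_series[ion], lz)
        # initial state by side classification z >= plane: the slab image
        # containing z[0] is [z_low + c*Lz, z_high + c*Lz)
        cell = np.floor((z[0] - boundaries.z_low) / lz)
        z_local = z[0] - cell * lz
        inside = z_local < boundaries.z_high
        entry_face: str | None = None  # unknown when starting inside
        entry_frame = 0
        for t in range(1, n_frames):
            for _, face in _crossings(z[t - 1], z[t], boundaries, lz):
                if not inside:
                    inside = True
                    entry_face = face
                    entry_frame = t - 1   # segment start: last frame outside
                else:
                    inside = False
                    if entry_face is not None and face != entry_face:
                        direction = "up" if entry_face == "low" else "down"
                        events.append(PermeationEvent(
                            ion=ion, species=labels[ion], direction=direction,
                            entry_frame=entry_frame, exit_frame=t))
    cumulative = _cumulative_counts(events, labels, n_frames)
    return events, cumulative


def _cumulative_counts(events: list[PermeationEvent], labels: Sequence[str],
                       n_frames: int) -> pd.DataFrame:
    cols = {}
    for sp in dict.fromkeys(labels):
        for direction in ("up", "down"):
            counts = np.zeros(n_frames, dtype=int)
            for e in events:
                if e.species == sp and e.direction == direction:
                    counts[e.exit_frame:] += 1
            cols[f"{sp}_{direction}"] = counts
    df = pd.DataFrame(cols)
    df.insert(0, "frame", np.arange(n_frames))
    return df


def water_continuity(frame: Frame, system: MolecularSystem,
                     boundaries: SlabBoundaries,
                     axis_center: tuple[float, float],
                     cylinder_radius: float,
                     bin_dz: float = 0.3
                     ) -> tuple[bool, list[tuple[float, float]]]:
    """Is the water column through the membrane slab continuous?

    The slab [z_low, z_high] is split into bins of ``bin_dz`` (the last
    bin absorbs the remainder); the column is continuous iff every bin
    contains at least one water oxygen within ``cylinder_radius`` of the
    pore axis.  Returns (continuous, list of empty (z_lo, z_hi) gaps).
    The default bin width of 0.3 nm is about one water diameter.
    """
    if cylinder_radius <= 0:
        warnings.warn("non-positive cylinder radius: column can never be "
                      "continuous", stacklevel=2)
    ow = system.water_oxygen_indices()
    pos = frame.positions[ow] if len(ow) else np.empty((0, 3))
    r_xy = np.linalg.norm(pos[:, :2] - np.asarray(axis_center), axis=1)
    in_cyl = pos[r_xy <= cylinder_radius, 2]
    n_bins = max(1, int((boundaries.z_high - boundaries.z_low) // bin_dz))
    edges = np.linspace(boundaries.z_low, boundaries.z_high, n_bins + 1)
    counts, _ = np.histogram(in_cyl, bins=edges)
    gaps = [(float(edges[i]), float(edges[i + 1]))
            for i in range(n_bins) if counts[i] == 0]
    return len(gaps) == 0, gaps
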