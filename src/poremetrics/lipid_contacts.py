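"""Lipid-protein contacts, dual-cutoff residence, enrichment, bridging lipids.

A contact exists between a lipid and a protein residue in a frame when
the minimum distance between any lipid *headgroup heavy atom* and any
protein *heavy atom* is at or below the detection cutoff (default
0.36 nm), under the minimum-image convention.

Contact *durations* use the dual-cutoff scheme: an interval opens when
the pair distance drops to the detection cutoff and closes only at the
first frame where it exceeds the looser release cutoff (default
0.50 nm).  The looser release suppresses "rattling-in-a-cage" artifacts,
where a bound lipid vibrates across a single tight cutoff.

A *bridging* lipid simultaneously contacts two adjacent protein subunits
in the same frame — double-sided tape across an oligomer interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import Frame, MolecularSystem, n_subunits as _n_subunits

DETECTION_CUTOFF_NM = 0.36
RELEASE_CUTOFF_NM = 0.50


@dataclass(frozen=True)
class ContactPair:
    """Minimum heavy-atom contact between one lipid and one protein residue."""

    lipid: int            # lipid residue index
    protein_residue: int  # protein residue index
    frame: int
    distance: float       # nm, min over headgroup-heavy x protein-heavy pairs


@dataclass(frozen=True)
class ResidenceInterval:
    lipid: int
    protein_residue: int
    start_frame: int
    end_frame: int        # half-open
    duration_ns: float

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass(frozen=True)
class BridgeRecord:
    lipid: int
    interface: tuple[int, int]  # adjacent subunit pair (i, j)
    frame: int


# ---------------------------------------------------------------------------
# Contact detection
# ---------------------------------------------------------------------------

def _contact_selections(system: MolecularSystem
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(protein atom idx, their residue idx, lipid headgroup-heavy atom idx,
    their residue idx)."""
    prot_atoms, prot_res = [], []
    for ridx in system.protein_residues():
        heavy = system.heavy_atom_indices(ridx)
        prot_atoms.extend(heavy)
        prot_res.extend([ridx] * len(heavy))
    lip_atoms, lip_res = [], []
    for ridx in system.lipid_residues():
        heavy = system.headgroup_heavy_indices(ridx)
        lip_atoms.extend(heavy)
        lip_res.extend([ridx] * len(heavy))
    return (np.array(prot_atoms, dtype=int), np.array(prot_res, dtype=int),
            np.array(lip_atoms, dtype=int), np.array(lip_res, dtype=int))


def heavy_atom_contacts(frame: Frame, system: MolecularSystem,
                        cutoff: float = DETECTION_CUTOFF_NM,
                        frame_index: int = 0) -> list[ContactPair]:
    """All lipid/protein-residue contacts in one frame.

    Periodic minimum image in x, y, z via a KD-tree on the wrapped
    coordinates; expected cost O(N) at fixed density.  Emits one
    ContactPair per (lipid, protein residue) with the minimum heavy-atom
    distance, for pairs whose minimum is <= cutoff (strict boundary:
    0.36 is in, 0.37 is out).
    """
    box = frame.box
    if np.min(box) < 2 * cutoff:
        raise ValueError(
            f"box {box} smaller than twice the cutoff {cutoff}; minimum-image "
            f"convention invalid")
    pa, pr, la, lr = _contact_selections(system)
    if len(pa) == 0 or len(la) == 0:
        return []
    ppos = np.mod(frame.positions[pa], box)
    lpos = np.mod(frame.positions[la], box)
    tree = cKDTree(ppos, boxsize=box)
    neighbors = tree.query_ball_point(lpos, r=cutoff)
    best: dict[tuple[int, int], float] = {}
    for i, hits in enumerate(neighbors):
        if not hits:
            continue
        delta = np.abs(ppos[hits] - lpos[i])
        delta = np.minimum(delta, box - delta)
        dists = np.linalg.norm(delta, axis=1)
        for j, d in zip(hits, dists):
            key = (int(lr[i]), int(pr[j]))
            if d < best.get(key, np.inf):
                best[key] = float(d)
    return [ContactPair(lipid=l, protein_residue=p, frame=frame_index, distance=d)
            for (l, p), d in sorted(best.items())]


def contacts_over_trajectory(frames: Iterable[Frame], system: MolecularSystem,
                             cutoff: float = DETECTION_CUTOFF_NM
                             ) -> list[list[ContactPair]]:
    return [heavy_atom_contacts(f, system, cutoff, frame_index=i)
            for i, f in enumerate(frames)]


# ---------------------------------------------------------------------------
# Dual-cutoff residence
# ---------------------------------------------------------------------------

def intervals_from_distances(distances: np.ndarray,
                             start_cutoff: float = DETECTION_CUTOFF_NM,
                             release_cutoff: float = RELEASE_CUTOFF_NM
                             ) -> list[tuple[int, int]]:
    """Half-open [start, end) bound intervals of one pair's distance series.

    An interval opens at the first frame with d <= start_cutoff and
    closes at the first subsequent frame with d > release_cutoff.  With
    release == start this degenerates to single-cutoff segmentation.
    Intervals separated by even a single above-release frame are not
    merged.
    """
    if release_cutoff < start_cutoff:
        raise ValueError("release_cutoff must be >= start_cutoff")
    d = np.asarray(distances, dtype=float)
    intervals: list[tuple[int, int]] = []
    open_start: int | None = None
    for i, dist in enumerate(d):
        if open_start is None:
            if dist <= start_cutoff:
                open_start = i
        elif dist > release_cutoff:
            intervals.append((open_start, i))
            open_start = None
    if open_start is not None:
        intervals.append((open_start, len(d)))
    return intervals


def residence_intervals(distance_series: Mapping[tuple[int, int], np.ndarray],
                        start_cutoff: float = DETECTION_CUTOFF_NM,
                        release_cutoff: float = RELEASE_CUTOFF_NM,
                        dt_ns: float = 1.0) -> list[ResidenceInterval]:
    """Dual-cutoff residence intervals for per-pair distance series.

    ``distance_series`` maps (lipid residue, protein residue) to the
    per-frame minimum heavy-atom distance.
    """
    out: list[ResidenceInterval] = []
    for (lipid, pres), d in distance_series.items():
        for s, e in intervals_from_distances(d, start_cutoff, release_cutoff):
            out.append(ResidenceInterval(lipid=lipid, protein_residue=pres,
                                         start_frame=s, end_frame=e,
                                         duration_ns=(e - s) * dt_ns))
    return out


def analysis_window(frames: Sequence[Frame], discard_ns: float = 500.0
                    ) -> list[Frame]:
    """Drop the initial equilibration span: frames with time < discard
    removed.  Residence-duration counting conventionally runs on the full
    trajectory instead; both windows are exposed by keeping this separate
    from the contact operators."""
    return [f for f in frames if f.time >= discard_ns]


# ---------------------------------------------------------------------------
# Occupancy and enrichment
# ---------------------------------------------------------------------------

def occupancy(contacts_by_frame: Sequence[Sequence[ContactPair]],
              system: MolecularSystem,
              average_over_subunits: bool = False) -> pd.DataFrame:
    """Fraction of frames in which each (protein residue, lipid species)
    pair has at least one contact.

    With ``average_over_subunits`` the per-residue occupancies are
    averaged over subunits at equal residue position within the subunit
    (requires subunit labels), mirroring per-subunit reduction over a
    symmetric oligomer.
    """
    n_frames = len(contacts_by_frame)
    if n_frames == 0:
        raise ValueError("no frames provided")
    hits: dict[tuple[int, str], set[int]] = {}
    for fidx, contacts in enumerate(contacts_by_frame):
        for c in contacts:
            key = (c.protein_residue, str(system.residue_names[c.lipid]))
            hits.setdefault(key, set()).add(fidx)
    rows = [{"protein_residue": pres, "species": sp,
             "occupancy": len(f) / n_frames}
            for (pres, sp), f in sorted(hits.items())]
    df = pd.DataFrame(rows, columns=["protein_residue", "species", "occupancy"])
    if not average_over_subunits:
        return df
    prot = system.protein_residues()
    if np.any(system.subunit[prot] < 0):
        raise ValueError("subunit labels required for subunit averaging")
    position = {}
    for sub in range(_n_subunits(system)):
        members = [r for r in prot if system.subunit[r] == sub]
        for pos, r in enumerate(members):
            position[r] = pos
    df["position"] = df["protein_residue"].map(position)
    nsub = _n_subunits(system)
    # residues with zero contacts contribute zero occupancy to the average
    grouped = (df.groupby(["position", "species"])["occupancy"].sum() / nsub)
    return grouped.reset_index().rename(columns={"occupancy": "mean_occupancy"})


def species_enrichment(contacts_by_frame: Sequence[Sequence[ContactPair]],
                       system: MolecularSystem,
                       mole_fractions: Mapping[str, float] | None = None,
                       leaflet: str = "inner") -> pd.DataFrame:
    """Contact share of each lipid species relative to its abundance.

    enrichment(species) = (species' share of all lipid-protein contact
    pairs) / (species' mole fraction in the given leaflet).  Abundances
    default to the system's own leaflet census; species with contacts but
    absent from the leaflet get NaN (undefined).  1 means binding in
    proportion to abundance; >1 means preferential binding.
    """
    if mole_fractions is None:
        lipids = system.lipid_residues()
        in_leaflet = [r for r in lipids if system.leaflet[r] == leaflet]
        if not in_leaflet:
            raise ValueError(f"no lipids assigned to leaflet {leaflet!r}")
        names, counts = np.unique(
            [str(system.residue_names[r]) for r in in_leaflet], return_counts=True)
        mole_fractions = dict(zip(names, counts / counts.sum()))
    contact_counts: dict[str, int] = {}
    total = 0
    for contacts in contacts_by_frame:
        for c in contacts:
            sp = str(system.residue_names[c.lipid])
            contact_counts[sp] = contact_counts.get(sp, 0) + 1
            total += 1
    rows = []
    for sp in sorted(set(contact_counts) | set(mole_fractions)):
        share = contact_counts.get(sp, 0) / total if total else 0.0
        frac = mole_fractions.get(sp, np.nan)
        enrich = share / frac if frac and np.isfinite(frac) else np.nan
        rows.append({"species": sp, "contact_share": share,
                     "mole_fraction": frac, "enrichment": enrich})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bridging lipids
# ---------------------------------------------------------------------------

def adjacent_interfaces(n_sub: int, ring_closed: bool = True
                        ) -> list[tuple[int, int]]:
    if n_sub < 2:
        raise ValueError("bridging requires at least 2 subunits")
    pairs = [(i, i + 1) for i in range(n_sub - 1)]
    if ring_closed and n_sub > 2:
        pairs.append((n_sub - 1, 0))
    return pairs


def bridging_lipids(contacts_by_frame: Sequence[Sequence[ContactPair]],
                    system: MolecularSystem,
                    ring_closed: bool = True,
                    species: str | None = None
                    ) -> tuple[list[BridgeRecord], pd.DataFrame, pd.DataFrame]:
    """Lipids simultaneously contacting two *adjacent* subunits per frame.

    Returns (bridge records, per-frame totals, per-interface time series).
    The per-frame table also reports lipids touching two non-adjacent
    subunits separately (``n_nonadjacent``).  ``species`` restricts the
    count to one lipid species (e.g. only the 4-fold anionic PIP2).
    """
    nsub = _n_subunits(system)
    interfaces = adjacent_interfaces(nsub, ring_closed)
    iface_set = {frozenset(p) for p in interfaces}
    records: list[BridgeRecord] = []
    frame_rows = []
    iface_counts = {p: np.zeros(len(contacts_by_frame), dtype=int)
                    for p in interfaces}
    for fidx, contacts in enumerate(contacts_by_frame):
        touched: dict[int, set[int]] = {}
        for c in contacts:
            if species is not None and str(system.residue_names[c.lipid]) != species:
                continue
            sub = int(system.subunit[c.protein_residue])
            if sub >= 0:
                touched.setdefault(c.lipid, set()).add(sub)
        n_bridge = 0
        n_nonadj = 0
        for lipid, subs in touched.items():
            if len(subs) < 2:
                continue
            bridged = False
            for p in interfaces:
                if p[0] in subs and p[1] in subs:
                    records.append(BridgeRecord(lipid=lipid, interface=p,
                                                frame=fidx))
                    iface_counts[p][fidx] += 1
                    bridged = True
            if bridged:
                n_bridge += 1
            elif any(frozenset(pair) not in iface_set
                     for pair in _pairs(sorted(subs))):
                n_nonadj += 1
        frame_rows.append({"frame": fidx, "n_bridging": n_bridge,
                           "n_nonadjacent": n_nonadj})
    per_frame = pd.DataFrame(frame_rows)
    per_iface = pd.DataFrame({f"{i}-{j}": v for (i, j), v in iface_counts.items()})
    per_iface.insert(0, "frame", np.arange(len(contacts_by_frame)))
    return records, per_frame, per_iface


def _pairs(items: Sequence[int]):
    for a in range(len(items)):
        for b in range(a + 1, len(items)):
            yield (items[a], items[b])
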