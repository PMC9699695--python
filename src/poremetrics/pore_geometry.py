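"""Pore and membrane geometry observables.

Covers the descriptive geometry of pore-forming-protein simulations:
the width of the lipid-free pore, the crown-shaped upward deformation a
prepore ring imprints on the membrane, the tilt of membrane-inserted
hairpins relative to the membrane plane, the circularity of an oligomer
ring and the detection of interface "cracks" (lost inter-subunit
contacts), and local membrane thinning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import Frame, MolecularSystem, n_subunits as _n_subunits


@dataclass
class PoreMeasure:
    center: tuple[float, float]
    radius: float           # nm
    method: str
    grid_nm: float

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass
class DeformationProfile:
    bin_centers: np.ndarray    # radial distance nm
    mean_z: np.ndarray         # mean headgroup z per bin (nm); NaN if empty
    counts: np.ndarray
    far_field_z: float
    crown_height: float        # max(mean_z) - far_field_z


@dataclass
class CrackReport:
    """Adjacent-interface cracks: first frame/time the inter-subunit
    contact count stayed below threshold for the persistence window."""

    cracked: dict[tuple[int, int], float]   # interface -> first-crack time ns
    threshold: int
    persistence_frames: int


# ---------------------------------------------------------------------------
# Pore radius
# ---------------------------------------------------------------------------

def pore_radius(frame: Frame, system: MolecularSystem,
                slab_half_width: float = 1.0, grid: float = 0.5,
                center: tuple[float, float] | None = None,
                min_radius: float = 1.5) -> PoreMeasure | None:
    """Radius of the lipid-free disc at the membrane center.

    Lipid heavy atoms within ``slab_half_width`` of the membrane midplane
    are rasterized onto an (x, y) grid; the radius is that of the largest
    disc centered at the given center (default: protein centroid, else
    box center) lying fully inside the lipid-free region, i.e. the
    distance to the nearest occupied cell.  Returns None ("no pore")
    when the center cell itself is occupied or when the disc radius
    falls below ``min_radius``, under which a void is indistinguishable
    from ordinary packing gaps.  Accuracy is limited by the grid spacing.
    """
    if grid > 2.0:
        raise ValueError(f"grid {grid} nm too coarse; use <= 2 nm")
    lipid_heavy = np.concatenate(
        [system.heavy_atom_indices(r) for r in system.lipid_residues()])
    pos = frame.positions[lipid_heavy]
    ref_z = np.array([frame.positions[system.headgroup_reference_index(r), 2]
                      for r in system.lipid_residues()])
    midplane = ref_z.mean()
    slab = pos[np.abs(pos[:, 2] - midplane) <= slab_half_width]

    nx = max(1, int(np.ceil(frame.box[0] / grid)))
    ny = max(1, int(np.ceil(frame.box[1] / grid)))
    occupied = np.zeros((nx, ny), dtype=bool)
    ix = np.clip((slab[:, 0] / grid).astype(int), 0, nx - 1)
    iy = np.clip((slab[:, 1] / grid).astype(int), 0, ny - 1)
    occupied[ix, iy] = True

    if center is None:
        prot = system.protein_residues()
        if len(prot):
            atoms = np.concatenate([system.atoms_of_residue(r) for r in prot])
            cxy = frame.positions[atoms, :2].mean(axis=0)
        else:
            cxy = frame.box[:2] / 2.0
        center = (float(cxy[0]), float(cxy[1]))
    ci = min(nx - 1, max(0, int(center[0] / grid)))
    cj = min(ny - 1, max(0, int(center[1] / grid)))
    if occupied[ci, cj]:
        return None
    if not occupied.any():
        # membrane absent entirely; pore radius bounded by the box
        radius = float(min(frame.box[:2]) / 2.0)
    else:
        oi, oj = np.nonzero(occupied)
        cell_xy = np.column_stack(((oi + 0.5) * grid, (oj + 0.5) * grid))
        radius = float(np.min(np.linalg.norm(cell_xy - np.array(center), axis=1)))
    if radius < min_radius:
        return None
    return PoreMeasure(center=center, radius=radius,
                       method="largest-inscribed-disc", grid_nm=grid)


# ---------------------------------------------------------------------------
# Crown deformation
# ---------------------------------------------------------------------------

def deformation_profile(frame: Frame, system: MolecularSystem,
                        bin_dr: float = 1.0,
                        far_field_fraction: float = 0.25,
                        center: tuple[float, float] | None = None,
                        leaflet: str = "outer") -> DeformationProfile:
    """Radial profile of headgroup height and the crown amplitude.

    Headgroup reference z of the chosen leaflet is binned by radial
    distance from the (ring) center; the far-field reference is the
    count-weighted mean z over the outermost ``far_field_fraction`` of
    the radial range.  The crown height is the apex height above that
    reference, with the apex estimated by linear extrapolation to r = 0
    through the two innermost populated bins (at their radial
    centroids): bin-averaging a profile that keeps rising toward the
    center would otherwise bias the amplitude low by ~ half a bin times
    the slope.  Invariant under rigid z-translation by construction.
    """
    lipids = [r for r in system.lipid_residues() if system.leaflet[r] == leaflet]
    if not lipids:
        raise ValueError(f"no lipids in leaflet {leaflet!r}; assign leaflets first")
    ref_idx = [system.headgroup_reference_index(r) for r in lipids]
    xy = frame.positions[ref_idx, :2]
    z = frame.positions[ref_idx, 2]
    if center is None:
        center = (float(frame.box[0] / 2), float(frame.box[1] / 2))
    r = np.linalg.norm(xy - np.asarray(center), axis=1)
    r_max = r.max()
    n_bins = max(1, int(np.ceil(r_max / bin_dr)))
    edges = np.linspace(0, n_bins * bin_dr, n_bins + 1)
    which = np.clip(np.digitize(r, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=z, minlength=n_bins)
    r_sums = np.bincount(which, weights=r, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_z = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    far_mask = (edges[1:] >= (1.0 - far_field_fraction) * r_max) & (counts > 0)
    if not far_mask.any():
        raise ValueError("no populated far-field bins; widen far_field_fraction")
    far_z = float(sums[far_mask].sum() / counts[far_mask].sum())
    populated = np.flatnonzero(counts > 0)
    b1 = populated[0]
    if len(populated) > 1:
        b2 = populated[1]
        r1, z1 = r_sums[b1] / counts[b1], mean_z[b1]
        r2, z2 = r_sums[b2] / counts[b2], mean_z[b2]
        apex = z1 - (z2 - z1) / (r2 - r1) * r1
    else:
        apex = mean_z[b1]
    crown = float(apex - far_z)
    return DeformationProfile(bin_centers=0.5 * (edges[:-1] + edges[1:]),
                              mean_z=mean_z, counts=counts,
                              far_field_z=far_z, crown_height=crown)


# ---------------------------------------------------------------------------
# Hairpin tilt
# ---------------------------------------------------------------------------

def hairpin_tilt(frame: Frame, system: MolecularSystem, subunit: int,
                 base_atoms: frozenset[str] = frozenset({"CB"}),
                 tip_atoms: frozenset[str] = frozenset({"CT"})) -> float:
    """Tilt of a subunit's hairpin vector against the membrane plane, deg.

    The vector runs from the centroid of the base selection to the
    centroid of the tip selection; the tilt is 90 deg minus the angle to
    the z axis (90 = membrane normal, 0 = in plane).
    """
    members = np.flatnonzero(system.subunit == subunit)
    if len(members) == 0:
        raise ValueError(f"no residues labeled subunit {subunit}")
    base, tip = [], []
    for ridx in members:
        for i in system.atoms_of_residue(ridx):
            if system.atoms[i].name in base_atoms:
                base.append(frame.positions[i])
            elif system.atoms[i].name in tip_atoms:
                tip.append(frame.positions[i])
    if not base or not tip:
        raise ValueError(f"subunit {subunit}: base/tip selections are empty")
    v = np.mean(tip, axis=0) - np.mean(base, axis=0)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("zero-length hairpin vector")
    return float(np.degrees(np.arcsin(np.clip(v[2] / norm, -1.0, 1.0))))


def hairpin_tilts(frame: Frame, system: MolecularSystem, **kwargs) -> np.ndarray:
    """Per-subunit hairpin tilt angles (degrees)."""
    return np.array([hairpin_tilt(frame, system, s, **kwargs)
                     for s in range(_n_subunits(system))])


# ---------------------------------------------------------------------------
# Ring circularity and crack detection
# ---------------------------------------------------------------------------

def subunit_centroids(frame: Frame, system: MolecularSystem,
                      heavy_only: bool = True) -> np.ndarray:
    """(n_subunits, 3) centroids of each subunit's globular heavy atoms.

    Hairpin pseudo-residues (base/tip beads) are excluded so the centroid
    tracks the globular body.
    """
    out = []
    for s in range(_n_subunits(system)):
        atoms = []
        for ridx in np.flatnonzero(system.subunit == s):
            if str(system.residue_names[ridx]) == "HPN":
                continue
            idx = (system.heavy_atom_indices(ridx) if heavy_only
                   else system.atoms_of_residue(ridx))
            atoms.extend(idx)
        out.append(frame.positions[atoms].mean(axis=0))
    return np.array(out)


def circle_fit(points_xy: np.ndarray) -> tuple[tuple[float, float], float, float]:
    """Algebraic (Kasa) circle fit: returns (center, radius, RMS residual).

    Solves the linear least-squares system for (cx, cy, r) minimizing the
    algebraic distance; the residual is the RMS of |r_i - R| over points.
    Closed form and deterministic; exact (residual ~1e-15) for points on
    a true circle.
    """
    pts = np.asarray(points_xy, dtype=float)
    if len(pts) < 3:
        raise ValueError("circle fit requires at least 3 points")
    A = np.column_stack([2 * pts[:, 0], 2 * pts[:, 1], np.ones(len(pts))])
    b = (pts ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0], sol[1]
    radius = float(np.sqrt(sol[2] + cx ** 2 + cy ** 2))
    dist = np.linalg.norm(pts - [cx, cy], axis=1)
    rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
    return (float(cx), float(cy)), radius, rms


def interface_contact_counts(frame: Frame, system: MolecularSystem,
                             cutoff: float = 0.36,
                             ring_closed: bool = False) -> dict[tuple[int, int], int]:
    """Heavy-atom contact-pair counts between adjacent subunits' globular
    domains (hairpin pseudo-residues excluded)."""
    nsub = _n_subunits(system)
    atoms_of_sub: dict[int, np.ndarray] = {}
    for s in range(nsub):
        atoms = []
        for ridx in np.flatnonzero(system.subunit == s):
            if str(system.residue_names[ridx]) == "HPN":
                continue
            atoms.extend(system.heavy_atom_indices(ridx))
        atoms_of_sub[s] = np.array(atoms, dtype=int)
    pairs = [(i, i + 1) for i in range(nsub - 1)]
    if ring_closed and nsub > 2:
        pairs.append((nsub - 1, 0))
    counts = {}
    for i, j in pairs:
        pi = frame.positions[atoms_of_sub[i]]
        pj = frame.positions[atoms_of_sub[j]]
        tree = cKDTree(pj)
        counts[(i, j)] = int(sum(len(h) for h in
                                 tree.query_ball_point(pi, r=cutoff)))
    return counts


def detect_cracks(interface_counts: pd.DataFrame | dict[tuple[int, int], np.ndarray],
                  threshold: int = 5, persistence_frames: int = 50,
                  dt_ns: float = 1.0) -> CrackReport:
    """First sustained loss of inter-subunit contacts per interface.

    An interface is cracked at the first frame where its contact count
    stays strictly below ``threshold`` for at least
    ``persistence_frames`` consecutive frames (including runs that last
    to the end of the series).  ``threshold`` 0 can never crack.
    """
    if isinstance(interface_counts, pd.DataFrame):
        series = {tuple(int(x) for x in col.split("-")):
                  interface_counts[col].to_numpy()
                  for col in interface_counts.columns if col != "frame"}
    else:
        series = {k: np.asarray(v) for k, v in interface_counts.items()}
    cracked: dict[tuple[int, int], float] = {}
    for iface, counts in series.items():
        below = counts < threshold
        run = 0
        for t, b in enumerate(below):
            run = run + 1 if b else 0
            if run >= persistence_frames:
                cracked[iface] = (t - persistence_frames + 1) * dt_ns
                break
    return CrackReport(cracked=cracked, threshold=threshold,
                       persistence_frames=persistence_frames)


def ring_circularity_and_cracks(centroid_series: np.ndarray,
                                interface_counts: pd.DataFrame,
                                threshold: int = 5,
                                persistence_frames: int = 50,
                                dt_ns: float = 1.0
                                ) -> tuple[np.ndarray, CrackReport]:
    """Per-frame circle-fit RMS residuals plus the crack report.

    ``centroid_series``: (n_frames, n_subunits, >=2) subunit centroid
    coordinates (x, y used).
    """
    residuals = np.array([circle_fit(c[:, :2])[2] for c in centroid_series])
    report = detect_cracks(interface_counts, threshold, persistence_frames, dt_ns)
    return residuals, report


# ---------------------------------------------------------------------------
# Membrane thinning
# ---------------------------------------------------------------------------

def membrane_thinning(frame: Frame, system: MolecularSystem,
                      bin_xy: float = 1.0) -> tuple[np.ndarray, float]:
    """Local inter-leaflet phosphate distance on an (x, y) grid.

    Per bin: (mean outer-leaflet headgroup z) - (mean inner-leaflet
    headgroup z); bins missing either leaflet are NaN, never zero.
    Returns (thickness map, bulk reference = median of finite bins).
    """
    nx = max(1, int(np.ceil(frame.box[0] / bin_xy)))
    ny = max(1, int(np.ceil(frame.box[1] / bin_xy)))
    sums = {tag: np.zeros((nx, ny)) for tag in ("inner", "outer")}
    counts = {tag: np.zeros((nx, ny), dtype=int) for tag in ("inner", "outer")}
    any_lipid = False
    for ridx in system.lipid_residues():
        tag = system.leaflet[ridx]
        if tag not in sums:
            continue
        any_lipid = True
        p = frame.positions[system.headgroup_reference_index(ridx)]
        i = min(nx - 1, max(0, int(p[0] / bin_xy)))
        j = min(ny - 1, max(0, int(p[1] / bin_xy)))
        sums[tag][i, j] += p[2]
        counts[tag][i, j] += 1
    if not any_lipid:
        raise ValueError("no leaflet-labeled lipids; assign leaflets first")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = {tag: np.where(counts[tag] > 0, sums[tag] / np.maximum(counts[tag], 1),
                              np.nan) for tag in sums}
    thickness = mean["outer"] - mean["inner"]
    finite = thickness[np.isfinite(thickness)]
    if len(finite) == 0:
        raise ValueError("no bin holds both leaflets; coarsen bin_xy")
    return thickness, float(np.median(finite))
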