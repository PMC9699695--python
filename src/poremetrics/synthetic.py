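"""Seeded synthetic systems with recorded ground truth.

Every analysis stage in this package has a generator here producing the
input class it consumes — pressure/box series, bilayer patches with
optional pore/crown/thinning, protein arcs and rings with hairpins,
planted lipid-contact schedules, ion z-paths, water columns — together
with a :class:`GroundTruth` recording the planted parameters, so
analysis-versus-truth tests can be generated programmatically.

All generators take an explicit integer seed and are deterministic given
it; there is no hidden global RNG state.  Systems are built from
pseudo-atoms (single-bead headgroups, bead-cluster protein domains):
the analysis operators only require positions, heavy-atom flags and
species/leaflet/subunit labels, not chemically complete molecules.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .edge_mechanics import PressureBoxSeries
from .structures import Atom, Frame, MolecularSystem, assign_subunits
from .units import BAR_NM2_TO_PN

#: area per phospholipid headgroup used for capacity checks [nm^2]
AREA_PER_LIPID_NM2 = 0.65


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic fixture."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(f"not serializable: {type(o)}")
        text = json.dumps({"generator": self.generator, "seed": self.seed,
                           "params": self.params}, indent=2, default=_default,
                          sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Pressure/box series
# ---------------------------------------------------------------------------

def synth_pressure_series(gamma_true: float, box_xy: float = 20.0,
                          noise_sd: float = 0.0, n_frames: int = 1000,
                          seed: int = 0, dt_ns: float = 0.01,
                          n_edges: int = 2
                          ) -> tuple[PressureBoxSeries, GroundTruth]:
    """Stationary pressure/box series whose two-edge tension estimator has
    expectation ``gamma_true`` (pN).

    Emulates the fixed-edge-length protocol: the box is constant
    (Lx = Ly = box_xy), the lateral pressures fluctuate i.i.d. around
    1 bar, and the normal pressure around ``1 - delta`` with the mean
    anisotropy ``delta`` chosen so that
    (1/n_edges) * <Lx*Ly*((Pxx+Pyy)/2 - Pzz)> * 0.1 = gamma_true.
    Negative tensions (edge under compression) are allowed.
    """
    if box_xy <= 0:
        raise ValueError("box_xy must be positive")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    delta = gamma_true * n_edges / (BAR_NM2_TO_PN * box_xy ** 2)
    time = np.arange(n_frames) * dt_ns
    noise = (lambda: rng.normal(0.0, noise_sd, n_frames)) if noise_sd \
        else (lambda: np.zeros(n_frames))
    pxx = 1.0 + noise()
    pyy = 1.0 + noise()
    pzz = (1.0 - delta) + noise()
    series = PressureBoxSeries(time=time, Pxx=pxx, Pyy=pyy, Pzz=pzz,
                               Lx=np.full(n_frames, box_xy),
                               Ly=np.full(n_frames, box_xy))
    truth = GroundTruth("synth_pressure_series", seed,
                        {"gamma_true_pn": gamma_true, "box_xy_nm": box_xy,
                         "noise_sd_bar": noise_sd, "n_frames": n_frames,
                         "mean_anisotropy_bar": delta, "n_edges": n_edges})
    return series, truth


# ---------------------------------------------------------------------------
# Membrane patch
# ---------------------------------------------------------------------------

def _sample_positions(rng: np.random.Generator, n: int, box_xy: float,
                      pore_radius: float | None, center: np.ndarray,
                      min_spacing: float) -> np.ndarray:
    """Rejection-sample n (x, y) points: outside the pore disc, pairwise
    farther than min_spacing."""
    accepted: list[np.ndarray] = []
    attempts = 0
    max_attempts = 20000 * max(n, 1)
    while len(accepted) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("rejection sampling stalled; patch overcrowded")
        p = rng.uniform(0.0, box_xy, size=2)
        if pore_radius is not None and np.linalg.norm(p - center) < pore_radius:
            continue
        if accepted and np.min(np.linalg.norm(np.array(accepted) - p, axis=1)) < min_spacing:
            continue
        accepted.append(p)
    return np.array(accepted)


def synth_membrane_patch(inner_counts: Mapping[str, int],
                         outer_counts: Mapping[str, int],
                         box_xy: float | None = None,
                         area: float | None = None,
                         pore_radius: float | None = None,
                         crown_height: float | None = None,
                         ring_radius: float | None = None,
                         thin_annulus: tuple[float, float, float] | None = None,
                         leaflet_separation: float = 4.0,
                         lz: float = 10.0,
                         min_spacing: float = 0.45,
                         seed: int = 0
                         ) -> tuple[MolecularSystem, Frame, GroundTruth]:
    """Bilayer patch of pseudo-lipids on two z-planes.

    Each phospholipid contributes a headgroup bead ("P") on its leaflet
    plane plus three laterally jittered tail beads filling the bilayer
    core down to the local midplane; sterols ("CHOL") contribute their
    hydroxyl bead ("O3") plus one tail bead.  When a pore is requested,
    every bead is kept outside the lipid-free disc (tail jitter is
    projected back to the rim), so the planted radius is the true
    lipid-edge radius.  Options:

    * ``pore_radius``: a lipid-free disc at the patch center.
    * ``crown_height`` with ``ring_radius``: lipids at radial distance
      r < ring_radius raised by ``crown_height * (1 - r/ring_radius)``
      (linear profile; the planted shape is recorded in the truth).
    * ``thin_annulus`` = (r0, r1, factor): leaflet planes pulled toward
      the midplane inside the annulus so the local thickness becomes
      ``factor`` times the bulk separation.
    """
    if box_xy is None:
        box_xy = math.sqrt(area) if area is not None else 20.0
    area = box_xy ** 2
    usable = area - (math.pi * pore_radius ** 2 if pore_radius else 0.0)
    n_max = max(sum(inner_counts.values()), sum(outer_counts.values()))
    if usable < AREA_PER_LIPID_NM2 * n_max:
        raise ValueError(
            f"patch overcrowded: {n_max} lipids need >= "
            f"{AREA_PER_LIPID_NM2 * n_max:.1f} nm^2 usable area, have {usable:.1f}")
    rng = np.random.default_rng(seed)
    center = np.array([box_xy / 2, box_xy / 2])
    z_mid = lz / 2.0
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    resid = 0
    for tag, counts, sign in (("inner", inner_counts, -1.0),
                              ("outer", outer_counts, +1.0)):
        n_leaflet = sum(counts.values())
        xy = _sample_positions(rng, n_leaflet, box_xy, pore_radius, center,
                               min_spacing)
        k = 0
        for species in counts:
            for _ in range(counts[species]):
                resid += 1
                x, y = xy[k]
                k += 1
                z_plane = z_mid + sign * leaflet_separation / 2.0
                r = np.linalg.norm([x - center[0], y - center[1]])
                if thin_annulus is not None:
                    r0, r1, factor = thin_annulus
                    if r0 <= r < r1:
                        z_plane -= sign * leaflet_separation * (1.0 - factor) / 2.0
                if crown_height is not None and ring_radius:
                    if r < ring_radius:
                        z_plane += crown_height * (1.0 - r / ring_radius)
                z_core = z_plane - sign * leaflet_separation / 2.0  # local midplane
                if species == "CHOL":
                    beads = [("O3", np.array([x, y, z_plane]))]
                    tail_z = [z_core + sign * 0.3]
                else:
                    beads = [("P", np.array([x, y, z_plane]))]
                    tail_z = [z_core + sign * 0.6, z_core + sign * 0.2,
                              z_core - sign * 0.2]
                for tz in tail_z:
                    jxy = np.array([x, y]) + rng.uniform(-0.15, 0.15, size=2)
                    if pore_radius is not None:
                        rj = np.linalg.norm(jxy - center)
                        if rj < pore_radius:
                            jxy = center + (jxy - center) / max(rj, 1e-9) \
                                * (pore_radius + 0.02)
                    beads.append(("C2", np.array([jxy[0], jxy[1], tz])))
                for name, xyz in beads:
                    atoms.append(Atom(name, species, resid))
                    coords.append(xyz)
    system = MolecularSystem(atoms)
    frame = Frame(time=0.0, positions=np.array(coords),
                  box=np.array([box_xy, box_xy, lz]))
    truth = GroundTruth("synth_membrane_patch", seed, {
        "inner_counts": dict(inner_counts), "outer_counts": dict(outer_counts),
        "box_xy_nm": box_xy, "pore_radius_nm": pore_radius,
        "crown_height_nm": crown_height, "ring_radius_nm": ring_radius,
        "thin_annulus": list(thin_annulus) if thin_annulus else None,
        "leaflet_separation_nm": leaflet_separation, "midplane_z_nm": z_mid})
    return system, frame, truth


# ---------------------------------------------------------------------------
# Protein arcs and rings
# ---------------------------------------------------------------------------

def synth_ring(n_subunits: int, ring_radius: float = 6.0,
               arc_fraction: float = 1.0, hairpin_tilt_deg: float = 55.0,
               seed: int = 0, z_plane: float = 5.0, lz: float = 12.0,
               hairpin_length: float = 1.5, box_pad: float = 4.0
               ) -> tuple[MolecularSystem, Frame, GroundTruth]:
    """Arc or ring of pseudo-subunits with transmembrane hairpins.

    Each subunit holds a globular pseudo-domain (bead clusters on the
    ring circle, 1 nm above the membrane plane) and a two-bead hairpin
    (base "CB" on the plane, tip "CT" displaced at the planted tilt).
    Subunits are equally spaced over ``arc_fraction`` of the circle;
    neighbouring subunits' interface bead stacks sit within heavy-atom
    contact distance, so adjacent interfaces start un-cracked.
    """
    if n_subunits < 1:
        raise ValueError("n_subunits must be >= 1")
    if not 0.0 < arc_fraction <= 1.0:
        raise ValueError("arc_fraction must be in (0, 1]")
    box_xy = 2 * (ring_radius + box_pad)
    cx = cy = box_xy / 2.0
    delta = 2 * math.pi * arc_fraction / n_subunits
    eps = 0.1 / ring_radius              # interface stack half-gap [rad]
    z_glob = z_plane + 1.0
    tilt = math.radians(hairpin_tilt_deg)

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    resid = 0

    def ring_point(theta: float, radius: float, z: float) -> np.ndarray:
        return np.array([cx + radius * math.cos(theta),
                         cy + radius * math.sin(theta), z])

    # body beads between the interface stacks, ~0.4 nm apart
    span = delta - 4 * eps
    n_body = max(2, int(ring_radius * span / 0.4))
    for k in range(n_subunits):
        phi0 = k * delta
        resid += 1
        for theta in (phi0 + eps, phi0 + delta - eps):      # interface stacks
            for dz in (0.0, 0.15, 0.30):
                atoms.append(Atom("C1", "GBD", resid))
                coords.append(ring_point(theta, ring_radius, z_glob + dz))
        for theta in np.linspace(phi0 + 2 * eps, phi0 + delta - 2 * eps, n_body):
            atoms.append(Atom("C2", "GBD", resid))
            coords.append(ring_point(theta, ring_radius, z_glob))
        # hairpin: base on the membrane plane, tip tilted toward the axis
        resid += 1
        theta_c = phi0 + delta / 2.0
        base = ring_point(theta_c, ring_radius - 1.0, z_plane)
        inward = np.array([-math.cos(theta_c), -math.sin(theta_c), 0.0])
        tip = base + hairpin_length * (math.cos(tilt) * inward
                                       + math.sin(tilt) * np.array([0, 0, 1.0]))
        atoms.append(Atom("CB", "HPN", resid))
        coords.append(base)
        atoms.append(Atom("CT", "HPN", resid))
        coords.append(tip)

    system = MolecularSystem(atoms)
    assign_subunits(system, n_subunits)
    frame = Frame(time=0.0, positions=np.array(coords),
                  box=np.array([box_xy, box_xy, lz]))
    truth = GroundTruth("synth_ring", seed, {
        "n_subunits": n_subunits, "ring_radius_nm": ring_radius,
        "arc_fraction": arc_fraction, "hairpin_tilt_deg": hairpin_tilt_deg,
        "gap_angle_rad": 2 * math.pi * (1 - arc_fraction),
        "center_xy": [cx, cy],
        "subunit_of_residue": system.subunit.tolist()})
    return system, frame, truth


def synth_crack_trajectory(n_subunits: int = 16,
                           crack_interface: tuple[int, int] = (8, 9),
                           crack_frame: int = 890, n_frames: int = 1000,
                           dt_ns: float = 1.0, gap_nm: float = 1.0,
                           ring_radius: float = 6.0,
                           arc_fraction: float = 16 / 33,
                           seed: int = 0
                           ) -> tuple[MolecularSystem, list[Frame], GroundTruth]:
    """Arc trajectory that cracks at one adjacent interface.

    Up to ``crack_frame`` the arc is rigid; from that frame on the
    subunits beyond the cracked interface are rotated about the ring
    center so the interface gap opens to ``gap_nm`` and its inter-subunit
    contacts vanish, while all other interfaces stay intact.
    """
    i, j = crack_interface
    if j != i + 1 or not 0 <= i < n_subunits - 1:
        raise ValueError("crack_interface must be an adjacent pair (i, i+1)")
    system, frame0, base_truth = synth_ring(
        n_subunits, ring_radius=ring_radius, arc_fraction=arc_fraction, seed=seed)
    center = np.array(base_truth.params["center_xy"])
    dtheta = gap_nm / ring_radius
    rot = np.array([[math.cos(dtheta), -math.sin(dtheta)],
                    [math.sin(dtheta), math.cos(dtheta)]])
    moved = np.isin(system.subunit[system.residue_of_atom], np.arange(j, n_subunits))
    cracked_pos = frame0.positions.copy()
    rel = cracked_pos[moved, :2] - center
    cracked_pos[moved, :2] = rel @ rot.T + center
    frames = [Frame(time=t * dt_ns,
                    positions=frame0.positions if t < crack_frame else cracked_pos,
                    box=frame0.box) for t in range(n_frames)]
    truth = GroundTruth("synth_crack_trajectory", seed, {
        **base_truth.params, "crack_interface": list(crack_interface),
        "crack_frame": crack_frame, "crack_time_ns": crack_frame * dt_ns,
        "gap_nm": gap_nm, "n_frames": n_frames, "dt_ns": dt_ns})
    return system, frames, truth


# ---------------------------------------------------------------------------
# Planted lipid-contact schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactEvent:
    """One planted binding event: a lipid close to one protein residue
    (or bridging two) over [start, end) frames at ``approach`` nm, with
    optional mid-event excursions to a looser distance."""

    lipid: int                      # 0-based lipid number
    residues: tuple[int, ...]       # 1 or 2 protein residue numbers
    start: int
    end: int                        # half-open
    approach: float = 0.30
    excursions: tuple[tuple[int, int, float], ...] = ()


def synth_contact_traces(schedule: Sequence[ContactEvent], n_frames: int,
                         n_protein: int | None = None,
                         n_lipids: int | None = None,
                         far: float = 2.0, spacing: float = 0.5,
                         dt_ns: float = 1.0, seed: int = 0
                         ) -> tuple[MolecularSystem, list[Frame],
                                    dict[tuple[int, int], np.ndarray], GroundTruth]:
    """Coordinate realization of a planted contact schedule.

    Protein residues (one "CA" bead each, one subunit per residue) sit on
    a line ``spacing`` nm apart; each lipid is one "P" headgroup bead.
    During an event the lipid sits exactly at the scheduled distance from
    its target residue(s) (perpendicular offset, so distances to other
    residues stay above the release cutoff); outside events it rests
    ``far`` nm away.  Returns (system, frames, per-pair distance series
    for every scheduled pair, truth).
    """
    if n_protein is None:
        n_protein = max(r for ev in schedule for r in ev.residues) + 1 if schedule else 1
    if n_lipids is None:
        n_lipids = max((ev.lipid for ev in schedule), default=-1) + 1
    for ev in schedule:
        if not (0 <= ev.start < ev.end <= n_frames):
            raise ValueError(f"event {ev} outside [0, {n_frames})")
        if len(ev.residues) not in (1, 2):
            raise ValueError("events target 1 or 2 residues")
        for (xs, xe, xd) in ev.excursions:
            if not (ev.start <= xs < xe <= ev.end):
                raise ValueError(f"excursion [{xs},{xe}) outside event {ev}")
    by_pair: dict[tuple[int, int], list[ContactEvent]] = {}
    by_lipid: dict[int, list[ContactEvent]] = {}
    for ev in schedule:
        by_lipid.setdefault(ev.lipid, []).append(ev)
        for r in ev.residues:
            by_pair.setdefault((ev.lipid, r), []).append(ev)
    for (lipid, r), evs in by_pair.items():
        evs_sorted = sorted(evs, key=lambda e: e.start)
        for a, b in zip(evs_sorted, evs_sorted[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping events for lipid {lipid}, "
                                 f"residue {r}")
    for lipid, evs in by_lipid.items():
        evs_sorted = sorted(evs, key=lambda e: e.start)
        for a, b in zip(evs_sorted, evs_sorted[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping events for lipid {lipid}")

    y0, z0 = 5.0, 5.0
    prot_x = np.arange(n_protein) * spacing + 2.0
    box = np.array([prot_x[-1] + 4.0, 10.0, 10.0])
    atoms = [Atom("CA", "GLY", r + 1) for r in range(n_protein)]
    home_x = {lip: prot_x[by_lipid[lip][0].residues[0]] if lip in by_lipid
              else 2.0 + lip * spacing for lip in range(n_lipids)}
    for lip in range(n_lipids):
        atoms.append(Atom("P", "POPC", n_protein + lip + 1))
    system = MolecularSystem(atoms)
    assign_subunits(system, n_protein)

    def lipid_pos(lip: int, t: int) -> np.ndarray:
        for ev in by_lipid.get(lip, ()):
            if ev.start <= t < ev.end:
                d = ev.approach
                for (xs, xe, xd) in ev.excursions:
                    if xs <= t < xe:
                        d = xd
                if len(ev.residues) == 1:
                    return np.array([prot_x[ev.residues[0]], y0 + d, z0])
                xa, xb = prot_x[ev.residues[0]], prot_x[ev.residues[1]]
                half = abs(xb - xa) / 2.0
                if d <= half:
                    raise ValueError(f"approach {d} too small to bridge "
                                     f"residues {ev.residues} ({2*half} nm apart)")
                return np.array([(xa + xb) / 2.0,
                                 y0 + math.sqrt(d ** 2 - half ** 2), z0])
        return np.array([home_x[lip], y0 + far, z0])

    frames = []
    for t in range(n_frames):
        pos = np.empty((system.n_atoms, 3))
        pos[:n_protein] = np.column_stack([prot_x, np.full(n_protein, y0),
                                           np.full(n_protein, z0)])
        for lip in range(n_lipids):
            pos[n_protein + lip] = lipid_pos(lip, t)
        frames.append(Frame(time=t * dt_ns, positions=pos, box=box))

    distances: dict[tuple[int, int], np.ndarray] = {}
    for (lip, r) in by_pair:
        lip_res_idx = n_protein + lip   # residue index within the system
        d = np.array([np.linalg.norm(frames[t].positions[n_protein + lip]
                                     - frames[t].positions[r])
                      for t in range(n_frames)])
        distances[(lip_res_idx, r)] = d
    truth = GroundTruth("synth_contact_traces", seed, {
        "n_frames": n_frames, "n_protein": n_protein, "n_lipids": n_lipids,
        "far_nm": far, "spacing_nm": spacing,
        "schedule": [{"lipid": ev.lipid, "residues": list(ev.residues),
                      "start": ev.start, "end": ev.end,
                      "approach_nm": ev.approach,
                      "excursions": [list(x) for x in ev.excursions]}
                     for ev in schedule]})
    return system, frames, distances, truth


# ---------------------------------------------------------------------------
# Ion z-paths
# ---------------------------------------------------------------------------

PATH_TYPES = ("full_up", "full_down", "rebound", "boundary_dither",
              "pbc_wrapped_cross")


def synth_ion_paths(plan: Sequence[tuple[str, str]],
                    slab: tuple[float, float] = (4.0, 8.0),
                    n_frames: int = 200, lz: float = 12.0, seed: int = 0,
                    jitter: float = 0.0
                    ) -> tuple[np.ndarray, list[str], GroundTruth]:
    """Wrapped ion z-trajectories with known crossing counts.

    ``plan`` lists (species, path_type) per ion; path types:

    * ``full_up`` / ``full_down``: one complete slab traversal.
    * ``rebound``: enters the slab and exits the same side (0 events).
    * ``boundary_dither``: oscillates across the lower face 50 times
      without ever reaching the upper face (0 events).
    * ``pbc_wrapped_cross``: one upward traversal that continues through
      the periodic z boundary (1 event after unwrapping).
    """
    z_low, z_high = slab
    if not 0 < z_low < z_high < lz:
        raise ValueError("require 0 < z_low < z_high < Lz")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_frames)
    below, above = z_low - 1.0, z_high + 1.0
    paths = []
    up = down = 0
    for species, ptype in plan:
        if ptype == "full_up":
            z = np.interp(t, [0, 0.25, 0.75, 1], [below, below, above, above])
            up += 1
        elif ptype == "full_down":
            z = np.interp(t, [0, 0.25, 0.75, 1], [above, above, below, below])
            down += 1
        elif ptype == "rebound":
            mid = (z_low + z_high) / 2.0
            z = np.interp(t, [0, 0.25, 0.5, 0.75, 1],
                          [below, below, mid, below, below])
        elif ptype == "boundary_dither":
            z = z_low + 0.3 * np.sin(2 * math.pi * 25 * t + math.pi)
        elif ptype == "pbc_wrapped_cross":
            end = lz + min(0.5, z_low / 2.0)
            z = np.interp(t, [0, 0.2, 0.9, 1], [below, below, end, end])
            up += 1
        else:
            raise ValueError(f"unknown path type {ptype!r}; use one of "
                             f"{PATH_TYPES}")
        if jitter:
            z = z + rng.normal(0.0, jitter, n_frames)
        paths.append(np.mod(z, lz))
    truth = GroundTruth("synth_ion_paths", seed, {
        "plan": [list(p) for p in plan], "slab": [z_low, z_high], "lz": lz,
        "n_frames": n_frames, "jitter": jitter,
        "events_up": up, "events_down": down, "net": up - down})
    return np.array(paths), [sp for sp, _ in plan], truth


# ---------------------------------------------------------------------------
# Water columns
# ---------------------------------------------------------------------------

def synth_water_column(z_low: float = 4.0, z_high: float = 8.0,
                       bin_dz: float = 0.3, n_per_bin: int = 2,
                       gap_bins: Sequence[int] = (), radius: float = 0.5,
                       axis_center: tuple[float, float] = (5.0, 5.0),
                       box_xy: float = 10.0, lz: float = 12.0, seed: int = 0
                       ) -> tuple[MolecularSystem, Frame, GroundTruth]:
    """Column of water oxygens spanning the slab, with optional empty bins.

    Bin edges replicate the continuity analysis (``n_bins =
    (z_high - z_low) // bin_dz``, last bin absorbing the remainder);
    every bin not listed in ``gap_bins`` receives ``n_per_bin`` oxygens
    near the axis.
    """
    rng = np.random.default_rng(seed)
    n_bins = max(1, int((z_high - z_low) // bin_dz))
    edges = np.linspace(z_low, z_high, n_bins + 1)
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    resid = 0
    for b in range(n_bins):
        if b in gap_bins:
            continue
        zc = 0.5 * (edges[b] + edges[b + 1])
        for _ in range(n_per_bin):
            resid += 1
            ang = rng.uniform(0, 2 * math.pi)
            rr = rng.uniform(0, 0.5 * radius)
            atoms.append(Atom("OW", "SOL", resid))
            coords.append(np.array([axis_center[0] + rr * math.cos(ang),
                                    axis_center[1] + rr * math.sin(ang), zc]))
    system = MolecularSystem(atoms)
    frame = Frame(time=0.0, positions=(np.array(coords) if coords
                                       else np.empty((0, 3))),
                  box=np.array([box_xy, box_xy, lz]))
    truth = GroundTruth("synth_water_column", seed, {
        "z_low": z_low, "z_high": z_high, "bin_dz": bin_dz,
        "n_bins": n_bins, "gap_bins": list(gap_bins),
        "continuous": len(gap_bins) == 0})
    return system, frame, truth
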