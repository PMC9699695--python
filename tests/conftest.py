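"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's algorithms: contacts
by all-pairs minimum-image arithmetic, permeation by a densely resampled
three-state machine, so the efficient implementations are checked
against independent routes.
"""

import numpy as np
import pytest

from poremetrics.structures import MolecularSystem, Frame


def brute_force_contacts(frame: Frame, system: MolecularSystem,
                         cutoff: float = 0.36) -> dict[tuple[int, int], float]:
    """All-pairs minimum-image contact map: (lipid res, protein res) ->
    min heavy-atom distance, for pairs with min distance <= cutoff."""
    box = frame.box
    out: dict[tuple[int, int], float] = {}
    prot = [(r, system.heavy_atom_indices(r)) for r in system.protein_residues()]
    for lres in system.lipid_residues():
        lidx = system.headgroup_heavy_indices(lres)
        if not len(lidx):
            continue
        lpos = frame.positions[lidx]
        for pres, pidx in prot:
            if not len(pidx):
                continue
            ppos = frame.positions[pidx]
            delta = np.abs(lpos[:, None, :] - ppos[None, :, :])
            delta = np.mod(delta, box)
            delta = np.minimum(delta, box - delta)
            dmin = float(np.sqrt((delta ** 2).sum(axis=2)).min())
            if dmin <= cutoff:
                out[(int(lres), int(pres))] = dmin
    return out


def brute_force_permeation(z_wrapped: np.ndarray, z_low: float, z_high: float,
                           lz: float, upsample: int = 200) -> tuple[int, int]:
    """(up, down) full-traversal counts by dense linear resampling of the
    unwrapped path and a literal below/inside/above state walk."""
    z = np.asarray(z_wrapped, dtype=float)
    jumps = np.diff(z)
    z_un = z.copy()
    z_un[1:] -= np.cumsum(np.round(jumps / lz)) * lz
    t = np.arange(len(z_un))
    fine = np.interp(np.linspace(0, len(z_un) - 1, len(z_un) * upsample), t, z_un)
    up = down = 0
    state = None          # 'below' | 'inside' | 'above' w.r.t. local image
    entry = None
    for zz in fine:
        k = np.floor((zz - z_low) / lz)
        local = zz - k * lz          # in [z_low, z_low + lz)
        region = "inside" if local < z_high else "outside"
        if state is None:
            state = region
            continue
        if region == "inside" and state == "outside":
            # which face did we come through? the nearer one, within the
            # inside region [z_low, z_high) of the local cell
            entry = "low" if (local - z_low) < (z_high - local) else "high"
            state = "inside"
        elif region == "outside" and state == "inside":
            # outside region spans [z_high, z_low + lz): its lower face is
            # 'high', its upper face is the next image's 'low'
            exit_face = "high" if (local - z_high) < (z_low + lz - local) \
                else "low"
            if entry == "low" and exit_face == "high":
                up += 1
            elif entry == "high" and exit_face == "low":
                down += 1
            state = "outside"
    return up, down


@pytest.fixture
def flat_patch():
    from poremetrics.synthetic import synth_membrane_patch
    from poremetrics.structures import assign_leaflets
    system, frame, truth = synth_membrane_patch({"POPC": 99}, {"POPC": 100},
                                                seed=11)
    assign_leaflets(system, frame)
    return system, frame, truth
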