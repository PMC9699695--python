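"""Membrane edge tension from the pressure tensor, and continuum bookkeeping.

The estimator targets the open-edge simulation protocol: a bilayer ribbon
with two open edges oriented along z, the box length along z fixed so the
edge length cannot relax, and the remaining two dimensions pressure
coupled.  Under that protocol the edge tension per unit length is

    gamma = (1/n_edges) * < Lx * Ly * [ (Pxx + Pyy)/2 - Pzz ] >

in bar*nm^2, converted to pN (factor 0.1), with n_edges = 2 for the
standard ribbon geometry.  Tension is positive when the normal (z)
pressure is tensile relative to the lateral pressures; the sign
convention is tied to the rotated-box protocol above.

The statistical error is the standard error over non-overlapping block
means; the block length must exceed the correlation time of the series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .units import BAR_NM2_TO_PN, PN_NM_TO_J, kbt_in_joule, kbt_in_pn_nm

logger = logging.getLogger(__name__)

TSV_COLUMNS = ["time_ns", "Pxx_bar", "Pyy_bar", "Pzz_bar", "Lx_nm", "Ly_nm"]


@dataclass
class PressureBoxSeries:
    """Time series of the diagonal pressure tensor and lateral box lengths.

    time in ns, pressures in bar, box lengths in nm.
    """

    time: np.ndarray
    Pxx: np.ndarray
    Pyy: np.ndarray
    Pzz: np.ndarray
    Lx: np.ndarray
    Ly: np.ndarray

    def __post_init__(self) -> None:
        arrays = [np.asarray(getattr(self, f), dtype=float)
                  for f in ("time", "Pxx", "Pyy", "Pzz", "Lx", "Ly")]
        n = len(arrays[0])
        if any(len(a) != n for a in arrays):
            raise ValueError("all series must have equal length")
        if n and (np.any(arrays[4] <= 0) or np.any(arrays[5] <= 0)):
            raise ValueError("box lengths must be positive")
        (self.time, self.Pxx, self.Pyy, self.Pzz, self.Lx, self.Ly) = arrays

    def __len__(self) -> int:
        return len(self.time)

    def select(self, mask: np.ndarray) -> "PressureBoxSeries":
        return PressureBoxSeries(*(a[mask] for a in
                                   (self.time, self.Pxx, self.Pyy,
                                    self.Pzz, self.Lx, self.Ly)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(zip(TSV_COLUMNS, (self.time, self.Pxx, self.Pyy,
                                                   self.Pzz, self.Lx, self.Ly))))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PressureBoxSeries":
        return cls(*(df[c].to_numpy() for c in TSV_COLUMNS))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PressureBoxSeries":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#"))

    def to_tsv(self, path: str | Path) -> None:
        from .fileio import write_tsv
        write_tsv(path, self.to_frame(),
                  comments=["pressure/box series: time ns, pressures bar, box nm"])


@dataclass
class EdgeTensionResult:
    gamma: float          # pN
    sem: float            # pN; nan when fewer than 2 blocks
    n_edges: int
    n_blocks: int
    discarded_ns: float


def retained_window(series: PressureBoxSeries, keep_last_ns: float,
                    total_ns: float | None = None) -> PressureBoxSeries:
    """Keep only the last ``keep_last_ns`` of the series.

    Frames with time >= total - keep_last are retained, where ``total``
    defaults to the last time stamp; keeping the full span is the
    identity.
    """
    if len(series) == 0:
        return series
    total = series.time.max() if total_ns is None else total_ns
    if keep_last_ns > total:
        raise ValueError(f"keep_last_ns={keep_last_ns} exceeds total span {total}")
    if keep_last_ns == 0:
        return series.select(np.zeros(len(series), dtype=bool))
    return series.select(series.time >= total - keep_last_ns)


def per_frame_tension(series: PressureBoxSeries, n_edges: int = 2) -> np.ndarray:
    """Instantaneous edge tension per frame in pN."""
    aniso = 0.5 * (series.Pxx + series.Pyy) - series.Pzz
    return series.Lx * series.Ly * aniso * BAR_NM2_TO_PN / n_edges


def edge_tension(series: PressureBoxSeries, n_edges: int = 2,
                 discard_ns: float = 0.0,
                 block_len_ns: float | None = None,
                 n_blocks: int | None = None) -> EdgeTensionResult:
    """Estimate the edge tension (pN) and its block-averaged SEM.

    Parameters
    ----------
    n_edges : number of open edges sharing the measured anisotropy (2 for
        the standard ribbon system).
    discard_ns : initial time span to drop before averaging.
    block_len_ns, n_blocks : the non-overlapping block scheme for the SEM;
        give one of the two.  Default: one tenth of the retained span
        (10 blocks).  With fewer than 2 complete blocks the SEM is nan.
    """
    if n_edges < 1:
        raise ValueError("n_edges must be >= 1")
    retained = series.select(series.time >= discard_ns) if discard_ns else series
    if len(retained) == 0:
        raise ValueError("no frames retained after discarding")
    gamma_t = per_frame_tension(retained, n_edges)
    gamma = float(gamma_t.mean())

    if n_blocks is not None:
        nb = int(n_blocks)
    else:
        span = retained.time.max() - retained.time.min()
        if block_len_ns is None:
            nb = 10
        else:
            nb = int(span // block_len_ns) if block_len_ns > 0 else 0
    nb = min(nb, len(retained))
    if nb >= 2:
        # equal-count blocks over the (time-ordered) retained frames
        order = np.argsort(retained.time, kind="stable")
        usable = (len(retained) // nb) * nb
        blocks = gamma_t[order][:usable].reshape(nb, -1).mean(axis=1)
        sem = float(blocks.std(ddof=1) / np.sqrt(nb))
    else:
        nb = max(nb, 1)
        sem = float("nan")
        logger.info("fewer than 2 blocks; SEM not available")
    if gamma < 0:
        logger.warning("negative edge tension %.3g pN (edge under compression)", gamma)
    return EdgeTensionResult(gamma=gamma, sem=sem, n_edges=n_edges,
                             n_blocks=nb, discarded_ns=discard_ns)


def edge_free_energy(gamma_pn: float, delta_len_nm: float,
                     temperature_k: float) -> tuple[float, float]:
    """Free-energy change for shortening an open edge by ``delta_len_nm``.

    Returns (delta_F in J, delta_F in units of kB*T).  A positive gamma
    and positive shortening give the energy *released*.
    """
    df_joule = gamma_pn * delta_len_nm * PN_NM_TO_J
    return df_joule, df_joule / kbt_in_joule(temperature_k)


def vesiculation_kappa_max(diameter_nm: float, gamma_pn: float,
                           temperature_k: float | None = None
                           ) -> tuple[float, float | None]:
    """Largest bending rigidity at which a circular patch of the given
    diameter is unstable toward vesiculation.

    The instability criterion pi*D*gamma = 8*pi*kappa gives
    kappa_max = D*gamma/8.  Returns (kappa in pN*nm, kappa in kBT or None
    if no temperature given).
    """
    if diameter_nm <= 0 or gamma_pn <= 0:
        raise ValueError("diameter and gamma must be positive")
    kappa = diameter_nm * gamma_pn / 8.0
    kbt = kappa / kbt_in_pn_nm(temperature_k) if temperature_k else None
    return kappa, kbt


def critical_diameter(kappa_pn_nm: float, gamma_pn: float) -> float:
    """Diameter above which a patch of rigidity kappa vesiculates: 8*kappa/gamma."""
    if kappa_pn_nm <= 0:
        raise ValueError("kappa must be positive")
    if gamma_pn == 0:
        warnings.warn("zero edge tension: critical diameter is infinite",
                      stacklevel=2)
        return float("inf")
    return 8.0 * kappa_pn_nm / gamma_pn
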