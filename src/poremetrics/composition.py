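"""Leaflet composition planning, charge/counterion accounting, asymmetry repair.

Plans integer lipid counts per leaflet from mole-percent recipes of an
asymmetric plasma-membrane mimetic, using largest-remainder (Hamilton)
apportionment; accounts formal leaflet charge; derives Na+/Cl- counts for
a 150 mM salt protocol where chloride serves as the neutralizing excess
ion; and rebalances leaflets after clash-driven lipid removal, treating
sterols and phospholipids as separate groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .units import WATER_MOLARITY

logger = logging.getLogger(__name__)


@dataclass
class LeafletRecipe:
    """Mole-percent recipe for one leaflet.

    ``species`` preserves table order (used for apportionment
    tie-breaking); ``mole_percent`` and ``charge`` are keyed by species.
    """

    species: list[str]
    mole_percent: dict[str, float]
    charge: dict[str, int]
    tag: str = ""

    def __post_init__(self) -> None:
        total = sum(self.mole_percent[s] for s in self.species)
        if any(self.mole_percent[s] < 0 for s in self.species):
            raise ValueError("mole percents must be non-negative")
        if not (99.0 <= total <= 101.0):
            raise ValueError(
                f"mole percents sum to {total:.2f}; expected within [99, 101] "
                f"before normalization")

    @classmethod
    def from_tsv(cls, path: str | Path, tag: str = "") -> "LeafletRecipe":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(species=list(df["species"]),
                   mole_percent=dict(zip(df["species"], df["mole_percent"])),
                   charge=dict(zip(df["species"], df["charge"])), tag=tag)


@dataclass
class LeafletPlan:
    """Integer per-species lipid counts for one leaflet."""

    counts: dict[str, int]
    tag: str = ""
    seed: int | None = None

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())


def plan_leaflet(recipe: LeafletRecipe, n_lipids: int) -> LeafletPlan:
    """Apportion ``n_lipids`` among the recipe species.

    Percents are first normalized to sum to 100 (printed tables often sum
    to 99.9 or 100.1 from rounding), then quotas ``pct * n / 100`` are
    allocated by the largest-remainder rule: floor every quota, then give
    the remaining lipids one-by-one to the largest fractional remainders,
    ties broken by recipe (table) order.
    """
    if n_lipids < 1:
        raise ValueError("n_lipids must be >= 1")
    pct = np.array([recipe.mole_percent[s] for s in recipe.species], dtype=float)
    quotas = pct / pct.sum() * n_lipids
    counts = np.floor(quotas).astype(int)
    remainders = quotas - counts
    short = n_lipids - counts.sum()
    # stable sort on -remainder keeps recipe order among ties
    for idx in np.argsort(-remainders, kind="stable")[:short]:
        counts[idx] += 1
    for s, c in zip(recipe.species, counts):
        if recipe.mole_percent[s] > 0 and c == 0:
            logger.info("species %s requested (%.1f%%) but receives 0 lipids "
                        "at n=%d", s, recipe.mole_percent[s], n_lipids)
    return LeafletPlan(counts=dict(zip(recipe.species, (int(c) for c in counts))),
                       tag=recipe.tag)


def leaflet_charge(plan: LeafletPlan, recipe: LeafletRecipe) -> int:
    """Net formal charge of a planned leaflet."""
    return sum(n * recipe.charge[s] for s, n in plan.counts.items())


def counterion_counts(n_water: int, system_net_charge: int,
                      concentration_mm: float = 150.0) -> tuple[int, int]:
    """Na+/Cl- counts for a salt-then-neutralize ion protocol.

    Sodium is added at the requested molarity relative to the water count
    (``c * n_water / 55.5 M``); the neutralizing species is then added on
    top: excess chloride when the system-plus-sodium charge is positive,
    extra sodium otherwise.  ``system_net_charge`` is the formal charge
    of membrane plus protein, before any ions.  Returns (n_Na, n_Cl).
    """
    if n_water <= 0:
        raise ValueError("n_water must be positive")
    n_na = round(concentration_mm / 1000.0 * n_water / WATER_MOLARITY)
    charge_with_na = system_net_charge + n_na
    if charge_with_na >= 0:
        return n_na, charge_with_na
    return n_na - charge_with_na, 0


@dataclass
class RemovalInstruction:
    leaflet: str
    group: str               # "sterol" or "phospholipid"
    species_counts: dict[str, int]

    @property
    def n_total(self) -> int:
        return sum(self.species_counts.values())


def asymmetry_repair(removed_inner: dict[str, int], removed_outer: dict[str, int],
                     plan_inner: LeafletPlan, plan_outer: LeafletPlan,
                     recipe_inner: LeafletRecipe, recipe_outer: LeafletRecipe,
                     sterol_species: set[str] = frozenset({"CHOL"}),
                     seed: int = 0) -> list[RemovalInstruction]:
    """Rebalance leaflets after clash-driven lipid removal.

    ``removed_inner``/``removed_outer`` tally, per species, the lipids
    already lost to protein clashes.  Sterols and phospholipids are
    balanced independently: for each group, the leaflet that lost fewer
    lipids (and thus now holds the surplus) loses additional randomly
    chosen lipids until the group's removal counts match.  Random choices
    are seeded and drawn from the surviving lipids in proportion to their
    counts, without replacement.
    """
    rng = np.random.default_rng(seed)
    instructions: list[RemovalInstruction] = []

    def group_of(species: str) -> str:
        return "sterol" if species in sterol_species else "phospholipid"

    for group in ("sterol", "phospholipid"):
        lost = {}
        for tag, removed in (("inner", removed_inner), ("outer", removed_outer)):
            lost[tag] = sum(n for s, n in removed.items() if group_of(s) == group)
        if lost["inner"] == lost["outer"]:
            continue
        surplus_tag = "outer" if lost["inner"] > lost["outer"] else "inner"
        n_remove = abs(lost["inner"] - lost["outer"])
        plan = plan_inner if surplus_tag == "inner" else plan_outer
        removed = removed_inner if surplus_tag == "inner" else removed_outer
        pool: list[str] = []
        for s, n in plan.counts.items():
            if group_of(s) == group:
                pool.extend([s] * (n - removed.get(s, 0)))
        if n_remove > len(pool):
            raise ValueError(
                f"cannot remove {n_remove} {group}s from {surplus_tag} "
                f"leaflet: only {len(pool)} remain")
        chosen = rng.choice(len(pool), size=n_remove, replace=False)
        species_counts: dict[str, int] = {}
        for i in chosen:
            species_counts[pool[i]] = species_counts.get(pool[i], 0) + 1
        instructions.append(RemovalInstruction(leaflet=surplus_tag, group=group,
                                               species_counts=species_counts))
    return instructions


# ---------------------------------------------------------------------------
# Default asymmetric plasma-membrane mimetic recipes
# ---------------------------------------------------------------------------
# Inner (cytosolic) leaflet: PE-rich, polyunsaturated, carries the anionic
# PS and PI(4,5)P2; outer leaflet: sphingomyelin/PC-rich.  40 mol %
# cholesterol in both.  Printed inner percents sum to 99.9 (rounding).

PLASMA_MEMBRANE_INNER = LeafletRecipe(
    tag="inner",
    species=["CHOL", "PSM", "PLPC", "POPC", "DPPC", "PLA20", "PDOPE",
             "SAPE", "POPE", "PAPS", "SAPS", "PIP2"],
    mole_percent={"CHOL": 40.4, "PSM": 1.0, "PLPC": 8.1, "POPC": 3.0,
                  "DPPC": 2.0, "PLA20": 11.1, "PDOPE": 8.1, "SAPE": 4.0,
                  "POPE": 3.0, "PAPS": 13.1, "SAPS": 1.0, "PIP2": 5.1},
    charge={"CHOL": 0, "PSM": 0, "PLPC": 0, "POPC": 0, "DPPC": 0,
            "PLA20": 0, "PDOPE": 0, "SAPE": 0, "POPE": 0,
            "PAPS": -1, "SAPS": -1, "PIP2": -4},
)

PLASMA_MEMBRANE_OUTER = LeafletRecipe(
    tag="outer",
    species=["CHOL", "PSM", "NSM", "LSM", "PLPC", "SOPC", "PAPC",
             "PLA20", "SAPS"],
    mole_percent={"CHOL": 40.0, "PSM": 12.0, "NSM": 9.0, "LSM": 8.0,
                  "PLPC": 15.0, "SOPC": 7.0, "PAPC": 5.0, "PLA20": 3.0,
                  "SAPS": 1.0},
    charge={"CHOL": 0, "PSM": 0, "NSM": 0, "LSM": 0, "PLPC": 0,
            "SOPC": 0, "PAPC": 0, "PLA20": 0, "SAPS": -1},
)
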