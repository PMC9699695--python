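"""Eisenberg consensus-scale hydrophobicity scoring of residue stretches.

Used to compare the pore-facing faces of the membrane-inserted beta-sheets
of different gasdermins: the sum of per-residue consensus hydrophobicities
(kcal/mol) over the pore-facing residues of each strand, and the relative
hydrophilicity of two such sheets.  More negative = more hydrophilic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

logger = logging.getLogger(__name__)

#: Eisenberg consensus hydrophobicity scale, kcal/mol per residue.
EISENBERG_SCALE: dict[str, float] = {
    "A": 0.25, "R": -1.76, "N": -0.64, "D": -0.72, "C": 0.04,
    "Q": -0.69, "E": -0.62, "G": 0.16, "H": -0.40, "I": 0.73,
    "L": 0.53, "K": -1.10, "M": 0.26, "F": 0.61, "P": -0.07,
    "S": -0.26, "T": -0.18, "W": 0.37, "Y": 0.02, "V": 0.54,
}


def load_scale(path: str | Path) -> dict[str, float]:
    """Load an alternative scale from a two-column TSV (residue, kcal/mol)."""
    scale: dict[str, float] = {}
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        fields = ln.split("\t") if "\t" in ln else ln.split()
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected two columns")
        scale[fields[0].upper()] = float(fields[1])
    missing = set(EISENBERG_SCALE) - set(scale)
    if missing:
        raise ValueError(f"scale file missing residues: {sorted(missing)}")
    return scale


def eisenberg_score(sequence: str,
                    scale: Mapping[str, float] = EISENBERG_SCALE) -> float:
    """Summed hydrophobicity (kcal/mol) of a one-letter-code sequence.

    The empty sequence scores 0.  Unknown letters raise, naming the
    position.
    """
    total = 0.0
    for pos, letter in enumerate(sequence.upper()):
        try:
            total += scale[letter]
        except KeyError:
            raise ValueError(
                f"unknown residue code {letter!r} at position {pos} "
                f"of {sequence!r}") from None
    return total


@dataclass
class SheetScore:
    """Per-strand hydrophobicity scores of a beta-sheet face plus total."""

    strands: list[tuple[str, str, float]]  # (label, sequence, score)
    total: float


def sheet_score(strands: Sequence[tuple[str, str]],
                scale: Mapping[str, float] = EISENBERG_SCALE) -> SheetScore:
    """Score the pore-facing residues of each strand and the full sheet."""
    scored = [(label, seq, eisenberg_score(seq, scale)) for label, seq in strands]
    return SheetScore(strands=scored, total=sum(s for _, _, s in scored))


def hydrophilicity_excess(score_a: float, score_b: float) -> float:
    """How much more hydrophilic sheet A is than sheet B, in percent.

    For two hydrophilic (negative) scores this is
    ``100 * (|A|/|B| - 1)``: a sheet twice as negative is 100% more
    hydrophilic.  If either score is non-negative the "more hydrophilic"
    phrasing does not apply; the raw signed ratio is returned and a
    warning logged.
    """
    if score_b == 0:
        raise ZeroDivisionError("reference score is zero")
    if score_a < 0 and score_b < 0:
        return 100.0 * (abs(score_a) / abs(score_b) - 1.0)
    logger.warning("scores not both negative (%.3g, %.3g); returning raw "
                   "signed ratio", score_a, score_b)
    return 100.0 * (score_a / score_b - 1.0)


#: Pore-facing residues of the membrane-inserted beta-sheet, per strand:
#: human GSDMD N-terminal domain vs mouse GSDMA3 N-terminal domain.
GSDMD_PORE_FACING_STRANDS: list[tuple[str, str]] = [
    ("beta3", "ADQQSE"), ("beta5", "KAGASS"),
    ("beta7", "TKESRS"), ("beta8", "QEQHSK"),
]
GSDMA3_PORE_FACING_STRANDS: list[tuple[str, str]] = [
    ("beta3", "MDQQLE"), ("beta5", "TKKTGS"),
    ("beta7", "TNNISP"), ("beta8", "LGQSNN"),
]
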