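"""Protein charge properties used to interpret non-specific electrostatic binding.

Negatively charged DNA aptamers tend to stick electrostatically to proteins
that carry a positive net charge at the assay pH.  High-pI proteins such as
interferon gamma or thrombin are therefore prone to non-specific aptamer
binding in neutral buffers, and even low-pI proteins become sticky once the
buffer pH drops below their isoelectric point.  This module computes the
quantities needed for that interpretation: the net charge of a protein as a
function of pH (Henderson-Hasselbalch summation over ionizable groups), the
isoelectric point (the unique pH of zero net charge), and the molecular
weight.

The pKa values are the Bjellqvist set, bundled as a versioned data file so the
numbers are reproducible; an alternative table can be passed explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml
from Bio.SeqUtils import molecular_weight

__all__ = [
    "ProteinRecord",
    "InvalidResidueError",
    "load_pka_table",
    "net_charge",
    "isoelectric_point",
    "read_fasta_records",
]

#: the 20 standard one-letter amino-acid codes
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: side chains that carry a positive charge when protonated
POSITIVE_RESIDUES = ("K", "R", "H")
#: side chains that carry a negative charge when deprotonated
NEGATIVE_RESIDUES = ("D", "E", "C", "Y")


class InvalidResidueError(ValueError):
    """A sequence contains a character outside the 20 standard residues."""

    def __init__(self, residue: str, position: int):
        self.residue = residue
        self.position = position
        super().__init__(
            f"invalid residue {residue!r} at position {position} "
            "(0-based); only the 20 standard one-letter codes are accepted"
        )


def _validate_sequence(sequence: str) -> str:
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("sequence must be non-empty")
    for i, aa in enumerate(seq):
        if aa not in STANDARD_RESIDUES:
            raise InvalidResidueError(aa, i)
    return seq


def load_pka_table(path: str | Path | None = None) -> dict[str, float]:
    """Load an ionizable-group pKa table.

    The default is the bundled Bjellqvist set.  The table maps group names
    (``Nterm``, ``Cterm`` and the one-letter codes of the seven ionizable
    side chains D, E, C, Y, H, K, R) to pKa values.
    """
    if path is None:
        ref = resources.files("beadscreen").joinpath("data/pka_bjellqvist.yaml")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    table = yaml.safe_load(text)
    required = {"Nterm", "Cterm", *POSITIVE_RESIDUES[:-1], *NEGATIVE_RESIDUES, "H"}
    missing = required - set(table)
    if missing:
        raise ValueError(f"pKa table missing groups: {sorted(missing)}")
    return {k: float(v) for k, v in table.items()}


_DEFAULT_PKA: dict[str, float] | None = None


def _default_pka() -> dict[str, float]:
    global _DEFAULT_PKA
    if _DEFAULT_PKA is None:
        _DEFAULT_PKA = load_pka_table()
    return _DEFAULT_PKA


def net_charge(
    sequence: str,
    pH: float,
    pka: Mapping[str, float] | None = None,
) -> float:
    """Net charge of a protein at a given pH, in elementary charges.

    Henderson-Hasselbalch summation over the N-terminus, the C-terminus and
    the ionizable side chains.  A positively ionizable group (N-terminus, K,
    R, H) contributes ``+1 / (1 + 10**(pH - pKa))``; a negatively ionizable
    group (C-terminus, D, E, C, Y) contributes ``-1 / (1 + 10**(pKa - pH))``.

    Parameters
    ----------
    sequence
        One-letter amino-acid sequence (20 standard residues only).
    pH
        pH in [0, 14].
    pka
        Optional pKa table overriding the bundled Bjellqvist set.
    """
    seq = _validate_sequence(sequence)
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH must be in [0, 14], got {pH}")
    table = dict(pka) if pka is not None else _default_pka()

    def pos(pka_value: float, count: int = 1) -> float:
        return count / (1.0 + 10.0 ** (pH - pka_value))

    def neg(pka_value: float, count: int = 1) -> float:
        return -count / (1.0 + 10.0 ** (pka_value - pH))

    charge = pos(table["Nterm"]) + neg(table["Cterm"])
    for aa in ("K", "R", "H"):
        charge += pos(table[aa], seq.count(aa))
    for aa in ("D", "E", "C", "Y"):
        charge += neg(table[aa], seq.count(aa))
    return charge


def isoelectric_point(
    sequence: str,
    pka: Mapping[str, float] | None = None,
    tol: float = 1e-4,
) -> float:
    """Isoelectric point: the pH at which the net charge is zero.

    ``net_charge`` is strictly decreasing in pH for any sequence (every
    ionizable group's contribution is non-increasing and the termini are
    always present), so the root in [0, 14] is unique; it is found by
    bisection until ``|charge| < tol``.
    """
    seq = _validate_sequence(sequence)
    lo, hi = 0.0, 14.0
    charge_lo = net_charge(seq, lo, pka)
    charge_hi = net_charge(seq, hi, pka)
    if charge_lo < 0:
        return lo
    if charge_hi > 0:
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        c = net_charge(seq, mid, pka)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class ProteinRecord:
    """A named protein with its computed charge characteristics.

    ``molecular_weight`` is the average isotopic mass in daltons of the
    unmodified chain; ``pI`` is the isoelectric point in pH units.
    """

    name: str
    sequence: str
    molecular_weight: float = field(init=False)
    pI: float = field(init=False)

    def __post_init__(self) -> None:
        seq = _validate_sequence(self.sequence)
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(
            self, "molecular_weight", molecular_weight(seq, seq_type="protein")
        )
        object.__setattr__(self, "pI", isoelectric_point(seq))

    def net_charge(self, pH: float) -> float:
        return net_charge(self.sequence, pH)


def read_fasta_records(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(name=rec.id, sequence=str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records
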