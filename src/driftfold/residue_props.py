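"""Amino-acid property tables and pH-dependent sequence annotation.

The folding model consumes exactly two per-residue observables: a
hydrophobicity value ``h`` (a hydropathy-scale number, positive =
hydrophobic) and a fractional side-chain charge ``q`` in elementary-charge
units.  Charges are pH dependent and come from a Henderson--Hasselbalch
titration of the side-chain pKa:

    acid:  q(pH) = -1 / (1 + 10**(pKa - pH))
    base:  q(pH) = +1 / (1 + 10**(pH - pKa))

so an acid approaches -1 well above its pKa, a base approaches +1 well
below its pKa, and every titratable residue carries exactly +/-0.5 at its
pKa.  Non-ionizable side chains are neutral at every pH.  N-/C-terminal
charges are ignored.

The property table ships as a versioned JSON data file; the default
hydrophobicity values are the Kyte--Doolittle hydropathy scale.
Alternative scales can be loaded from any file with the same layout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ResidueProperties",
    "ResidueTable",
    "AnnotatedSequence",
    "load_residue_table",
    "charge_at_pH",
    "classify_hydropathy",
    "annotate_sequence",
    "HYDROPHOBIC",
    "HYDROPHILIC",
]

HYDROPHOBIC = "hydrophobic"
HYDROPHILIC = "hydrophilic"

#: Default binary hydropathy threshold on the bundled scale: residues with
#: h strictly above it are hydrophobic; the boundary value is hydrophilic.
DEFAULT_HYDROPATHY_THRESHOLD = 0.0


class UnknownResidueError(ValueError):
    """A sequence letter outside the canonical 20-residue alphabet."""


@dataclass(frozen=True)
class ResidueProperties:
    """Static properties of one canonical amino acid.

    ``charge_sign`` is +1 for bases (K, R, H), -1 for acids (D, E, C, Y)
    and 0 for non-ionizable side chains; ``pka_side`` is ``None`` exactly
    when ``charge_sign`` is 0.
    """

    code: str
    name: str
    h: float
    pka_side: float | None
    charge_sign: int

    def charge_at_pH(self, pH: float) -> float:
        """Fractional side-chain charge (e) at the given pH."""
        if not 0.0 < pH < 14.0:
            raise ValueError(f"pH must lie in (0, 14), got {pH!r}")
        if self.charge_sign == 0:
            return 0.0
        assert self.pka_side is not None
        if self.charge_sign < 0:  # acid: deprotonates to -1 above pKa
            return -1.0 / (1.0 + 10.0 ** (self.pka_side - pH))
        # base: protonates to +1 below pKa
        return 1.0 / (1.0 + 10.0 ** (pH - self.pka_side))


@dataclass(frozen=True)
class ResidueTable:
    """The 20-entry canonical property table plus the scale it came from."""

    scale: str
    residues: Mapping[str, ResidueProperties]

    def __post_init__(self) -> None:
        if len(self.residues) != 20:
            raise ValueError(
                f"expected 20 canonical residues, got {len(self.residues)}"
            )

    def __getitem__(self, code: str) -> ResidueProperties:
        try:
            return self.residues[code]
        except KeyError:
            raise UnknownResidueError(
                f"unknown residue code {code!r} (canonical 20-letter alphabet)"
            ) from None

    def __contains__(self, code: str) -> bool:
        return code in self.residues


def load_residue_table(path: str | None = None) -> ResidueTable:
    """Load the bundled property table, or one with the same JSON layout."""
    if path is None:
        raw = (
            resources.files("driftfold.data")
            .joinpath("residue_table.json")
            .read_text()
        )
    else:
        with open(path) as fh:
            raw = fh.read()
    doc = json.loads(raw)
    residues = {
        code: ResidueProperties(
            code=code,
            name=entry.get("name", code),
            h=float(entry["h"]),
            pka_side=None if entry["pka_side"] is None else float(entry["pka_side"]),
            charge_sign=int(entry["charge_sign"]),
        )
        for code, entry in doc["residues"].items()
    }
    return ResidueTable(scale=doc.get("scale", "unnamed"), residues=residues)


_DEFAULT_TABLE: ResidueTable | None = None


def default_table() -> ResidueTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_residue_table()
    return _DEFAULT_TABLE


def charge_at_pH(code: str, pH: float, table: ResidueTable | None = None) -> float:
    """Henderson--Hasselbalch fractional side-chain charge (e) at ``pH``."""
    table = table or default_table()
    return table[code].charge_at_pH(pH)


def classify_hydropathy(
    h: float, threshold: float = DEFAULT_HYDROPATHY_THRESHOLD
) -> str:
    """Binary hydropathy class: strictly above threshold -> hydrophobic."""
    if not math.isfinite(h):
        raise ValueError(f"hydrophobicity must be finite, got {h!r}")
    return HYDROPHOBIC if h > threshold else HYDROPHILIC


@dataclass(frozen=True)
class AnnotatedSequence:
    """A sequence with per-residue charge, hydrophobicity and hydropathy.

    This is the sole input to both the secondary-structure rules and the
    force field: residue identity only matters through (q, h).
    """

    residues: tuple[str, ...]
    q: tuple[float, ...]
    h: tuple[float, ...]
    hydropathy: tuple[str, ...]
    pH: float

    def __post_init__(self) -> None:
        n = len(self.residues)
        if not (len(self.q) == len(self.h) == len(self.hydropathy) == n):
            raise ValueError("annotation arrays must all match sequence length")
        for qi in self.q:
            if not -1.0 <= qi <= 1.0:
                raise ValueError(f"residue charge {qi} outside [-1, +1] e")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(self.residues)

    def is_hydrophilic(self, i: int) -> bool:
        return self.hydropathy[i] == HYDROPHILIC

    def net_charge(self) -> float:
        return sum(self.q)


def annotate_sequence(
    residues: Sequence[str] | str,
    pH: float = 7.0,
    table: ResidueTable | None = None,
    threshold: float = DEFAULT_HYDROPATHY_THRESHOLD,
) -> AnnotatedSequence:
    """Annotate a canonical sequence with (q, h, hydropathy) at ``pH``.

    Raises :class:`UnknownResidueError` on any non-canonical letter; empty
    sequences are rejected rather than silently annotated.
    """
    table = table or default_table()
    codes = tuple(residues)
    if not codes:
        raise ValueError("cannot annotate an empty sequence")
    q, h, cls = [], [], []
    for code in codes:
        props = table[code]
        q.append(props.charge_at_pH(pH))
        h.append(props.h)
        cls.append(classify_hydropathy(props.h, threshold))
    return AnnotatedSequence(
        residues=codes, q=tuple(q), h=tuple(h), hydropathy=tuple(cls), pH=pH
    )
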