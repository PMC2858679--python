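"""Shared domain types.

The vocabulary of the package: a protein chain is reduced to an ordered
list of residues with 3-state secondary structure (H/E/C); maximal helix
or strand runs become secondary-structure elements (SSElement); every
pair of consecutive elements plus the connecting loop is a supersecondary
motif (Smotif), characterised by four internal coordinates:

* ``D``     — distance (Å) between the C-terminal Cα of SS1 and the
              N-terminal Cα of SS2,
* ``delta`` — hoist: angle (deg) between the connecting vector L and the
              principal axis M1 of SS1,
* ``theta`` — packing: angle (deg) between the two element axes M1, M2,
* ``rho``   — meridian: azimuth (deg, 0-360) of M2 about M1 measured
              from the plane spanned by M1 and the normal of plane(M1, L).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "ChainModel",
    "SSElement",
    "SmotifGeometry",
    "Smotif",
]


@dataclass
class AtomRecord:
    """A single atom: name (e.g. ``CA``), element symbol and position in Å."""

    name: str
    element: str
    coord: np.ndarray  # shape (3,)

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")


@dataclass
class ResidueRecord:
    """One residue: author numbering (with insertion code), atoms and H/E/C state."""

    chain_id: str
    seq_pos: str  # author residue number + insertion code, e.g. "42" or "42A"
    aa: str
    atoms: list[AtomRecord] = field(default_factory=list)
    ss3: str = "C"

    def get_atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> np.ndarray | None:
        a = self.get_atom("CA")
        return None if a is None else a.coord

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.element.upper() not in ("H", "D")]


@dataclass
class ChainModel:
    """An ordered single protein chain, the substrate of every analysis."""

    structure_id: str
    residues: list[ResidueRecord]
    deposition_date: _dt.date | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.residues:
            if r.seq_pos in seen:
                raise ValueError(
                    f"{self.structure_id}: duplicate residue id {r.seq_pos!r}"
                )
            seen.add(r.seq_pos)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ss3_string(self) -> str:
        return "".join(r.ss3 for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(n, 3) Cα array; rows of NaN where a residue lacks a Cα."""
        out = np.full((len(self.residues), 3), np.nan)
        for i, r in enumerate(self.residues):
            ca = r.ca
            if ca is not None:
                out[i] = ca
        return out


@dataclass
class SSElement:
    """A maximal helix (H) or strand (E) run.

    ``start``/``end`` are inclusive indices into the parent chain's residue
    list; ``resid_start``/``resid_end`` carry the author numbering for
    reporting.  ``ca_coords`` holds one Cα per residue, N- to C-terminal.
    """

    kind: str  # "H" or "E"
    start: int
    end: int
    ca_coords: np.ndarray | None = None
    resid_start: str = ""
    resid_end: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("H", "E"):
            raise ValueError(f"element kind must be H or E, got {self.kind!r}")
        if self.end < self.start:
            raise ValueError("element end precedes start")
        if self.ca_coords is not None:
            self.ca_coords = np.asarray(self.ca_coords, dtype=float)
            if self.ca_coords.shape != (self.length, 3):
                raise ValueError("ca_coords count must equal element length")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SmotifGeometry:
    """The four internal coordinates of a Smotif (see module docstring)."""

    D: float
    delta: float
    theta: float
    rho: float
    degenerate: bool = False  # connecting vector (anti)parallel to M1: rho ill-defined

    def __post_init__(self) -> None:
        vals = (self.D, self.delta, self.theta, self.rho)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("geometry values must be finite")
        if self.D < 0:
            raise ValueError("D must be non-negative")
        if not (0.0 <= self.delta <= 180.0 and 0.0 <= self.theta <= 180.0):
            raise ValueError("delta/theta must lie in [0, 180]")
        if not (0.0 <= self.rho < 360.0):
            raise ValueError("rho must lie in [0, 360)")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.D, self.delta, self.theta, self.rho)


@dataclass
class Smotif:
    """Two consecutive SS elements bridged by a loop."""

    ss1: SSElement
    ss2: SSElement
    source: str = ""
    chain_id: str = ""
    geometry: SmotifGeometry | None = None
    date: _dt.date | None = None

    def __post_init__(self) -> None:
        if self.ss2.start <= self.ss1.end:
            raise ValueError("ss2 must follow ss1 in sequence")

    @property
    def cls(self) -> str:
        """Bracing-type class: HH, HE, EH or EE (SS1 kind first)."""
        return self.ss1.kind + self.ss2.kind

    @property
    def loop_len(self) -> int:
        return self.ss2.start - self.ss1.end - 1

    @property
    def size(self) -> int:
        """Residues in the bracing elements (loop excluded)."""
        return self.ss1.length + self.ss2.length
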