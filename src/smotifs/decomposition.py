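"""Decompose an annotated chain into its string of overlapping Smotifs.

A chain with k regular secondary-structure elements yields k − 1 Smotifs:
the SS2 of one Smotif is the SS1 of the next, so the whole structure is a
string of overlapping motifs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ChainModel, Smotif, SSElement
from .geometry import compute_geometry

__all__ = [
    "DecompositionConfig",
    "extract_ss_elements",
    "decompose",
    "smotif_string",
    "chain_breaks",
    "CHAIN_BREAK_CA_DIST",
]

log = logging.getLogger(__name__)

#: consecutive Cα further apart than this (Å) mark a chain break
CHAIN_BREAK_CA_DIST = 4.5


@dataclass
class DecompositionConfig:
    """Knobs of the decomposition stage.

    min_helix / min_strand: shortest run kept as an element (shorter runs
    are demoted to coil and absorbed into the surrounding loop).  A helix
    needs >= 4 residues for a stable axis and DSSP helices are >= 4 by
    construction; 3 Cα is the minimum for an inertia axis of a strand.
    max_loop: optional cap on loop length; Smotifs with longer loops are
    dropped (off by default — decomposition itself imposes no cap).
    """

    min_helix: int = 4
    min_strand: int = 3
    max_loop: int | None = None


def chain_breaks(chain: ChainModel) -> set[int]:
    """Indices i such that the polymer is broken between residues i and i+1.

    A break is a missing Cα on either side or a Cα-Cα distance above
    ``CHAIN_BREAK_CA_DIST``.
    """
    cas = chain.ca_coords()
    breaks: set[int] = set()
    for i in range(len(chain) - 1):
        a, b = cas[i], cas[i + 1]
        if np.any(np.isnan(a)) or np.any(np.isnan(b)):
            breaks.add(i)
        elif np.linalg.norm(b - a) > CHAIN_BREAK_CA_DIST:
            breaks.add(i)
    return breaks


def _runs(ss3: str) -> list[tuple[str, int, int]]:
    """Maximal runs of identical ss3 state as (state, start, end) inclusive."""
    runs = []
    start = 0
    for i in range(1, len(ss3) + 1):
        if i == len(ss3) or ss3[i] != ss3[start]:
            runs.append((ss3[start], start, i - 1))
            start = i
    return runs


def extract_ss_elements(
    chain: ChainModel,
    min_helix: int = 4,
    min_strand: int = 3,
) -> list[SSElement]:
    """Maximal H/E runs of the chain that meet the minimum element length.

    Runs are split at chain breaks before the length filter, so an
    element never spans a physical gap.  Sub-minimal runs are demoted to
    coil (they become part of the loop between their neighbours).
    """
    minima = {"H": min_helix, "E": min_strand}
    breaks = chain_breaks(chain)
    cas = chain.ca_coords()
    elements: list[SSElement] = []
    for state, start, end in _runs(chain.ss3_string):
        if state not in ("H", "E"):
            continue
        # split the run at chain breaks
        pieces = []
        s = start
        for i in range(start, end):
            if i in breaks:
                pieces.append((s, i))
                s = i + 1
        pieces.append((s, end))
        for s, e in pieces:
            if e - s + 1 < minima[state]:
                continue
            coords = cas[s : e + 1]
            if np.any(np.isnan(coords)):
                log.warning(
                    "%s: element %d-%d lacks Cα atoms, skipped",
                    chain.structure_id, s, e,
                )
                continue
            elements.append(
                SSElement(
                    kind=state,
                    start=s,
                    end=e,
                    ca_coords=coords,
                    resid_start=chain.residues[s].seq_pos,
                    resid_end=chain.residues[e].seq_pos,
                )
            )
    return elements


def decompose(
    elements: list[SSElement],
    chain: ChainModel,
    max_loop: int | None = None,
) -> list[Smotif]:
    """Pair consecutive elements into Smotifs.

    k elements give max(0, k − 1) Smotifs; Smotif i shares its SS2 with
    Smotif i + 1's SS1.  Smotifs whose loop crosses a chain break (or
    exceeds ``max_loop``, when set) are dropped and logged.
    """
    breaks = chain_breaks(chain)
    chain_part = chain.structure_id.split("_")[-1] if "_" in chain.structure_id else ""
    out: list[Smotif] = []
    for ss1, ss2 in zip(elements, elements[1:]):
        if any(i in breaks for i in range(ss1.end, ss2.start)):
            log.info(
                "%s: Smotif %s-%s crosses a chain break, dropped",
                chain.structure_id, ss1.resid_end, ss2.resid_start,
            )
            continue
        m = Smotif(
            ss1=ss1,
            ss2=ss2,
            source=chain.structure_id,
            chain_id=chain_part,
            date=chain.deposition_date,
        )
        if max_loop is not None and m.loop_len > max_loop:
            log.info(
                "%s: Smotif %s-%s loop length %d exceeds cap %d, dropped",
                chain.structure_id, ss1.resid_end, ss2.resid_start,
                m.loop_len, max_loop,
            )
            continue
        out.append(m)
    return out


def smotif_string(
    chain: ChainModel,
    config: DecompositionConfig | None = None,
) -> list[Smotif]:
    """Full pipeline: extract elements, pair them, fill in the geometry."""
    cfg = config or DecompositionConfig()
    elements = extract_ss_elements(chain, cfg.min_helix, cfg.min_strand)
    motifs = decompose(elements, chain, max_loop=cfg.max_loop)
    for m in motifs:
        m.geometry = compute_geometry(m.ss1, m.ss2)
    return motifs
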