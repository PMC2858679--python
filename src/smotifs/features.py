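"""Per-Smotif structural features: contacts, size, and solvent exposure.

Non-bonded contacts are counted with a symmetric heavy-atom distance
criterion (default cutoff 4.5 Å) between the two bracing elements, loop
atoms excluded.  No contact typing is attempted; the count enters the
analysis only as a scalar.

Solvent exposure is Shrake-Rupley accessible surface area (probe 1.4 Å,
element-keyed van der Waals radii, 1000 Fibonacci sphere points per atom)
computed
in the context of the whole chain and averaged per Smotif residue, with
or without the loop.  When a DSSP file is available its per-residue ACC
column can be used verbatim instead (see ``structure_io.read_dssp_acc``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import ChainModel, Smotif

__all__ = [
    "SmotifFeatures",
    "internal_contacts",
    "ic_ratio",
    "solvent_exposure",
    "chain_sasa_per_residue",
    "smotif_features",
    "DEFAULT_CONTACT_CUTOFF",
]

log = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 4.5  # Å, heavy-atom pair distance


@dataclass
class SmotifFeatures:
    n_contacts: int
    ic_ratio: float
    size: int
    loop_len: int
    mean_acc: float | None = None
    mean_acc_no_loop: float | None = None


def _element_heavy_coords(smotif: Smotif, chain: ChainModel, which: str) -> np.ndarray:
    elem = smotif.ss1 if which == "ss1" else smotif.ss2
    coords = [
        a.coord
        for i in range(elem.start, elem.end + 1)
        for a in chain.residues[i].heavy_atoms()
    ]
    return np.array(coords) if coords else np.empty((0, 3))


def internal_contacts(
    smotif: Smotif, chain: ChainModel, cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> int:
    """Heavy-atom pairs (one in SS1, one in SS2) within ``cutoff`` Å.

    Loop atoms never participate.  When the loop has zero length the pair
    of sequence-adjacent junction residues is excluded, so covalent
    neighbours are not reported as contacts.
    """
    ss1_range = range(smotif.ss1.start, smotif.ss1.end + 1)
    ss2_range = range(smotif.ss2.start, smotif.ss2.end + 1)
    exclude_pair = None
    if smotif.loop_len == 0:
        exclude_pair = (smotif.ss1.end, smotif.ss2.start)

    coords1, owner1 = [], []
    for i in ss1_range:
        for a in chain.residues[i].heavy_atoms():
            coords1.append(a.coord)
            owner1.append(i)
    coords2, owner2 = [], []
    for j in ss2_range:
        for a in chain.residues[j].heavy_atoms():
            coords2.append(a.coord)
            owner2.append(j)
    if not coords1 or not coords2:
        return 0
    tree = cKDTree(np.array(coords2))
    neighbours = tree.query_ball_point(np.array(coords1), r=cutoff)
    count = 0
    for idx1, hits in enumerate(neighbours):
        for idx2 in hits:
            if exclude_pair and (owner1[idx1], owner2[idx2]) == exclude_pair:
                continue
            count += 1
    return count


def ic_ratio(
    smotif: Smotif,
    chain: ChainModel,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    size_mode: str = "braces",
) -> float:
    """Internal contacts per residue.

    ``size_mode="braces"`` divides by the bracing-element residue count
    (the default); ``"total"`` also counts loop residues.
    """
    size = smotif.size if size_mode == "braces" else smotif.size + smotif.loop_len
    return internal_contacts(smotif, chain, cutoff) / size


def chain_sasa_per_residue(
    chain: ChainModel,
    probe_radius: float = 1.4,
    point_number: int = 1000,
) -> np.ndarray:
    """Shrake-Rupley accessible surface (Å²) per residue, whole chain.

    Residues without heavy atoms get NaN and are logged.
    """
    import biotite.structure as struc

    atoms = []
    for i, r in enumerate(chain.residues):
        for a in r.heavy_atoms():
            atoms.append((i, r, a))
    if not atoms:
        raise ValueError("chain has no heavy atoms")
    arr = struc.AtomArray(len(atoms))
    arr.coord = np.array([a.coord for _, _, a in atoms])
    arr.chain_id = np.array([r.chain_id or "A" for _, r, _ in atoms])
    arr.res_id = np.array([i + 1 for i, _, _ in atoms])
    arr.res_name = np.array(["UNK" for _ in atoms])
    arr.atom_name = np.array([a.name for _, _, a in atoms])
    arr.element = np.array([a.element.upper() for _, _, a in atoms])
    arr.hetero = np.zeros(len(atoms), dtype=bool)
    per_atom = struc.sasa(
        arr, probe_radius=probe_radius, point_number=point_number,
        vdw_radii="Single", ignore_ions=False,
    )
    out = np.full(len(chain.residues), np.nan)
    owners = np.array([i for i, _, _ in atoms])
    for i in range(len(chain.residues)):
        mask = owners == i
        if mask.any():
            out[i] = np.nansum(per_atom[mask])
        else:
            log.warning(
                "%s: residue %s has no heavy atoms, SASA skipped",
                chain.structure_id, chain.residues[i].seq_pos,
            )
    return out


def solvent_exposure(
    smotif: Smotif,
    chain: ChainModel,
    include_loop: bool = True,
    per_residue_acc: np.ndarray | None = None,
) -> float:
    """Mean accessible surface (Å² per residue) over the Smotif's span.

    ``per_residue_acc`` may carry precomputed values (e.g. the ACC column
    of a DSSP file, or a cached ``chain_sasa_per_residue`` result);
    otherwise SASA is computed from the chain coordinates.
    """
    if per_residue_acc is None:
        per_residue_acc = chain_sasa_per_residue(chain)
    idx = list(range(smotif.ss1.start, smotif.ss1.end + 1))
    if include_loop:
        idx += list(range(smotif.ss1.end + 1, smotif.ss2.start))
    idx += list(range(smotif.ss2.start, smotif.ss2.end + 1))
    vals = np.asarray(per_residue_acc, dtype=float)[idx]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no residues with accessible-surface values")
    return float(vals.mean())


def smotif_features(
    smotif: Smotif,
    chain: ChainModel,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    size_mode: str = "braces",
    with_sasa: bool = False,
    per_residue_acc: np.ndarray | None = None,
) -> SmotifFeatures:
    """Bundle of all per-Smotif features."""
    n = internal_contacts(smotif, chain, cutoff)
    size = smotif.size if size_mode == "braces" else smotif.size + smotif.loop_len
    acc = acc_nl = None
    if with_sasa or per_residue_acc is not None:
        if per_residue_acc is None:
            per_residue_acc = chain_sasa_per_residue(chain)
        acc = solvent_exposure(smotif, chain, True, per_residue_acc)
        acc_nl = solvent_exposure(smotif, chain, False, per_residue_acc)
    return SmotifFeatures(
        n_contacts=n,
        ic_ratio=n / size,
        size=smotif.size,
        loop_len=smotif.loop_len,
        mean_acc=acc,
        mean_acc_no_loop=acc_nl,
    )
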