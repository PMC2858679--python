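"""Reading structures and annotations; writing tabular output.

PDB content is parsed with gemmi into the package's uniform
:class:`~smotifs.core.ChainModel`; classic DSSP output is parsed with
Biopython's DSSP-file reader and reduced to three states
(H, G, I -> H; E -> E; everything else -> C).  Smotif tables are TSV
with a fixed column set and commented (#) metadata header lines.
"""

from __future__ import annotations

import datetime as _dt
import io
import tempfile
from typing import Iterable, Mapping, Sequence

import numpy as np

from .classification import BinId, BinningScheme, bin_smotif, default_scheme
from .core import AtomRecord, ChainModel, ResidueRecord, Smotif, SmotifGeometry, SSElement

__all__ = [
    "read_pdb",
    "read_dssp",
    "read_dssp_acc",
    "reduce_dssp_state",
    "annotate_ss",
    "assign_ss_psea",
    "fetch_pdb",
    "write_smotif_table",
    "read_smotif_table",
    "chain_to_pdb",
    "write_ss3_sidecar",
    "read_ss3_sidecar",
    "read_two_column_table",
    "SMOTIF_TABLE_COLUMNS",
]

#: DSSP 8-state -> 3-state reduction.  B (isolated bridge) goes to coil:
#: a single bridge residue lacks the extended geometry a strand axis needs.
DSSP_3STATE = {
    "H": "H", "G": "H", "I": "H",
    "E": "E",
    "B": "C", "T": "C", "S": "C", "P": "C", " ": "C", "-": "C",
}

SMOTIF_TABLE_COLUMNS = [
    "structure_id", "chain", "class",
    "ss1_start", "ss1_end", "ss1_len", "loop_len",
    "ss2_start", "ss2_end", "ss2_len",
    "D", "delta", "theta", "rho", "bin_id", "frequency",
]

_STANDARD_AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M", "SEC": "U", "PYL": "O",
}


def read_pdb(
    text: str,
    chain: str | None = None,
    model: int = 0,
    structure_id: str | None = None,
) -> ChainModel:
    """Parse one chain of a PDB-format string into a ChainModel.

    Alternate locations collapse to the highest-occupancy conformer;
    HETATM records are kept only for (modified) amino acids; ss3 starts
    as all-coil.  ``chain=None`` takes the first chain of the model.
    """
    import gemmi

    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise ValueError("no models in PDB content")
    if model >= len(st):
        raise ValueError(f"model {model} not present ({len(st)} model(s))")
    mdl = st[model]
    if chain is None:
        if len(mdl) == 0:
            raise ValueError("model has no chains")
        ch = mdl[0]
        chain = ch.name
    else:
        ch = mdl.find_chain(chain)
        if ch is None:
            raise ValueError(f"chain not found: {chain!r}")

    residues: list[ResidueRecord] = []
    seen_pos: set[str] = set()
    for res in ch:
        info = gemmi.find_tabulated_residue(res.name)
        is_aa = info is not None and info.is_amino_acid()
        if res.het_flag == "H" and not is_aa:
            continue
        if not is_aa and res.name not in _STANDARD_AA3:
            continue
        seq_pos = f"{res.seqid.num}{res.seqid.icode.strip()}"
        if seq_pos in seen_pos:
            continue  # altloc-duplicated residue entries
        # collapse altlocs: highest occupancy per atom name
        best: dict[str, object] = {}
        for atom in res:
            prev = best.get(atom.name)
            if prev is None or atom.occ > prev.occ:
                best[atom.name] = atom
        atoms = [
            AtomRecord(
                name=a.name,
                element=a.element.name,
                coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
            )
            for a in best.values()
        ]
        if not atoms:
            continue
        seen_pos.add(seq_pos)
        residues.append(
            ResidueRecord(
                chain_id=chain,
                seq_pos=seq_pos,
                aa=_STANDARD_AA3.get(res.name, "X"),
                atoms=atoms,
                ss3="C",
            )
        )
    if not any(r.ca is not None for r in residues):
        raise ValueError(f"chain {chain!r} is not a polypeptide chain (no CA atoms)")

    date = None
    key = "_pdbx_database_status.recvd_initial_deposition_date"
    raw = st.info[key] if key in st.info else None
    if raw:
        try:
            date = _dt.date.fromisoformat(raw)
        except ValueError:
            date = None
    sid = structure_id or (st.name.lower() or "struct") + f"_{chain}"
    return ChainModel(structure_id=sid, residues=residues, deposition_date=date)


def reduce_dssp_state(code: str) -> str:
    """Map one 8-state DSSP code to H/E/C."""
    return DSSP_3STATE.get(code.upper() if code.strip() else " ", "C")


def _parse_dssp(text: str):
    from Bio.PDB.DSSP import make_dssp_dict

    header_idx = next(
        (i for i, line in enumerate(text.splitlines())
         if line.lstrip().startswith("#  RESIDUE")),
        None,
    )
    if header_idx is None:
        raise ValueError(
            "malformed DSSP content: no '#  RESIDUE' table header line found"
        )
    with tempfile.NamedTemporaryFile("w", suffix=".dssp", delete=False) as fh:
        fh.write(text)
        path = fh.name
    try:
        dssp_dict, _ = make_dssp_dict(path)
    finally:
        import os

        os.unlink(path)
    return dssp_dict


def read_dssp(text: str) -> dict[tuple[str, str], str]:
    """(chain, seq_pos) -> 3-state code from classic DSSP output."""
    out: dict[tuple[str, str], str] = {}
    for (chain_id, res_id), values in _parse_dssp(text).items():
        _, num, icode = res_id
        seq_pos = f"{num}{icode.strip()}"
        out[(chain_id, seq_pos)] = reduce_dssp_state(values[1])
    return out


def read_dssp_acc(text: str) -> dict[tuple[str, str], float]:
    """(chain, seq_pos) -> ACC (Å² accessible surface) from DSSP output."""
    out: dict[tuple[str, str], float] = {}
    for (chain_id, res_id), values in _parse_dssp(text).items():
        _, num, icode = res_id
        out[(chain_id, f"{num}{icode.strip()}")] = float(values[2])
    return out


def annotate_ss(
    chain: ChainModel,
    ann: Mapping,
) -> ChainModel:
    """Overwrite ss3 where the mapping has entries; the rest keep theirs.

    Keys may be (chain_id, seq_pos) pairs or bare seq_pos strings.
    Returns a new ChainModel; the input is untouched.
    """
    import copy

    out = copy.deepcopy(chain)
    for r in out.residues:
        for key in ((r.chain_id, r.seq_pos), r.seq_pos):
            if key in ann:
                r.ss3 = ann[key]
                break
    return out


def write_smotif_table(
    smotifs: Sequence[Smotif],
    dest=None,
    scheme: BinningScheme | None = None,
    freqs: Mapping[BinId, float] | None = None,
    meta: Mapping[str, object] | None = None,
) -> str:
    """Serialise Smotifs as TSV (one row each, deterministic order).

    Rows sort by (structure, SS1 start).  ``meta`` entries become
    commented ``# key=value`` header lines.  Returns the TSV text and, if
    ``dest`` is a writable object, also writes it there.
    """
    scheme = scheme or default_scheme()
    buf = io.StringIO()
    for k, v in (meta or {}).items():
        buf.write(f"# {k}={v}\n")
    buf.write("\t".join(SMOTIF_TABLE_COLUMNS) + "\n")
    for m in sorted(smotifs, key=lambda m: (m.source, m.ss1.start)):
        g = m.geometry
        if g is None:
            raise ValueError("cannot serialise a Smotif without geometry")
        b = bin_smotif(m, scheme)
        freq = "" if freqs is None else f"{freqs.get(b, 0.0):.6g}"
        row = [
            m.source, m.chain_id, m.cls,
            m.ss1.resid_start or str(m.ss1.start), m.ss1.resid_end or str(m.ss1.end),
            str(m.ss1.length), str(m.loop_len),
            m.ss2.resid_start or str(m.ss2.start), m.ss2.resid_end or str(m.ss2.end),
            str(m.ss2.length),
            f"{g.D:.3f}", f"{g.delta:.3f}", f"{g.theta:.3f}", f"{g.rho:.3f}",
            str(b), freq,
        ]
        buf.write("\t".join(row) + "\n")
    text = buf.getvalue()
    if dest is not None:
        dest.write(text)
    return text


def read_smotif_table(text: str) -> list[Smotif]:
    """Parse a Smotif TSV back into (coordinate-free) Smotif records."""
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError("empty Smotif table")
    header = lines[0].split("\t")
    if header[: len(SMOTIF_TABLE_COLUMNS) - 1] != SMOTIF_TABLE_COLUMNS[:-1]:
        raise ValueError("unrecognised Smotif table header")
    out: list[Smotif] = []
    for ln in lines[1:]:
        f = dict(zip(header, ln.split("\t")))
        cls = f["class"]
        len1, len2 = int(f["ss1_len"]), int(f["ss2_len"])
        loop = int(f["loop_len"])
        ss1 = SSElement(
            kind=cls[0], start=0, end=len1 - 1,
            resid_start=f["ss1_start"], resid_end=f["ss1_end"],
        )
        ss2 = SSElement(
            kind=cls[1], start=len1 + loop, end=len1 + loop + len2 - 1,
            resid_start=f["ss2_start"], resid_end=f["ss2_end"],
        )
        out.append(
            Smotif(
                ss1=ss1, ss2=ss2, source=f["structure_id"], chain_id=f["chain"],
                geometry=SmotifGeometry(
                    D=float(f["D"]), delta=float(f["delta"]),
                    theta=float(f["theta"]), rho=float(f["rho"]),
                ),
            )
        )
    return out


def chain_to_pdb(chain: ChainModel) -> str:
    """Write a ChainModel as minimal PDB ATOM records (synthetic chains)."""
    lines = []
    serial = 1
    cid = (chain.residues[0].chain_id or "A")[:1] if chain.residues else "A"
    for i, r in enumerate(chain.residues, start=1):
        for a in r.atoms:
            x, y, z = a.coord
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name} ALA {cid}{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{a.element.upper():>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_ss3_sidecar(chain: ChainModel) -> str:
    """Ground-truth ss3 labels as a two-column sidecar (seq_pos, state)."""
    return "".join(f"{r.seq_pos}\t{r.ss3}\n" for r in chain.residues)


def read_ss3_sidecar(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        pos, state = ln.split("\t")
        out[pos] = state.strip()
    return out


def assign_ss_psea(chain: ChainModel) -> ChainModel:
    """3-state secondary structure from Cα coordinates via P-SEA.

    Uses biotite's P-SEA implementation (distance/angle criteria on the
    Cα trace).  This is the assignment path for real structures when no
    DSSP output is supplied; synthetic chains carry ground-truth labels
    and do not need it.  Residues without Cα stay coil.
    """
    import biotite.structure as struc

    idx = [i for i, r in enumerate(chain.residues) if r.ca is not None]
    n = len(idx)
    if n == 0:
        raise ValueError("no Cα atoms to assign secondary structure from")
    arr = struc.AtomArray(n)
    arr.coord = np.array([chain.residues[i].ca for i in idx])
    arr.chain_id = np.array([chain.residues[i].chain_id or "A" for i in idx])
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.array(["ALA"] * n)
    arr.atom_name = np.array(["CA"] * n)
    arr.element = np.array(["C"] * n)
    arr.hetero = np.zeros(n, dtype=bool)
    sse = struc.annotate_sse(arr)
    mapping = {"a": "H", "b": "E", "c": "C"}
    ann = {
        chain.residues[i].seq_pos: mapping.get(str(s), "C")
        for i, s in zip(idx, sse)
    }
    return annotate_ss(chain, ann)


#: set to the failure reason after a connectivity-level download failure,
#: so batch fetches do not retry a dead route for every entry
_DOWNLOADS_UNAVAILABLE: str | None = None


def fetch_pdb(pdb_id: str, cache_dir: str | None = None, timeout: float = 20.0) -> str:
    """PDB-format text for an entry, from a local cache or the RCSB.

    Looks for ``<cache_dir>/<id>.pdb`` first; otherwise downloads and
    (when a cache dir is given) stores it.  Raises ``RuntimeError`` when
    the entry is unavailable locally and the download fails.
    """
    import pathlib
    import urllib.error
    import urllib.request

    pdb_id = pdb_id.lower()
    if cache_dir:
        cached = pathlib.Path(cache_dir) / f"{pdb_id}.pdb"
        if cached.exists():
            return cached.read_text()
    global _DOWNLOADS_UNAVAILABLE
    if _DOWNLOADS_UNAVAILABLE:
        raise RuntimeError(
            f"PDB entry {pdb_id} not in local cache and a previous download "
            f"attempt already failed ({_DOWNLOADS_UNAVAILABLE})"
        )
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            text = resp.read().decode()
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        if isinstance(exc, urllib.error.URLError) and not isinstance(
            exc, urllib.error.HTTPError
        ):
            _DOWNLOADS_UNAVAILABLE = str(exc.reason)  # no route to the archive
        raise RuntimeError(
            f"PDB entry {pdb_id} not in local cache and download failed: {exc}"
        ) from exc
    if cache_dir:
        pathlib.Path(cache_dir).mkdir(parents=True, exist_ok=True)
        (pathlib.Path(cache_dir) / f"{pdb_id}.pdb").write_text(text)
    return text


def read_two_column_table(text: str) -> dict[str, str]:
    """Generic two-column TSV (e.g. structure -> fold, structure -> date)."""
    out: dict[str, str] = {}
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) < 2:
            raise ValueError(f"expected two tab-separated columns: {ln!r}")
        out[parts[0]] = parts[1].strip()
    return out
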