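import numpy as np
import pytest

from smotifs.synthetic import (
    PlacementTarget,
    build_synthetic_chain,
    random_placement_targets,
)


def chain_targets(targets: list[PlacementTarget]) -> list[PlacementTarget]:
    """Make consecutive targets chainable (SS2 of i becomes SS1 of i+1)."""
    for i in range(1, len(targets)):
        targets[i].kinds = (targets[i - 1].kinds[1], targets[i].kinds[1])
        targets[i].lengths = (targets[i - 1].lengths[1], targets[i].lengths[1])
    return targets


def make_synthetic_chain(n_smotifs: int, seed: int, structure_id: str = "syn_A"):
    rng = np.random.default_rng(seed)
    targets = chain_targets(random_placement_targets(n_smotifs, rng))
    return build_synthetic_chain(targets, structure_id=structure_id), targets


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture
def three_element_chain():
    """A synthetic chain of 3 SS elements (2 Smotifs) with ground-truth ss3."""
    chain, targets = make_synthetic_chain(2, seed=42)
    return chain, targets


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      -0.525   1.362   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       1.526   0.000   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       2.100   1.200   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       3.600   1.300   0.100  1.00  0.00           C
ATOM      6  C   GLY A   2       4.200   2.600   0.500  1.00  0.00           C
ATOM      7  N   SER A   3       5.500   2.700   0.600  1.00  0.00           N
ATOM      8  CA  SER A   3       6.900   2.900   0.900  1.00  0.00           C
ATOM      9  OG  SER A   3       7.500   4.100   1.300  1.00  0.00           O
TER
HETATM   10  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O
END
"""


@pytest.fixture
def minimal_pdb_text():
    return MINIMAL_PDB


def dssp_line(idx: int, num: int, chain: str, aa: str, ss: str, acc: int = 50) -> str:
    """One classic-format DSSP data line with the fixed columns filled."""
    line = [" "] * 120
    line[0:5] = f"{idx:5d}"
    line[5:10] = f"{num:5d}"
    line[11] = chain
    line[13] = aa
    line[16] = ss
    line[34:38] = f"{acc:4d}"
    for lo, hi, text in (
        (38, 45, f"{0:7d}"), (46, 50, f"{0.0:4.1f}"),
        (50, 56, f"{0:6d}"), (57, 61, f"{0.0:4.1f}"),
        (61, 67, f"{0:6d}"), (68, 72, f"{0.0:4.1f}"),
        (72, 78, f"{0:6d}"), (79, 83, f"{0.0:4.1f}"),
        (103, 109, f"{-60.0:6.1f}"), (109, 115, f"{-45.0:6.1f}"),
    ):
        line[lo:hi] = text
    return "".join(line)


def make_dssp_text(records: list[tuple[str, int, str, str]], acc: int = 50) -> str:
    """Minimal classic DSSP output with the given (chain, num, aa, ss) rows."""
    head = [
        "==== Secondary Structure Definition by the program DSSP ====",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
        "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA",
    ]
    rows = [
        dssp_line(i + 1, num, chain, aa, ss, acc)
        for i, (chain, num, aa, ss) in enumerate(records)
    ]
    return "\n".join(head + rows) + "\n"
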