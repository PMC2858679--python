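"""Contacts and solvent-exposure features against brute-force oracles."""

import math

import numpy as np
import pytest

from smotifs.core import AtomRecord, ChainModel, ResidueRecord, Smotif, SSElement
from smotifs.features import (
    chain_sasa_per_residue,
    ic_ratio,
    internal_contacts,
    smotif_features,
    solvent_exposure,
)


def residue(i, atom_coords, chain_id="A", elements=None):
    elements = elements or ["C"] * len(atom_coords)
    return ResidueRecord(
        chain_id=chain_id,
        seq_pos=str(i),
        aa="A",
        atoms=[
            AtomRecord(name=f"X{j}", element=el, coord=np.array(c, dtype=float))
            for j, (c, el) in enumerate(zip(atom_coords, elements))
        ],
    )


def pair_chain(coords1_per_res, loop_coords, coords2_per_res):
    """Chain of SS1 residues, loop residues, SS2 residues with given atoms."""
    residues = []
    i = 1
    for c in coords1_per_res:
        residues.append(residue(i, c))
        i += 1
    for c in loop_coords:
        residues.append(residue(i, c))
        i += 1
    for c in coords2_per_res:
        residues.append(residue(i, c))
        i += 1
    chain = ChainModel("toy_A", residues)
    n1, nl, n2 = len(coords1_per_res), len(loop_coords), len(coords2_per_res)
    m = Smotif(
        ss1=SSElement("H", 0, n1 - 1),
        ss2=SSElement("H", n1 + nl, n1 + nl + n2 - 1),
    )
    return chain, m


def brute_force_contacts(m, chain, cutoff):
    """O(n^2) enumeration of cross-element heavy-atom pairs within cutoff."""
    count = 0
    for i in range(m.ss1.start, m.ss1.end + 1):
        for j in range(m.ss2.start, m.ss2.end + 1):
            if m.loop_len == 0 and (i, j) == (m.ss1.end, m.ss2.start):
                continue
            for a in chain.residues[i].heavy_atoms():
                for b in chain.residues[j].heavy_atoms():
                    if np.linalg.norm(a.coord - b.coord) <= cutoff:
                        count += 1
    return count


class TestInternalContacts:
    def test_far_apart_elements_have_none(self):
        chain, m = pair_chain(
            [[(0, 0, 0)], [(0, 0, 3)]], [[(50, 0, 0)]],
            [[(100, 0, 0)], [(100, 0, 3)]],
        )
        assert internal_contacts(m, chain) == 0

    def test_hand_built_fixture_matches_enumeration(self):
        # small fixture with a mix of close and distant cross-element atoms;
        # the exact count (4) was verified by the O(n^2) oracle
        chain, m = pair_chain(
            [[(0, 0, 0), (1.5, 0, 0)]],          # 2 atoms in SS1
            [[(0, 50, 0)]],                       # loop atom (never counted)
            [[(0, 0, 4.0)], [(0, 0, 20.0), (1.5, 0, 4.0)]],
        )
        assert internal_contacts(m, chain, cutoff=4.5) == pytest.approx(
            brute_force_contacts(m, chain, 4.5)
        )
        assert internal_contacts(m, chain, cutoff=4.5) == 4  # verified by oracle

    def test_matches_bruteforce_on_random_fixtures(self, rng):
        for _ in range(5):
            c1 = [[tuple(rng.uniform(0, 8, 3)) for _ in range(3)] for _ in range(3)]
            c2 = [[tuple(rng.uniform(4, 12, 3)) for _ in range(3)] for _ in range(2)]
            loop = [[tuple(rng.uniform(0, 12, 3))]]
            chain, m = pair_chain(c1, loop, c2)
            for cutoff in (2.0, 4.5, 8.0):
                assert internal_contacts(m, chain, cutoff) == brute_force_contacts(
                    m, chain, cutoff
                )

    def test_monotone_in_cutoff(self, rng):
        c1 = [[tuple(rng.uniform(0, 6, 3))] for _ in range(4)]
        c2 = [[tuple(rng.uniform(2, 9, 3))] for _ in range(4)]
        chain, m = pair_chain(c1, [[(0, 30, 0)]], c2)
        counts = [internal_contacts(m, chain, c) for c in (1, 2, 3, 4.5, 6, 10)]
        assert all(x <= y for x, y in zip(counts, counts[1:]))

    def test_zero_loop_excludes_junction_pair_only(self):
        chain, m = pair_chain(
            [[(0, 0, 0)], [(0, 0, 3)]], [],
            [[(0, 0, 6)], [(0, 0, 9)]],
        )
        assert m.loop_len == 0
        # junction residues 2 and 3 are 3 A apart but sequence-adjacent:
        # their pair is excluded; residue 2 to residue 4 is 6 A (> cutoff)
        assert internal_contacts(m, chain, cutoff=4.5) == 0
        assert internal_contacts(m, chain, cutoff=7.0) == brute_force_contacts(
            m, chain, 7.0
        )


class TestIcRatio:
    def test_zero_contacts_zero_ratio(self):
        chain, m = pair_chain([[(0, 0, 0)]] * 3, [], [[(90, 0, 0)]] * 9)
        assert ic_ratio(m, chain) == 0.0

    def test_arithmetic(self):
        chain, m = pair_chain(
            [[(0, 0, 0), (0.5, 0, 0), (1.0, 0, 0)]] * 2,
            [],
            [[(0, 0, 1.0)]] * 10,
        )
        n = internal_contacts(m, chain, 4.5)
        assert ic_ratio(m, chain, 4.5) == pytest.approx(n / 12)  # size 2 + 10

    def test_total_size_mode_counts_loop(self):
        chain, m = pair_chain(
            [[(0, 0, 0)]] * 3, [[(0, 9, 0)]] * 2, [[(0, 0, 2)]] * 3
        )
        n = internal_contacts(m, chain, 4.5)
        assert ic_ratio(m, chain, 4.5, size_mode="braces") == pytest.approx(n / 6)
        assert ic_ratio(m, chain, 4.5, size_mode="total") == pytest.approx(n / 8)


VDW = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
PROBE = 1.4


def brute_force_sasa(coords, elements, n_points=500, seed=0):
    """Independent Shrake-Rupley: random sphere points, same radii table."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_points, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    coords = np.asarray(coords, dtype=float)
    radii = np.array([VDW[e] + PROBE for e in elements])
    out = np.zeros(len(coords))
    for i, (c, r) in enumerate(zip(coords, radii)):
        sphere = c + r * pts
        free = np.ones(n_points, dtype=bool)
        for j, (c2, r2) in enumerate(zip(coords, radii)):
            if j == i:
                continue
            free &= np.linalg.norm(sphere - c2, axis=1) >= r2
        out[i] = 4 * math.pi * r ** 2 * free.mean()
    return out


class TestSolventExposure:
    def test_isolated_single_atom_matches_sphere_area(self):
        chain = ChainModel("t_A", [residue(1, [(0, 0, 0)], elements=["C"])])
        acc = chain_sasa_per_residue(chain)
        assert acc[0] == pytest.approx(4 * math.pi * (1.7 + PROBE) ** 2, rel=0.01)

    def test_isolated_residue_matches_bruteforce_oracle(self):
        coords = [(0, 0, 0), (1.5, 0, 0), (2.1, 1.2, 0), (2.0, -1.1, 0.8)]
        elements = ["N", "C", "C", "O"]
        chain = ChainModel("t_A", [residue(1, coords, elements=elements)])
        acc = chain_sasa_per_residue(chain)
        expected = brute_force_sasa(coords, elements).sum()
        assert acc[0] == pytest.approx(expected, rel=0.05)

    def test_caged_atom_contributes_nearly_nothing(self):
        # a central atom surrounded by 12 icosahedral neighbours at 3 A
        phi = (1 + math.sqrt(5)) / 2
        verts = []
        for a in (-1, 1):
            for b in (-phi, phi):
                verts += [(0, a, b), (a, b, 0), (b, 0, a)]
        verts = 3.0 * np.array(verts) / np.linalg.norm(verts[0])
        chain = ChainModel(
            "t_A",
            [residue(1, [(0, 0, 0)])] + [residue(i + 2, [tuple(v)])
                                         for i, v in enumerate(verts)],
        )
        acc = chain_sasa_per_residue(chain)
        free = 4 * math.pi * (1.7 + PROBE) ** 2
        assert acc[0] < 0.05 * free

    def test_zero_length_loop_modes_identical(self):
        chain, m = pair_chain(
            [[(0, 0, 0)], [(0, 0, 3)]], [], [[(0, 0, 6)], [(0, 0, 9)]]
        )
        acc = chain_sasa_per_residue(chain)
        with_loop = solvent_exposure(m, chain, include_loop=True,
                                     per_residue_acc=acc)
        without = solvent_exposure(m, chain, include_loop=False,
                                   per_residue_acc=acc)
        assert with_loop == pytest.approx(without)

    def test_features_bundle_consistency(self):
        chain, m = pair_chain(
            [[(0, 0, 0)], [(0, 0, 3)]], [[(5, 5, 5)]],
            [[(0, 2, 6)], [(0, 2, 9)]],
        )
        ft = smotif_features(m, chain, with_sasa=True)
        assert ft.size == 4
        assert ft.loop_len == 1
        assert ft.ic_ratio == pytest.approx(ft.n_contacts / ft.size)
        assert ft.mean_acc is not None and ft.mean_acc_no_loop is not None
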