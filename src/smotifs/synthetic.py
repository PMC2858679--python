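"""Ground-truth synthetic inputs.

Two generators live here:

* Idealised backbone geometry — Cα traces of textbook helices and
  strands, posed at prescribed (D, delta, theta, rho) internal
  coordinates by inverting the frame convention of :mod:`.geometry`.
  Whole chains built this way carry ground-truth H/E/C labels, so the
  decomposition and geometry stages can be verified end to end without
  any external structure or secondary-structure program.

* Fold populations — collections of "fold" Smotif-bin strings drawn
  from a heavy-tailed (Zipf) bin-frequency universe.  Novel folds draw a
  tunable fraction of their Smotifs from the rarest quartile of bins,
  emulating the enrichment of rare motifs in newly discovered folds.

Ideal element parameters (canonical textbook values): helix rise
1.5 Å/residue, twist 100°/residue, radius 2.3 Å; strand rise
3.3 Å/residue with an alternating ±1.0 Å zigzag.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .classification import BinId, default_scheme
from .core import AtomRecord, ChainModel, ResidueRecord, Smotif, SSElement
from .decomposition import CHAIN_BREAK_CA_DIST
from .geometry import DEGENERATE_TOL_DEG, compute_geometry, principal_axis

__all__ = [
    "HELIX_RISE", "HELIX_TWIST", "HELIX_RADIUS", "STRAND_RISE", "STRAND_ZIGZAG",
    "ROUNDTRIP_TOL",
    "PlacementTarget",
    "build_ideal_element",
    "place_at_geometry",
    "build_synthetic_chain",
    "random_placement_targets",
    "min_loop_len",
    "PopulationSpec",
    "PopulationSample",
    "simulate_population",
    "population_zscores",
]

HELIX_RISE = 1.5      # Å per residue along the axis
HELIX_TWIST = 100.0   # degrees per residue
HELIX_RADIUS = 2.3    # Å
STRAND_RISE = 3.3     # Å per residue along the axis
STRAND_ZIGZAG = 1.0   # Å lateral alternation

#: round-trip tolerance (D Å, delta°, theta°, rho°) of the placement solver
ROUNDTRIP_TOL = (0.5, 3.0, 3.0, 5.0)


@dataclass
class PlacementTarget:
    """Prescribed internal coordinates for posing SS2 relative to SS1.

    ``rho=None`` leaves the meridian unconstrained (required when delta
    is degenerate, i.e. the connecting vector lies along SS1's axis).
    """

    D: float
    delta: float
    theta: float
    rho: float | None
    loop_len: int = 3
    kinds: tuple[str, str] = ("H", "H")
    lengths: tuple[int, int] = (8, 8)

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("D must be positive")
        if not (0.0 <= self.delta <= 180.0 and 0.0 <= self.theta <= 180.0):
            raise ValueError("delta/theta must lie in [0, 180]")
        if self.rho is not None and not (0.0 <= self.rho < 360.0):
            raise ValueError("rho must lie in [0, 360)")
        if self.loop_len < 0:
            raise ValueError("loop_len must be >= 0")
        if any(k not in "HE" for k in self.kinds):
            raise ValueError("kinds must be H or E")
        minima = {"H": 3, "E": 3}
        if any(n < minima[k] for k, n in zip(self.kinds, self.lengths)):
            raise ValueError("element lengths must be >= 3")


def build_ideal_element(kind: str, length: int, start: int = 0) -> SSElement:
    """Ideal helix or strand Cα trace with its axis along +z.

    Deterministic; the first Cα sits near the origin at z = 0.
    """
    if length < 3:
        raise ValueError("an element needs at least 3 residues")
    i = np.arange(length)
    if kind == "H":
        ang = np.radians(HELIX_TWIST * i)
        coords = np.column_stack(
            [HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang), HELIX_RISE * i]
        )
    elif kind == "E":
        coords = np.column_stack(
            [STRAND_ZIGZAG * (-1.0) ** i, np.zeros(length), STRAND_RISE * i]
        )
    else:
        raise ValueError(f"kind must be H or E, got {kind!r}")
    return SSElement(kind=kind, start=start, end=start + length - 1, ca_coords=coords)


def _perp_reference(e1: np.ndarray) -> np.ndarray:
    r = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = r - np.dot(r, e1) * e1
    return u / np.linalg.norm(u)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix carrying unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 degrees about any perpendicular axis
        p = _perp_reference(a)
        return 2.0 * np.outer(p, p) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def place_at_geometry(ss1: SSElement, target: PlacementTarget) -> Smotif:
    """Build and pose SS2 so that the pair realises the target geometry.

    The inverse of :func:`smotifs.geometry.compute_geometry` under its
    frame convention; the azimuth solution is unique, and the result is
    verified by forward computation (tolerances ``ROUNDTRIP_TOL``) —
    the solver errors rather than silently approximating.
    """
    if ss1.ca_coords is None:
        raise ValueError("ss1 needs Cα coordinates")
    delta_degenerate = (
        target.delta < DEGENERATE_TOL_DEG or target.delta > 180.0 - DEGENERATE_TOL_DEG
    )
    theta_degenerate = (
        target.theta < DEGENERATE_TOL_DEG or target.theta > 180.0 - DEGENERATE_TOL_DEG
    )
    if delta_degenerate and target.rho is not None:
        raise ValueError(
            "delta of 0/180 makes the meridian undefined; use rho=None"
        )
    if theta_degenerate and target.rho not in (None, 0.0):
        raise ValueError(
            "theta of 0/180 leaves SS2's axis parallel to SS1's: "
            "no azimuth can realise a nonzero rho"
        )

    M1 = principal_axis(ss1)
    P1 = np.asarray(ss1.ca_coords[-1], dtype=float)
    e1 = M1
    u = _perp_reference(e1)
    d, t = math.radians(target.delta), math.radians(target.theta)
    L_dir = math.cos(d) * e1 + math.sin(d) * u
    P2 = P1 + target.D * L_dir
    e2, e3 = u, np.cross(e1, u)
    rho = 0.0 if target.rho is None else target.rho
    r = math.radians(rho)
    M2 = math.cos(t) * e1 + math.sin(t) * (math.sin(r) * e2 + math.cos(r) * e3)

    kind2, len2 = target.kinds[1], target.lengths[1]
    raw = build_ideal_element(
        kind2, len2, start=ss1.end + target.loop_len + 1
    )
    axis = principal_axis(raw)
    R = _rotation_between(axis, M2 / np.linalg.norm(M2))
    coords = (raw.ca_coords - raw.ca_coords[0]) @ R.T + P2
    ss2 = SSElement(
        kind=kind2, start=raw.start, end=raw.end, ca_coords=coords
    )

    got = compute_geometry(ss1, ss2)
    tolD, tol_d, tol_t, tol_r = ROUNDTRIP_TOL
    errs = [
        (abs(got.D - target.D), tolD),
        (abs(got.delta - target.delta), tol_d),
        (abs(got.theta - target.theta), tol_t),
    ]
    if target.rho is not None and not (delta_degenerate or theta_degenerate):
        diff = abs(got.rho - target.rho)
        errs.append((min(diff, 360.0 - diff), tol_r))
    if any(e > tol for e, tol in errs):
        raise RuntimeError(
            f"placement verification failed: target {target}, realised "
            f"({got.D:.2f}, {got.delta:.2f}, {got.theta:.2f}, {got.rho:.2f})"
        )
    return Smotif(ss1=ss1, ss2=ss2, source="synthetic", geometry=got)


def min_loop_len(D: float, step: float = 3.5) -> int:
    """Loop residues needed to bridge a gap of D Å without a chain break."""
    return max(1, math.ceil(D / step) - 1)


def _catmull_rom(p0, p1, p2, p3, n: int) -> np.ndarray:
    """n interior points of a Catmull-Rom segment from p1 to p2."""
    ts = np.linspace(0.0, 1.0, n + 2)[1:-1]
    out = []
    for t in ts:
        out.append(
            0.5 * ((2 * p1) + (-p0 + p2) * t
                   + (2 * p0 - 5 * p1 + 4 * p2 - p3) * t ** 2
                   + (-p0 + 3 * p1 - 3 * p2 + p3) * t ** 3)
        )
    return np.array(out) if out else np.empty((0, 3))


def build_synthetic_chain(
    targets: list[PlacementTarget],
    seed: int | None = None,
    structure_id: str = "SYNTH_A",
    first_kind: str = "H",
    first_length: int = 8,
) -> ChainModel:
    """A full Cα chain whose Smotif string realises the given targets.

    Consecutive targets chain: the SS2 posed for target i becomes the SS1
    of target i + 1 (its kind/length must match the next target's first
    kind/length).  Loop Cα are decorative Catmull-Rom points — geometry
    ops never read them — but their spacing is validated so the chain has
    no spurious break.  An empty target list gives a single-element chain.

    ``seed`` is accepted for interface uniformity; the construction is
    fully deterministic.
    """
    del seed  # deterministic construction
    if targets:
        first_kind, first_length = targets[0].kinds[0], targets[0].lengths[0]
    elements = [build_ideal_element(first_kind, first_length)]
    loops: list[np.ndarray] = []
    for i, tgt in enumerate(targets):
        ss1 = elements[-1]
        if (ss1.kind, ss1.length) != (tgt.kinds[0], tgt.lengths[0]):
            raise ValueError(
                f"target {i}: SS1 kind/length {tgt.kinds[0]}/{tgt.lengths[0]} does "
                f"not chain onto previous element {ss1.kind}/{ss1.length}"
            )
        motif = place_at_geometry(ss1, tgt)
        ss2 = motif.ss2
        p1, p2 = ss1.ca_coords[-1], ss2.ca_coords[0]
        p0 = ss1.ca_coords[-2] if ss1.length >= 2 else p1 - (p2 - p1)
        p3 = ss2.ca_coords[1] if ss2.length >= 2 else p2 + (p2 - p1)
        loop = _catmull_rom(p0, p1, p2, p3, tgt.loop_len)
        path = np.vstack([p1[None], loop, p2[None]])
        steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
        if np.any(steps > CHAIN_BREAK_CA_DIST):
            raise ValueError(
                f"target {i}: loop of {tgt.loop_len} residues cannot bridge "
                f"D={tgt.D:.1f} Å without a chain break "
                f"(max step {steps.max():.2f} Å); need loop_len >= "
                f"{min_loop_len(tgt.D)}"
            )
        loops.append(loop)
        elements.append(ss2)

    residues: list[ResidueRecord] = []

    def add_residue(coord: np.ndarray, ss3: str) -> None:
        residues.append(
            ResidueRecord(
                chain_id=structure_id.split("_")[-1] if "_" in structure_id else "A",
                seq_pos=str(len(residues) + 1),
                aa="A",
                atoms=[AtomRecord(name="CA", element="C", coord=np.array(coord))],
                ss3=ss3,
            )
        )

    for i, elem in enumerate(elements):
        for c in elem.ca_coords:
            add_residue(c, elem.kind)
        if i < len(loops):
            for c in loops[i]:
                add_residue(c, "C")
    return ChainModel(structure_id=structure_id, residues=residues)


def random_placement_targets(
    n: int,
    rng: np.random.Generator,
    kinds: tuple[str, str] | None = None,
) -> list[PlacementTarget]:
    """n feasible targets drawn away from degenerate boundaries.

    D in [4, 30] Å, delta/theta in [10, 170]°, rho uniform on [0, 360);
    element kinds random unless fixed, lengths 5-12 (helix) or 4-8
    (strand); loop length adequate for the drawn D.
    """
    out = []
    for _ in range(n):
        k = kinds or tuple(rng.choice(["H", "E"], size=2))
        lengths = tuple(
            int(rng.integers(5, 13)) if kk == "H" else int(rng.integers(4, 9))
            for kk in k
        )
        D = float(rng.uniform(4.0, 30.0))
        out.append(
            PlacementTarget(
                D=D,
                delta=float(rng.uniform(10.0, 170.0)),
                theta=float(rng.uniform(10.0, 170.0)),
                rho=float(rng.uniform(0.0, 360.0)),
                loop_len=min_loop_len(D),
                kinds=k,
                lengths=lengths,
            )
        )
    return out


def clustered_smotif_ensemble(
    n_clusters: int,
    per_cluster: int,
    rng: np.random.Generator,
    jitter: tuple[float, float, float, float] = (0.5, 5.0, 5.0, 8.0),
) -> list[Smotif]:
    """Smotifs grouped around recurring archetype geometries.

    Real structures reuse a modest set of motif geometries, so Smotifs
    sharing a bin are usually near-duplicates; a uniform random ensemble
    lacks that property.  Each cluster takes one random feasible
    archetype and scatters members around it with small jitter in
    (D, delta, theta, rho); element kinds and lengths are fixed within a
    cluster.
    """
    ensemble: list[Smotif] = []
    for tgt in random_placement_targets(n_clusters, rng):
        for _ in range(per_cluster):
            d = float(np.clip(tgt.D + rng.uniform(-jitter[0], jitter[0]), 1.0, None))
            de = float(np.clip(tgt.delta + rng.uniform(-jitter[1], jitter[1]),
                               DEGENERATE_TOL_DEG + 1, 179.0 - DEGENERATE_TOL_DEG))
            th = float(np.clip(tgt.theta + rng.uniform(-jitter[2], jitter[2]),
                               DEGENERATE_TOL_DEG + 1, 179.0 - DEGENERATE_TOL_DEG))
            rh = float((tgt.rho + rng.uniform(-jitter[3], jitter[3])) % 360.0)
            member = PlacementTarget(
                D=d, delta=de, theta=th, rho=rh,
                loop_len=tgt.loop_len, kinds=tgt.kinds, lengths=tgt.lengths,
            )
            ss1 = build_ideal_element(member.kinds[0], member.lengths[0])
            ensemble.append(place_at_geometry(ss1, member))
    return ensemble


# ---------------------------------------------------------------------------
# fold-population simulation
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """Conditions of a simulated fold population.

    The bin universe carries Zipf(s) base frequencies; "known" folds draw
    their Smotif strings from the base distribution, "novel" folds draw
    each Smotif from the rarest quartile of bins with probability
    ``enrichment`` (and from the base otherwise).
    """

    n_bins: int = 500
    zipf_s: float = 1.5
    n_known: int = 200
    n_novel: int = 200
    string_len_range: tuple[int, int] = (3, 12)
    enrichment: float = 0.8
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.enrichment <= 1.0):
            raise ValueError("enrichment must lie in [0, 1]")
        if min(self.n_bins, self.n_known, self.n_novel) < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.string_len_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid string_len_range")


@dataclass
class PopulationSample:
    spec: PopulationSpec
    known: dict[str, list[BinId]] = field(default_factory=dict)
    novel: dict[str, list[BinId]] = field(default_factory=dict)
    base_freqs: dict[BinId, float] = field(default_factory=dict)
    rare_quartile: set[BinId] = field(default_factory=set)


def _bin_universe(n: int) -> list[BinId]:
    scheme = default_scheme()
    bins = []
    for cls in ("HH", "HE", "EH", "EE"):
        bins.extend(scheme.all_bins(cls))
    if n > len(bins):
        raise ValueError(
            f"universe of {n} bins exceeds the {len(bins)} cells of the scheme"
        )
    # interleave classes so a truncated universe still mixes all four
    per_cls = len(bins) // 4
    order = [
        bins[c * per_cls + i] for i in range(per_cls) for c in range(4)
    ]
    return order[:n]


def simulate_population(spec: PopulationSpec) -> PopulationSample:
    """Draw known and novel fold Smotif-bin strings (seed-deterministic)."""
    rng = np.random.default_rng(spec.seed)
    bins = _bin_universe(spec.n_bins)
    ranks = np.arange(1, spec.n_bins + 1, dtype=float)
    base = ranks ** (-spec.zipf_s)
    base /= base.sum()
    # shuffle so frequency rank is not tied to bin enumeration order
    perm = rng.permutation(spec.n_bins)
    base = base[perm]

    order = np.argsort(base)  # ascending frequency
    n_rare = max(1, spec.n_bins // 4)
    rare_idx = order[:n_rare]
    rare_p = base[rare_idx] / base[rare_idx].sum()

    lo, hi = spec.string_len_range

    def draw_string(novel: bool) -> list[BinId]:
        n = int(rng.integers(lo, hi + 1))
        out = []
        for _ in range(n):
            if novel and rng.random() < spec.enrichment:
                out.append(bins[rare_idx[rng.choice(n_rare, p=rare_p)]])
            else:
                out.append(bins[rng.choice(spec.n_bins, p=base)])
        return out

    sample = PopulationSample(
        spec=spec,
        base_freqs={b: float(f) for b, f in zip(bins, base)},
        rare_quartile={bins[i] for i in rare_idx},
    )
    for i in range(spec.n_known):
        sample.known[f"known_{i:04d}"] = draw_string(False)
    for i in range(spec.n_novel):
        sample.novel[f"novel_{i:04d}"] = draw_string(True)
    return sample


def population_zscores(sample: PopulationSample, use_truth: bool = False):
    """Novelty Z-scores of all folds of a simulated population.

    Frequencies are estimated from the known folds' empirical bin counts
    (the realistic pipeline) unless ``use_truth`` selects the generator's
    base frequencies.  Returns (results, mean_z_known, mean_z_novel).
    """
    from .novelty import novelty_zscores, score_bin_string

    if use_truth:
        freqs = sample.base_freqs
    else:
        counts: dict[BinId, int] = {}
        for s in sample.known.values():
            for b in s:
                counts[b] = counts.get(b, 0) + 1
        total = sum(counts.values())
        freqs = {b: c / total for b, c in counts.items()}
    floor = min(f for f in freqs.values() if f > 0) / 2.0
    scored = [
        (sid, score_bin_string(s, freqs, floor))
        for sid, s in itertools.chain(sample.known.items(), sample.novel.items())
    ]
    results = novelty_zscores(scored)
    zk = [r.z for r in results if r.structure_id.startswith("known_")]
    zn = [r.z for r in results if r.structure_id.startswith("novel_")]
    return results, float(np.mean(zk)), float(np.mean(zn))
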