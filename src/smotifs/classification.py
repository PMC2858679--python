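"""Discretisation of Smotif geometry space into bins.

The default ("tailored") scheme uses 4 Å distance bins capped at 40 Å,
60° bins for the hoist and packing angles starting at 0°, and 60° bins
for the meridian starting at 30° (so [330°, 30°) is a single wrapped
bin).  That gives 10 × 3 × 3 × 6 = 540 geometric cells per bracing class;
the number of *occupied* cells in any given structure collection is
usually far smaller and is reported separately.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .core import Smotif, SmotifGeometry
from .geometry import superpose_rmsd

__all__ = [
    "BinningScheme",
    "BinId",
    "default_scheme",
    "assign_bin",
    "bin_smotif",
    "evaluate_binning",
    "BinningEvaluation",
]


class BinId(NamedTuple):
    """A Smotif's cell: bracing class plus indices along (D, δ, θ, ρ)."""

    cls: str
    iD: int
    i_delta: int
    i_theta: int
    i_rho: int

    def __str__(self) -> str:
        return f"{self.cls}_{self.iD}_{self.i_delta}_{self.i_theta}_{self.i_rho}"

    @classmethod
    def parse(cls, text: str) -> "BinId":
        c, *idx = text.split("_")
        if c not in ("HH", "HE", "EH", "EE") or len(idx) != 4:
            raise ValueError(f"malformed bin id {text!r}")
        return BinId(c, *(int(i) for i in idx))


@dataclass(frozen=True)
class BinningScheme:
    """Bin widths of the 4-coordinate discretisation.

    All intervals are half-open [lo, hi); D values above ``D_max`` are
    clamped into the last distance bin; δ/θ at exactly 180° fold into the
    last angular bin; ρ is shifted by ``rho_offset`` and wrapped.
    """

    dD: float = 4.0
    D_max: float = 40.0
    d_delta: float = 60.0
    d_theta: float = 60.0
    d_rho: float = 60.0
    rho_offset: float = 30.0

    def __post_init__(self) -> None:
        if min(self.dD, self.d_delta, self.d_theta, self.d_rho) <= 0:
            raise ValueError("bin widths must be positive")
        if self.D_max <= 0 or self.D_max % self.dD != 0:
            raise ValueError("D_max must be a positive multiple of dD")
        for width, span, name in (
            (self.d_delta, 180.0, "d_delta"),
            (self.d_theta, 180.0, "d_theta"),
            (self.d_rho, 360.0, "d_rho"),
        ):
            if span % width != 0:
                raise ValueError(f"{name}={width} must divide {span}")
        if not (0.0 <= self.rho_offset < self.d_rho):
            raise ValueError("rho_offset must lie in [0, d_rho)")

    # --- cell counts -------------------------------------------------
    @property
    def n_D(self) -> int:
        return int(self.D_max / self.dD)

    @property
    def n_delta(self) -> int:
        return int(180.0 / self.d_delta)

    @property
    def n_theta(self) -> int:
        return int(180.0 / self.d_theta)

    @property
    def n_rho(self) -> int:
        return int(360.0 / self.d_rho)

    @property
    def cells_per_class(self) -> int:
        return self.n_D * self.n_delta * self.n_theta * self.n_rho

    def all_bins(self, cls: str) -> Iterable[BinId]:
        for idx in itertools.product(
            range(self.n_D), range(self.n_delta), range(self.n_theta), range(self.n_rho)
        ):
            yield BinId(cls, *idx)

    # --- naming ------------------------------------------------------
    def name(self) -> str:
        def fmt(x: float) -> str:
            return str(int(x)) if float(x).is_integer() else str(x)

        return "_".join(fmt(v) for v in (self.dD, self.d_delta, self.d_theta, self.d_rho))

    @classmethod
    def from_name(
        cls, name: str, D_max: float = 40.0, rho_offset: float | None = None
    ) -> "BinningScheme":
        """Parse a ``dD_ddelta_dtheta_drho`` label such as ``4_60_60_60``.

        ``rho_offset`` defaults to half the meridian width for the
        tailored 60° scheme and to 0 otherwise, mirroring the convention
        that only the tailored scheme's meridian grid starts at 30°.
        """
        parts = name.split("_")
        if len(parts) != 4:
            raise ValueError(f"malformed scheme name {name!r}")
        dD, dd, dt, dr = (float(p) for p in parts)
        if rho_offset is None:
            rho_offset = 30.0 if dr == 60.0 else 0.0
        return cls(dD=dD, D_max=D_max, d_delta=dd, d_theta=dt, d_rho=dr,
                   rho_offset=rho_offset)


def default_scheme() -> BinningScheme:
    """The tailored scheme: 4 Å / 60° / 60° / 60° with ρ offset 30°."""
    return BinningScheme()


def assign_bin(g: SmotifGeometry, cls: str, scheme: BinningScheme) -> BinId:
    """Map a geometry to its cell (a total function over finite geometries)."""
    if cls not in ("HH", "HE", "EH", "EE"):
        raise ValueError(f"unknown bracing class {cls!r}")
    D = min(max(g.D, 0.0), scheme.D_max)
    iD = min(int(D // scheme.dD), scheme.n_D - 1)
    i_delta = min(int(g.delta // scheme.d_delta), scheme.n_delta - 1)
    i_theta = min(int(g.theta // scheme.d_theta), scheme.n_theta - 1)
    i_rho = int(((g.rho - scheme.rho_offset) % 360.0) // scheme.d_rho)
    i_rho = min(i_rho, scheme.n_rho - 1)
    return BinId(cls, iD, i_delta, i_theta, i_rho)


def bin_smotif(m: Smotif, scheme: BinningScheme) -> BinId:
    if m.geometry is None:
        raise ValueError("Smotif has no geometry; run the geometry stage first")
    return assign_bin(m.geometry, m.cls, scheme)


@dataclass
class BinningEvaluation:
    """Same-bin vs different-bin RMSD distributions for one scheme."""

    scheme: BinningScheme
    same_bin_rmsd: np.ndarray
    diff_bin_rmsd: np.ndarray

    @property
    def frac_same_bin_below_1A(self) -> float:
        if self.same_bin_rmsd.size == 0:
            return math.nan
        return float(np.mean(self.same_bin_rmsd < 1.0))


def evaluate_binning(
    smotifs: Sequence[Smotif],
    schemes: Sequence[BinningScheme],
    n_pairs: int = 2000,
    seed: int | None = None,
) -> list[BinningEvaluation]:
    """Assess partitioning power of candidate schemes.

    For each scheme, Smotif pairs sharing a bin and pairs from different
    bins are sampled (up to ``n_pairs`` each) and superposed; a sharp
    scheme keeps same-bin RMSD low.  Only same-class pairs are compared.
    """
    if not smotifs:
        raise ValueError("no Smotifs to evaluate")
    rng = np.random.default_rng(seed)
    results = []
    for scheme in schemes:
        by_bin: dict[BinId, list[Smotif]] = {}
        for m in smotifs:
            by_bin.setdefault(bin_smotif(m, scheme), []).append(m)
        same_pairs: list[tuple[Smotif, Smotif]] = []
        for members in by_bin.values():
            if len(members) < 2:
                continue
            same_pairs.extend(itertools.combinations(members, 2))
        if len(same_pairs) > n_pairs:
            idx = rng.choice(len(same_pairs), size=n_pairs, replace=False)
            same_pairs = [same_pairs[i] for i in idx]

        bins = list(by_bin)
        diff_pairs: list[tuple[Smotif, Smotif]] = []
        attempts = 0
        while len(diff_pairs) < n_pairs and attempts < 20 * n_pairs and len(bins) > 1:
            attempts += 1
            b1, b2 = rng.choice(len(bins), size=2, replace=False)
            if bins[b1].cls != bins[b2].cls:
                continue
            m1 = by_bin[bins[b1]][rng.integers(len(by_bin[bins[b1]]))]
            m2 = by_bin[bins[b2]][rng.integers(len(by_bin[bins[b2]]))]
            diff_pairs.append((m1, m2))

        results.append(
            BinningEvaluation(
                scheme=scheme,
                same_bin_rmsd=np.array([superpose_rmsd(a, b) for a, b in same_pairs]),
                diff_bin_rmsd=np.array([superpose_rmsd(a, b) for a, b in diff_pairs]),
            )
        )
    return results
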