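"""Fold-novelty scoring and comparison against a reference Smotif set.

A structure expressed as a string of N Smotifs gets a normalized
probability score: the length-normalised log of the product of the
individual Smotif bin frequencies,

    S = (1/N) * sum_i ln fr_i ,

so S is the mean log-frequency of the composition and does not grow with
chain length.  Scores are standardised over a population of structures
into Z-scores, z = (S − μ)/σ; structures enriched in rare Smotifs sit in
the low-z tail.

Comparison against a reference set follows two levels of strictness:
geometry-bin co-membership, and additionally comparable flanking-element
lengths (within 2 residues for strands, 4 for helices).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .classification import BinId, bin_smotif
from .core import Smotif
from .library import SmotifLibrary

__all__ = [
    "NoveltyResult",
    "ComparisonReport",
    "novelty_score",
    "score_bin_string",
    "novelty_zscores",
    "match_geometry",
    "match_strict_fss",
    "compare_to_reference",
    "shared_smotifs",
    "LENGTH_TOLERANCE",
]

#: flanking-length tolerance per element kind (residues)
LENGTH_TOLERANCE = {"E": 2, "H": 4}


@dataclass
class NoveltyResult:
    structure_id: str
    N: int
    score: float
    z: float


@dataclass
class MatchRecord:
    """Per-Smotif outcome of the reference comparison."""

    bin_id: BinId
    ss1_len: int
    ss2_len: int
    geometry_known: bool
    fss_known: bool


@dataclass
class ComparisonReport:
    n_smotifs: int
    n_new_geometry: int
    n_unique_fss: int
    records: list[MatchRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_new_geometry <= self.n_unique_fss <= self.n_smotifs


def _floor_value(library: SmotifLibrary, floor: float | None) -> float:
    # half the smallest nonzero frequency keeps unseen bins finite but
    # strictly rarer than anything observed
    return library.min_nonzero_freq() / 2.0 if floor is None else floor


def score_bin_string(
    bins: Sequence, freqs: Mapping, floor: float
) -> float:
    """Mean log-frequency of a string of bin keys under a frequency map."""
    if not bins:
        raise ValueError("cannot score an empty Smotif string")
    if floor <= 0:
        raise ValueError("frequency floor must be positive")
    return float(np.mean([math.log(max(freqs.get(b, 0.0), floor)) for b in bins]))


def novelty_score(
    smotifs: Sequence[Smotif],
    library: SmotifLibrary,
    floor: float | None = None,
) -> float:
    """Normalized probability score S of a structure's Smotif string.

    ``floor`` replaces zero frequencies of unseen bins; by default half
    the smallest nonzero library frequency.  Lower S = rarer composition.
    """
    bins = [bin_smotif(m, library.scheme) for m in smotifs]
    return score_bin_string(bins, library.freqs, _floor_value(library, floor))


def novelty_zscores(
    scores: Sequence[tuple[str, float]], n_smotifs: Mapping[str, int] | None = None
) -> list[NoveltyResult]:
    """Standardise scores over the supplied population (population σ).

    By construction the returned z-values have mean 0 and standard
    deviation 1 across the population.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 structures to standardise")
    values = np.array([s for _, s in scores], dtype=float)
    mu = values.mean()
    sigma = values.std()  # population convention
    if sigma == 0:
        raise ValueError("degenerate population: all scores identical")
    out = []
    for (sid, s), z in zip(scores, (values - mu) / sigma):
        n = n_smotifs.get(sid, 0) if n_smotifs else 0
        out.append(NoveltyResult(structure_id=sid, N=n, score=s, z=float(z)))
    return out


def match_geometry(q: Smotif, ref: SmotifLibrary) -> bool:
    """True iff the query's geometry bin is occupied in the reference."""
    return ref.count(bin_smotif(q, ref.scheme)) > 0


def match_strict_fss(q: Smotif, candidates: Iterable[Smotif]) -> bool:
    """True iff some candidate has comparable flanking-element lengths.

    Tolerance is applied per element by its own kind: a strand may differ
    by at most 2 residues, a helix by at most 4 (boundary inclusive).
    """
    t1 = LENGTH_TOLERANCE[q.ss1.kind]
    t2 = LENGTH_TOLERANCE[q.ss2.kind]
    for c in candidates:
        if (
            abs(c.ss1.length - q.ss1.length) <= t1
            and abs(c.ss2.length - q.ss2.length) <= t2
        ):
            return True
    return False


def compare_to_reference(
    smotifs: Sequence[Smotif],
    ref_library: SmotifLibrary,
    ref_smotifs: Sequence[Smotif],
) -> ComparisonReport:
    """Count query Smotifs with unseen geometry or unique flanking lengths.

    A Smotif has *new geometry* when its bin is unoccupied in the
    reference library; it has *unique FSS* when additionally no reference
    Smotif in the same (class, bin) has comparable SS1/SS2 lengths.  New
    geometry implies unique FSS, so n_new_geometry <= n_unique_fss.
    """
    scheme = ref_library.scheme
    ref_by_bin: dict[BinId, list[Smotif]] = {}
    for m in ref_smotifs:
        ref_by_bin.setdefault(bin_smotif(m, scheme), []).append(m)

    records: list[MatchRecord] = []
    for q in smotifs:
        b = bin_smotif(q, scheme)
        geom_known = match_geometry(q, ref_library) or b in ref_by_bin
        fss_known = geom_known and match_strict_fss(q, ref_by_bin.get(b, []))
        records.append(
            MatchRecord(
                bin_id=b, ss1_len=q.ss1.length, ss2_len=q.ss2.length,
                geometry_known=geom_known, fss_known=fss_known,
            )
        )
    return ComparisonReport(
        n_smotifs=len(records),
        n_new_geometry=sum(not r.geometry_known for r in records),
        n_unique_fss=sum(not r.fss_known for r in records),
        records=records,
    )


def shared_smotifs(
    a: Sequence[Smotif], b: Sequence[Smotif], scheme=None
) -> tuple[int, list[tuple[int, int]]]:
    """Greedy one-to-one matching of two Smotif strings on (class, bin).

    Returns the number of geometry-bin-equivalent pairs and the matched
    index pairs (i in ``a``, j in ``b``).  Each Smotif is used at most
    once; matching proceeds in sequence order of ``a``.
    """
    from .classification import default_scheme

    scheme = scheme or default_scheme()
    bins_b = [bin_smotif(m, scheme) for m in b]
    used = [False] * len(b)
    pairs: list[tuple[int, int]] = []
    for i, m in enumerate(a):
        bi = bin_smotif(m, scheme)
        for j, bj in enumerate(bins_b):
            if not used[j] and bj == bi:
                used[j] = True
                pairs.append((i, j))
                break
    return len(pairs), pairs
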