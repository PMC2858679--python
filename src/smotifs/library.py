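"""Smotif frequency libraries with fold-level redundancy removal.

Fold classifications are heavily redundant: one fold may be represented
by one structure or by thousands.  To keep popular folds from dominating
the statistics, each counting round draws exactly one structure per fold
uniformly at random; bin counts are averaged over ``n_rounds`` such
rounds (100 by default) and normalised into relative frequencies.

Frequencies are normalised globally over all four bracing classes (one
simplex) because novelty scores multiply frequencies of mixed-class
Smotifs in a single product; a per-class mode is available for class-wise
frequency profiles.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .classification import BinId, BinningScheme, bin_smotif
from .core import Smotif

__all__ = [
    "SmotifLibrary",
    "build_library",
    "count_bins",
    "saturation_curve",
    "frequency_profile_by_category",
    "categorize_folds",
    "FOLD_SIZE_CATEGORIES",
]

#: fold-population categories: label -> half-open [lo, hi) structure-count range
FOLD_SIZE_CATEGORIES: dict[str, tuple[int, float]] = {
    "1": (1, 2),
    "2-10": (2, 10),
    "10-50": (10, 50),
    "50-100": (50, 100),
    ">100": (100, float("inf")),
}


@dataclass
class SmotifLibrary:
    """Per-bin average counts and relative frequencies of Smotifs."""

    scheme: BinningScheme
    counts: dict[BinId, float]
    n_rounds: int = 1
    seed: int | None = None
    first_seen: dict[BinId, _dt.date] = field(default_factory=dict)
    normalization: str = "global"  # "global" or "per_class"
    freqs: dict[BinId, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.freqs:
            self.freqs = _normalize(self.counts, self.normalization)

    def frequency(self, b: BinId) -> float:
        return self.freqs.get(b, 0.0)

    def count(self, b: BinId) -> float:
        return self.counts.get(b, 0.0)

    @property
    def occupied_bins(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)

    def min_nonzero_freq(self) -> float:
        nz = [f for f in self.freqs.values() if f > 0]
        if not nz:
            raise ValueError("library has no occupied bins")
        return min(nz)

    # --- serialization ----------------------------------------------
    def to_json(self) -> str:
        entries = []
        for b in sorted(self.counts):
            e = {
                "cls": b.cls, "iD": b.iD, "i_delta": b.i_delta,
                "i_theta": b.i_theta, "i_rho": b.i_rho,
                "count": self.counts[b], "freq": self.freqs.get(b, 0.0),
            }
            if b in self.first_seen:
                e["first_seen"] = self.first_seen[b].isoformat()
            entries.append(e)
        scheme = self.scheme
        return json.dumps(
            {
                "scheme": {
                    "dD": scheme.dD, "D_max": scheme.D_max,
                    "d_delta": scheme.d_delta, "d_theta": scheme.d_theta,
                    "d_rho": scheme.d_rho, "rho_offset": scheme.rho_offset,
                },
                "n_rounds": self.n_rounds,
                "seed": self.seed,
                "normalization": self.normalization,
                "entries": entries,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SmotifLibrary":
        doc = json.loads(text)
        scheme = BinningScheme(**doc["scheme"])
        counts: dict[BinId, float] = {}
        freqs: dict[BinId, float] = {}
        first_seen: dict[BinId, _dt.date] = {}
        for e in doc["entries"]:
            b = BinId(e["cls"], e["iD"], e["i_delta"], e["i_theta"], e["i_rho"])
            counts[b] = float(e["count"])
            freqs[b] = float(e["freq"])
            if "first_seen" in e:
                first_seen[b] = _dt.date.fromisoformat(e["first_seen"])
        return cls(
            scheme=scheme, counts=counts, n_rounds=int(doc["n_rounds"]),
            seed=doc.get("seed"), first_seen=first_seen,
            normalization=doc.get("normalization", "global"), freqs=freqs,
        )


def _normalize(counts: Mapping[BinId, float], mode: str) -> dict[BinId, float]:
    if mode == "global":
        total = sum(counts.values())
        if total <= 0:
            return {b: 0.0 for b in counts}
        return {b: c / total for b, c in counts.items()}
    if mode == "per_class":
        totals: dict[str, float] = {}
        for b, c in counts.items():
            totals[b.cls] = totals.get(b.cls, 0.0) + c
        return {
            b: (c / totals[b.cls] if totals[b.cls] > 0 else 0.0)
            for b, c in counts.items()
        }
    raise ValueError(f"unknown normalization mode {mode!r}")


def count_bins(
    smotifs: Iterable[Smotif], scheme: BinningScheme
) -> dict[BinId, int]:
    """Plain instance counts of Smotifs per bin (no redundancy removal)."""
    counts: dict[BinId, int] = {}
    for m in smotifs:
        b = bin_smotif(m, scheme)
        counts[b] = counts.get(b, 0) + 1
    return counts


def build_library(
    smotifs_by_structure: Mapping[str, Sequence[Smotif]],
    folds: Mapping[str, str],
    scheme: BinningScheme,
    n_rounds: int = 100,
    seed: int | None = None,
    normalization: str = "global",
) -> SmotifLibrary:
    """Fold-debiased frequency library.

    Each round picks one structure per fold uniformly; per-bin instance
    counts from the picked structures are accumulated and divided by the
    number of rounds.  Fully reproducible under a fixed ``seed``.
    """
    if not smotifs_by_structure:
        raise ValueError("no structures supplied")
    missing = [s for s in smotifs_by_structure if s not in folds]
    if missing:
        raise ValueError(f"no fold assignment for structure(s): {', '.join(missing)}")
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")

    by_fold: dict[str, list[str]] = {}
    for sid in sorted(smotifs_by_structure):
        by_fold.setdefault(folds[sid], []).append(sid)

    # bins and first-seen dates never depend on the sampling
    bins_of: dict[str, list[BinId]] = {
        sid: [bin_smotif(m, scheme) for m in ms]
        for sid, ms in smotifs_by_structure.items()
    }
    first_seen: dict[BinId, _dt.date] = {}
    for sid, ms in smotifs_by_structure.items():
        for m, b in zip(ms, bins_of[sid]):
            if m.date is not None and (b not in first_seen or m.date < first_seen[b]):
                first_seen[b] = m.date

    rng = np.random.default_rng(seed)
    acc: dict[BinId, float] = {}
    for _ in range(n_rounds):
        for fold in sorted(by_fold):
            members = by_fold[fold]
            sid = members[rng.integers(len(members))]
            for b in bins_of[sid]:
                acc[b] = acc.get(b, 0.0) + 1.0
    counts = {b: c / n_rounds for b, c in acc.items()}
    return SmotifLibrary(
        scheme=scheme, counts=counts, n_rounds=n_rounds, seed=seed,
        first_seen=first_seen, normalization=normalization,
    )


def saturation_curve(
    smotifs: Iterable[Smotif], scheme: BinningScheme
) -> dict[str, list[tuple[_dt.date, int]]]:
    """Cumulative count of distinct occupied bins over deposition time.

    Returns, per bracing class, a monotone step function as a list of
    (date, cumulative distinct bins first seen on or before date) pairs.
    Undated Smotifs are ignored.
    """
    first: dict[BinId, _dt.date] = {}
    for m in smotifs:
        if m.date is None:
            continue
        b = bin_smotif(m, scheme)
        if b not in first or m.date < first[b]:
            first[b] = m.date
    curves: dict[str, list[tuple[_dt.date, int]]] = {}
    for cls in ("HH", "HE", "EH", "EE"):
        dates = sorted(d for b, d in first.items() if b.cls == cls)
        curve: list[tuple[_dt.date, int]] = []
        for d in dates:
            if curve and curve[-1][0] == d:
                curve[-1] = (d, curve[-1][1] + 1)
            else:
                curve.append((d, (curve[-1][1] if curve else 0) + 1))
        curves[cls] = curve
    return curves


def categorize_folds(
    fold_sizes: Mapping[str, int], new_folds: set[str] | None = None
) -> dict[str, str]:
    """Partition folds into population categories.

    Folds flagged in ``new_folds`` go to the "new" category regardless of
    size; the rest fall into half-open size ranges [1,2), [2,10), [10,50),
    [50,100), [100, inf).
    """
    new_folds = new_folds or set()
    out: dict[str, str] = {}
    for fold, n in fold_sizes.items():
        if fold in new_folds:
            out[fold] = "new"
            continue
        for label, (lo, hi) in FOLD_SIZE_CATEGORIES.items():
            if lo <= n < hi:
                out[fold] = label
                break
        else:
            raise ValueError(f"fold {fold!r} has invalid size {n}")
    return out


def frequency_profile_by_category(
    folds: Mapping[str, str],
    fold_sizes: Mapping[str, int],
    smotifs_by_structure: Mapping[str, Sequence[Smotif]],
    library: SmotifLibrary,
    new_folds: set[str] | None = None,
    n_hist_bins: int = 20,
) -> dict[str, dict]:
    """Distribution of library frequencies per fold-population category.

    For every category, the library frequencies of all member-structure
    Smotifs are histogrammed on a log scale (zero-frequency Smotifs are
    counted separately under ``n_unseen``).  Returns per category a dict
    with ``frequencies``, ``hist``, ``edges`` (log10-spaced), ``n_unseen``.
    """
    category_of = categorize_folds(fold_sizes, new_folds)
    freqs_by_cat: dict[str, list[float]] = {}
    for sid, ms in smotifs_by_structure.items():
        cat = category_of[folds[sid]]
        bucket = freqs_by_cat.setdefault(cat, [])
        for m in ms:
            bucket.append(library.frequency(bin_smotif(m, library.scheme)))

    all_nonzero = [f for fs in freqs_by_cat.values() for f in fs if f > 0]
    if all_nonzero:
        lo, hi = np.log10(min(all_nonzero)), np.log10(max(all_nonzero))
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.logspace(lo, hi, n_hist_bins + 1)
    else:
        edges = np.logspace(-6, 0, n_hist_bins + 1)

    out: dict[str, dict] = {}
    for cat, fs in freqs_by_cat.items():
        arr = np.asarray(fs)
        nz = arr[arr > 0]
        hist, _ = np.histogram(nz, bins=edges)
        total = hist.sum()
        out[cat] = {
            "frequencies": arr,
            "hist": hist / total if total else hist.astype(float),
            "edges": edges,
            "n_unseen": int(np.sum(arr == 0)),
        }
    return out
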