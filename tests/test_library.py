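"""Frequency-library construction, saturation curves, category profiles."""

import datetime as dt
import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from smotifs.classification import BinId, default_scheme
from smotifs.core import Smotif, SmotifGeometry, SSElement
from smotifs.library import (
    SmotifLibrary,
    build_library,
    categorize_folds,
    frequency_profile_by_category,
    saturation_curve,
)


def smotif_in_bin(iD: int, cls: str = "HH", date=None, ss_len: int = 5) -> Smotif:
    """A coordinate-free Smotif landing in distance bin iD of the default scheme."""
    g = SmotifGeometry(D=iD * 4.0 + 2.0, delta=30.0, theta=30.0, rho=60.0)
    ss1 = SSElement(kind=cls[0], start=0, end=ss_len - 1)
    ss2 = SSElement(kind=cls[1], start=ss_len + 2, end=2 * ss_len + 1)
    return Smotif(ss1=ss1, ss2=ss2, geometry=g, date=date)


BIN_A, BIN_B, BIN_C = 0, 1, 2  # distance-bin aliases used throughout


class TestBuildLibrary:
    def test_single_structure_exact_frequencies(self):
        """One fold, one structure: no sampling variance for any n_rounds."""
        ms = [smotif_in_bin(BIN_A), smotif_in_bin(BIN_A), smotif_in_bin(BIN_B)]
        for n_rounds in (1, 7):
            lib = build_library(
                {"s1": ms}, {"s1": "f1"}, default_scheme(), n_rounds=n_rounds, seed=0
            )
            freqs = {b.iD: f for b, f in lib.freqs.items()}
            assert freqs[BIN_A] == pytest.approx(2 / 3)
            assert freqs[BIN_B] == pytest.approx(1 / 3)

    def test_two_structures_converge_to_enumeration(self):
        """One fold, two structures in disjoint bins: each picked w.p. 1/2,
        so expected per-round counts are 0.5 and 0.5 (exact enumeration of
        the two equiprobable draws)."""
        data = {"s1": [smotif_in_bin(BIN_A)], "s2": [smotif_in_bin(BIN_B)]}
        folds = {"s1": "f1", "s2": "f1"}
        lib = build_library(data, folds, default_scheme(), n_rounds=4000, seed=3)
        counts = {b.iD: c for b, c in lib.counts.items()}
        assert counts[BIN_A] == pytest.approx(0.5, abs=0.03)
        assert counts[BIN_B] == pytest.approx(0.5, abs=0.03)

    def test_three_structure_enumeration(self):
        """<=3 structures per fold: averages approach the analytic
        expectation (each structure picked w.p. 1/3)."""
        data = {
            "s1": [smotif_in_bin(BIN_A)],
            "s2": [smotif_in_bin(BIN_A)],
            "s3": [smotif_in_bin(BIN_B), smotif_in_bin(BIN_B)],
        }
        folds = dict.fromkeys(data, "f1")
        lib = build_library(data, folds, default_scheme(), n_rounds=6000, seed=9)
        counts = {b.iD: c for b, c in lib.counts.items()}
        assert counts[BIN_A] == pytest.approx(2 / 3, abs=0.04)
        assert counts[BIN_B] == pytest.approx(2 / 3, abs=0.04)

    def test_frequencies_sum_to_one(self):
        data = {
            "s1": [smotif_in_bin(BIN_A), smotif_in_bin(BIN_C, "HE")],
            "s2": [smotif_in_bin(BIN_B, "EE")],
        }
        lib = build_library(
            data, {"s1": "f1", "s2": "f2"}, default_scheme(), n_rounds=11, seed=1
        )
        assert sum(lib.freqs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_seeded_determinism(self):
        data = {f"s{i}": [smotif_in_bin(i % 4)] for i in range(8)}
        folds = {f"s{i}": f"f{i % 3}" for i in range(8)}
        lib1 = build_library(data, folds, default_scheme(), n_rounds=20, seed=42)
        lib2 = build_library(data, folds, default_scheme(), n_rounds=20, seed=42)
        assert lib1.counts == lib2.counts

    def test_missing_fold_assignment_names_structure(self):
        with pytest.raises(ValueError, match="s_orphan"):
            build_library(
                {"s_orphan": [smotif_in_bin(0)]}, {}, default_scheme()
            )

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            build_library({}, {}, default_scheme())

    def test_per_class_normalization_mode(self):
        data = {
            "s1": [smotif_in_bin(BIN_A, "HH"), smotif_in_bin(BIN_B, "HH"),
                   smotif_in_bin(BIN_A, "EE")],
        }
        lib = build_library(
            data, {"s1": "f1"}, default_scheme(), n_rounds=1, seed=0,
            normalization="per_class",
        )
        by_cls = {}
        for b, f in lib.freqs.items():
            by_cls[b.cls] = by_cls.get(b.cls, 0.0) + f
        assert by_cls["HH"] == pytest.approx(1.0)
        assert by_cls["EE"] == pytest.approx(1.0)

    def test_json_roundtrip(self):
        data = {"s1": [smotif_in_bin(BIN_A, date=dt.date(2001, 5, 1))]}
        lib = build_library(data, {"s1": "f1"}, default_scheme(), n_rounds=3, seed=7)
        back = SmotifLibrary.from_json(lib.to_json())
        assert back.counts == lib.counts
        assert back.freqs == lib.freqs
        assert back.first_seen == lib.first_seen
        assert back.scheme == lib.scheme


class TestSaturationCurve:
    def test_single_date_single_step(self):
        d = dt.date(1999, 1, 1)
        ms = [smotif_in_bin(BIN_A, date=d), smotif_in_bin(BIN_B, date=d),
              smotif_in_bin(BIN_A, date=d)]
        curves = saturation_curve(ms, default_scheme())
        assert curves["HH"] == [(d, 2)]

    def test_monotone_nondecreasing_any_order(self, rng):
        dates = [dt.date(1995 + int(y), 1 + int(m), 1)
                 for y, m in zip(rng.integers(0, 10, 40), rng.integers(0, 12, 40))]
        ms = [smotif_in_bin(int(b), date=d)
              for b, d in zip(rng.integers(0, 10, 40), dates)]
        rng.shuffle(ms)
        curves = saturation_curve(ms, default_scheme())
        for curve in curves.values():
            counts = [c for _, c in curve]
            assert counts == sorted(counts)

    def test_matches_bruteforce_running_set_scan(self, rng):
        dates = sorted(
            dt.date(1990, 1, 1) + dt.timedelta(days=int(x))
            for x in rng.integers(0, 7000, 60)
        )
        bins = rng.integers(0, 10, 60)
        ms = [smotif_in_bin(int(b), date=d) for b, d in zip(bins, dates)]
        curve = saturation_curve(ms, default_scheme())["HH"]
        # oracle: running distinct-set size scanned in date order
        seen, expected = set(), {}
        for b, d in sorted(zip(bins, dates), key=lambda x: x[1]):
            seen.add(b)
            expected[d] = len(seen)
        assert curve[-1][1] == len(set(bins))
        for d, c in curve:
            assert c == expected[d]

    def test_terminal_value_is_order_independent(self, rng):
        ms = [smotif_in_bin(int(b), date=dt.date(2000, 1, 1 + int(i)))
              for i, b in enumerate(rng.integers(0, 6, 25))]
        fwd = saturation_curve(ms, default_scheme())["HH"][-1][1]
        rev = saturation_curve(ms[::-1], default_scheme())["HH"][-1][1]
        assert fwd == rev

    def test_undated_smotifs_give_empty_curves(self):
        curves = saturation_curve([smotif_in_bin(0)], default_scheme())
        assert all(curve == [] for curve in curves.values())


class TestCategoryProfiles:
    def test_category_partition_boundaries(self):
        sizes = {"fa": 1, "fb": 2, "fc": 9, "fd": 10, "fe": 50, "ff": 99,
                 "fg": 100, "fh": 500}
        cats = categorize_folds(sizes)
        assert cats == {"fa": "1", "fb": "2-10", "fc": "2-10", "fd": "10-50",
                        "fe": "50-100", "ff": "50-100", "fg": ">100",
                        "fh": ">100"}

    def test_new_flag_overrides_size(self):
        cats = categorize_folds({"fa": 70}, new_folds={"fa"})
        assert cats == {"fa": "new"}

    def test_single_category_mass_sums_to_one(self):
        data = {"s1": [smotif_in_bin(BIN_A), smotif_in_bin(BIN_B)]}
        folds = {"s1": "f1"}
        lib = build_library(data, folds, default_scheme(), n_rounds=1, seed=0)
        prof = frequency_profile_by_category(folds, {"f1": 1}, data, lib)
        assert set(prof) == {"1"}
        assert prof["1"]["hist"].sum() == pytest.approx(1.0)

    def test_rare_only_category_sits_in_low_bins(self):
        # f_common dominates bin A; f_rare built solely from the rarest bin C
        data = {
            "s_common": [smotif_in_bin(BIN_A)] * 8 + [smotif_in_bin(BIN_B)] * 3,
            "s_rare": [smotif_in_bin(BIN_C)],
        }
        folds = {"s_common": "f_common", "s_rare": "f_rare"}
        lib = build_library(data, folds, default_scheme(), n_rounds=1, seed=0)
        prof = frequency_profile_by_category(
            folds, {"f_common": 120, "f_rare": 1}, data, lib,
            new_folds={"f_rare"}, n_hist_bins=8,
        )
        edges = prof["new"]["edges"]
        hist = prof["new"]["hist"]
        # all of the novel category's mass lies below the common fold's bins
        common_lowest = np.flatnonzero(prof[">100"]["hist"])[0]
        novel_highest = np.flatnonzero(hist)[-1]
        assert novel_highest <= common_lowest

    def test_novel_category_left_shifted_on_simulated_population(self):
        from smotifs.synthetic import PopulationSpec, simulate_population

        sample = simulate_population(PopulationSpec(n_known=80, n_novel=80, seed=31))
        counts = {}
        for s in sample.known.values():
            for b in s:
                counts[b] = counts.get(b, 0) + 1
        total = sum(counts.values())
        freqs = {b: c / total for b, c in counts.items()}
        known_f = [freqs.get(b, 0.0)
                   for s in sample.known.values() for b in s]
        novel_f = [freqs.get(b, 0.0)
                   for s in sample.novel.values() for b in s]
        stat, p = mannwhitneyu(novel_f, known_f, alternative="less")
        assert p < 1e-6
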