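"""Window construction, site assignment, outlier flagging and region merging."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_matrix
from sweepscan import scan
from sweepscan.model import GenotypeMatrix
from sweepscan.scan import ScanConfig


class TestMakeWindows:
    def test_100kb_chromosome(self):
        w = scan.make_windows({"chr1": 100_000})
        assert list(w["start"]) == [0, 25_000, 50_000, 75_000]
        assert list(w["end"]) == [50_000, 75_000, 100_000, 100_000]

    def test_50kb_chromosome(self):
        w = scan.make_windows({"chr1": 50_000})
        assert list(zip(w["start"], w["end"])) == [(0, 50_000), (25_000, 50_000)]

    def test_short_chromosome_single_window(self):
        w = scan.make_windows({"chr1": 10_000})
        assert list(zip(w["start"], w["end"])) == [(0, 10_000)]

    def test_ordering_deterministic(self):
        w = scan.make_windows({"chr2": 60_000, "chr1": 60_000})
        assert list(w["chrom"]) == ["chr1"] * 3 + ["chr2"] * 3

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ScanConfig(window_span=50_000, step=60_000)
        with pytest.raises(ValueError):
            ScanConfig(outlier_quantile=0.0)


def _matrix_at(positions, chrom="chr1", n_samples=4):
    n = len(positions)
    gt = np.ones((n, n_samples), dtype=np.int8)
    return GenotypeMatrix(
        [chrom] * n, positions, ["A"] * n, ["T"] * n,
        [f"s{i}" for i in range(n_samples)], gt,
    )


class TestAssignSites:
    def test_boundary_site_single_window(self):
        g = _matrix_at([25_000])
        w = scan.make_windows({"chr1": 100_000})
        member = scan.assign_sites(g, w)
        hits = [i for i, m in enumerate(member) if len(m)]
        assert hits == [0]  # only [0, 50k)

    def test_boundary_site_double_window(self):
        g = _matrix_at([25_001])
        w = scan.make_windows({"chr1": 100_000})
        member = scan.assign_sites(g, w)
        hits = [i for i, m in enumerate(member) if len(m)]
        assert hits == [0, 1]  # [0, 50k) and [25k, 75k)

    def test_unknown_chromosome_rejected(self):
        g = _matrix_at([100], chrom="chrX")
        w = scan.make_windows({"chr1": 100_000})
        with pytest.raises(ValueError, match="chrX"):
            scan.assign_sites(g, w)

    def test_matches_interval_membership_oracle(self, rng):
        g = random_matrix(rng, n_variants=200, n_chroms=2)
        cfg = ScanConfig(window_span=2_000, step=1_000, min_sites_per_window=1)
        w = scan.make_windows({"chr1": 10_000, "chr2": 10_000}, cfg)
        member = scan.assign_sites(g, w)
        for widx, row in enumerate(w.itertuples()):
            expected = {
                i
                for i in range(g.n_variants)
                if g.chrom[i] == row.chrom and row.start <= g.pos[i] - 1 < row.end
            }
            assert set(member[widx]) == expected
        # every interior site falls in exactly two half-overlapping windows
        counts = np.zeros(g.n_variants)
        for m in member:
            counts[m] += 1
        interior = (g.pos - 1 >= 1_000) & (g.pos - 1 < 9_000)
        assert np.all(counts[interior] == 2)


class TestQuantileThreshold:
    def test_enumerated_top_five_percent(self):
        values = np.arange(1, 101, dtype=float)
        cut = scan.quantile_threshold(values, 0.05)
        outliers = values[values >= cut]
        assert set(outliers) == {96, 97, 98, 99, 100}

    def test_degenerate_ties_all_kept(self):
        values = np.full(50, 7.0)
        cut = scan.quantile_threshold(values, 0.05)
        assert np.all(values >= cut)

    def test_continuous_fraction_bounds(self, rng):
        values = rng.random(1000)
        cut = scan.quantile_threshold(values, 0.05)
        frac = float(np.mean(values >= cut))
        assert 0.05 - 1 / 1000 <= frac <= 0.05 + 1 / 1000

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            scan.quantile_threshold([], 0.05)


def _window_frame(rng, n=400, n_sites=20):
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * n,
            "start": np.arange(n) * 25_000,
            "end": np.arange(n) * 25_000 + 50_000,
            "n_sites": np.full(n, n_sites),
            "pi_target": rng.random(n) * 1e-3,
            "pi_ref": rng.random(n) * 1e-3,
            "pi_ratio": np.ones(n),
            "diversity_score": rng.normal(3, 1, size=n),
            "fst": rng.normal(0.05, 0.02, size=n),
        }
    )


class TestFlagCandidates:
    def test_intersection_rule(self, rng):
        w = _window_frame(rng)
        w.loc[0, "fst"] = 10.0  # top F_ST, median diversity
        w.loc[0, "diversity_score"] = float(w["diversity_score"].median())
        out = scan.flag_candidates(w)
        assert bool(out.loc[0, "fst_outlier"])
        assert not bool(out.loc[0, "pi_outlier"])
        assert not bool(out.loc[0, "candidate"])

    def test_joint_outlier_is_candidate(self, rng):
        w = _window_frame(rng)
        w.loc[5, "fst"] = 10.0
        w.loc[5, "diversity_score"] = 50.0
        out = scan.flag_candidates(w)
        assert bool(out.loc[5, "candidate"])

    def test_candidate_subset_of_single_statistics(self, rng):
        out = scan.flag_candidates(_window_frame(rng))
        assert (out["candidate"] <= out["fst_outlier"]).all()
        assert (out["candidate"] <= out["pi_outlier"]).all()

    def test_sparse_windows_excluded(self, rng):
        w = _window_frame(rng)
        w.loc[3, "n_sites"] = 2  # below min_sites_per_window
        w.loc[3, "fst"] = 10.0
        w.loc[3, "diversity_score"] = 50.0
        out = scan.flag_candidates(w)
        assert not bool(out.loc[3, "fst_outlier"])
        assert not bool(out.loc[3, "candidate"])

    def test_undefined_fst_excluded(self, rng):
        w = _window_frame(rng)
        w.loc[7, "fst"] = np.nan
        out = scan.flag_candidates(w)
        assert not bool(out.loc[7, "fst_outlier"])


class TestMergeRegions:
    def _frame(self, rows):
        df = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "fst", "pi_target", "candidate"]
        )
        df["n_sites"] = 10
        return df

    def test_overlap_merged(self):
        w = self._frame(
            [
                ("chr1", 0, 50_000, 0.5, 1e-4, True),
                ("chr1", 25_000, 75_000, 0.4, 2e-4, True),
            ]
        )
        r = scan.merge_regions(w)
        assert len(r) == 1
        assert (r.loc[0, "start"], r.loc[0, "end"]) == (0, 75_000)
        assert r.loc[0, "max_fst"] == 0.5
        assert r.loc[0, "min_pi_target"] == 1e-4

    def test_chromosomes_never_merged(self):
        w = self._frame(
            [
                ("chr1", 0, 50_000, 0.5, 1e-4, True),
                ("chr2", 0, 50_000, 0.4, 1e-4, True),
            ]
        )
        assert len(scan.merge_regions(w)) == 2

    def test_matches_union_of_intervals_oracle(self, rng):
        n = 200
        flags = rng.random(n) < 0.1
        w = self._frame(
            [
                ("chr1", i * 25_000, i * 25_000 + 50_000, 0.1, 1e-4, bool(f))
                for i, f in enumerate(flags)
            ]
        )
        regions = scan.merge_regions(w)
        # brute-force union of flagged intervals over a base-pair grid
        covered = np.zeros(n * 25_000 + 50_000, dtype=bool)
        for i, f in enumerate(flags):
            if f:
                covered[i * 25_000 : i * 25_000 + 50_000] = True
        expected = []
        i = 0
        while i < len(covered):
            if covered[i]:
                j = i
                while j < len(covered) and covered[j]:
                    j += 1
                expected.append((i, j))
                i = j
            else:
                i += 1
        assert [(r.start, r.end) for r in regions.itertuples()] == expected


def test_scan_deterministic(rng, fixture_dir):
    from sweepscan import io

    g = io.filter_variants(io.read_vcf(fixture_dir["vcf"]))
    m = io.read_sample_map(fixture_dir["samples"])
    lengths = io.read_chrom_lengths(fixture_dir["chrom_lengths"])
    tgt, ref = io.pool_reference(m, "NJ")
    w1, r1 = scan.scan(g, tgt, ref, lengths)
    w2, r2 = scan.scan(g, tgt, ref, lengths)
    assert w1.to_csv() == w2.to_csv()
    assert r1.to_csv() == r2.to_csv()
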