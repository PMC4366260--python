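"""Merge coding conventions, allele census, call-count distribution, tallies."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_matrix, write_vcf
from suidcat import variant_store as vs
from suidcat._panel import MISSING


class TestMerge:
    def test_homref_record_codes_00_and_absence_codes_missing(self, tmp_path):
        a = write_vcf(tmp_path / "A.vcf", "A",
                      [{"pos": 100, "ref": "A", "alts": ("G",), "gt": (0, 1), "dp": 8}])
        b = write_vcf(tmp_path / "B.vcf", "B",
                      [{"pos": 100, "ref": "A", "alts": (), "gt": (0, 0), "dp": 9}])
        c = write_vcf(tmp_path / "C.vcf", "C", [])
        m = vs.merge_individual_vcfs([a, b, c], {"A": "g", "B": "g", "C": "g"})
        assert m.n_sites == 1
        assert list(m.gt[0, m.sample_index("A")]) == [0, 1]
        assert list(m.gt[0, m.sample_index("B")]) == [0, 0]
        assert list(m.gt[0, m.sample_index("C")]) == [MISSING, MISSING]

    @pytest.mark.parametrize(
        "record, reason",
        [
            ({"pos": 5, "ref": "A", "alts": ("G",), "gt": (0, 1), "dp": 4}, "raw depth"),
            ({"pos": 5, "ref": "A", "alts": ("G",), "gt": (0, 1), "dp": 6, "hqd": 4},
             "high-quality depth"),
            ({"pos": 5, "ref": "A", "alts": ("G",), "gt": (0, 1), "dp": 8, "gq": 10},
             "genotype quality"),
        ],
    )
    def test_filter_failures_become_missing(self, tmp_path, record, reason):
        a = write_vcf(tmp_path / "A.vcf", "A", [record])
        b = write_vcf(tmp_path / "B.vcf", "B",
                      [{"pos": 5, "ref": "A", "alts": ("G",), "gt": (1, 1), "dp": 10}])
        m = vs.merge_individual_vcfs([a, b], {"A": "g", "B": "g"})
        assert list(m.gt[0, m.sample_index("A")]) == [MISSING, MISSING], reason

    def test_max_depth_cutoff_is_twice_mean_plus_one(self, tmp_path):
        # sample A mean depth 8.8 -> cutoff 18.6; its DP=20 call must be dropped
        recs = [{"pos": p, "ref": "A", "alts": (), "gt": (0, 0), "dp": 5}
                for p in (10, 20, 30)]
        recs.append({"pos": 40, "ref": "C", "alts": ("T",), "gt": (0, 1), "dp": 9})
        recs.append({"pos": 50, "ref": "C", "alts": ("T",), "gt": (0, 1), "dp": 20})
        a = write_vcf(tmp_path / "A.vcf", "A", recs)  # mean = (5+5+5+9+20)/5 = 8.8
        # B keeps site 50 in the union with a passing variant call
        b = write_vcf(tmp_path / "B.vcf", "B",
                      [{"pos": 50, "ref": "C", "alts": ("T",), "gt": (1, 1), "dp": 10}])
        m = vs.merge_individual_vcfs([a, b], {"A": "g", "B": "g"})
        pos = list(m.sites["pos"])
        assert list(m.gt[pos.index(40), m.sample_index("A")]) == [0, 1]
        assert list(m.gt[pos.index(50), m.sample_index("A")]) == [MISSING, MISSING]

    def test_merge_never_invents_variant_calls(self, tmp_path):
        """A sample without a variant record at a union site is 0/0 or missing."""
        a = write_vcf(tmp_path / "A.vcf", "A",
                      [{"pos": 7, "ref": "T", "alts": ("C",), "gt": (1, 1), "dp": 12}])
        b = write_vcf(tmp_path / "B.vcf", "B",
                      [{"pos": 7, "ref": "T", "alts": (), "gt": (0, 0), "dp": 12},
                       {"pos": 9, "ref": "G", "alts": ("A",), "gt": (0, 1), "dp": 12}])
        m = vs.merge_individual_vcfs([a, b], {"A": "g", "B": "g"})
        for s in range(m.n_sites):
            g = m.gt[s, m.sample_index("A")]
            if int(m.sites.iloc[s]["pos"]) != 7:
                assert set(g) <= {0, MISSING}

    def test_multiallelic_union_keeps_unsplit_site(self, tmp_path):
        a = write_vcf(tmp_path / "A.vcf", "A",
                      [{"pos": 50, "ref": "A", "alts": ("G",), "gt": (1, 1), "dp": 10}])
        b = write_vcf(tmp_path / "B.vcf", "B",
                      [{"pos": 50, "ref": "A", "alts": ("T",), "gt": (1, 1), "dp": 10}])
        m = vs.merge_individual_vcfs([a, b], {"A": "g", "B": "g"})
        assert m.n_sites == 1
        assert m.sites.iloc[0]["alts"] == ("G", "T")
        assert list(m.gt[0, m.sample_index("A")]) == [1, 1]
        assert list(m.gt[0, m.sample_index("B")]) == [2, 2]

    def test_reference_mismatch_and_unknown_sample_rejected(self, tmp_path):
        a = write_vcf(tmp_path / "A.vcf", "A",
                      [{"pos": 5, "ref": "A", "alts": ("G",), "gt": (0, 1), "dp": 9}])
        b = write_vcf(tmp_path / "B.vcf", "B",
                      [{"pos": 5, "ref": "C", "alts": ("G",), "gt": (0, 1), "dp": 9}])
        with pytest.raises(ValueError, match="mismatch"):
            vs.merge_individual_vcfs([a, b], {"A": "g", "B": "g"})
        with pytest.raises(ValueError, match="group map"):
            vs.merge_individual_vcfs([a], {"Z": "g"})

    def test_all_homref_sites_dropped(self, tmp_path):
        a = write_vcf(tmp_path / "A.vcf", "A",
                      [{"pos": 5, "ref": "A", "alts": ("G",), "gt": (0, 1), "dp": 4},
                       {"pos": 8, "ref": "T", "alts": ("C",), "gt": (0, 1), "dp": 9}])
        b = write_vcf(tmp_path / "B.vcf", "B",
                      [{"pos": 5, "ref": "A", "alts": (), "gt": (0, 0), "dp": 9},
                       {"pos": 8, "ref": "T", "alts": (), "gt": (0, 0), "dp": 9}])
        m = vs.merge_individual_vcfs([a, b], {"A": "g", "B": "g"})
        # pos 5: A's variant call fails depth, B is 0/0 -> no variant observed
        assert list(m.sites["pos"]) == [8]


class TestAlleleCensus:
    @pytest.mark.parametrize(
        "n_alts, calls, expected",
        [
            (1, [(1, 1), (1, 1)], "AA"),
            (1, [(0, 0), (0, 1), (1, 1)], "RA"),
            (2, [(1, 1), (2, 2), (1, 2)], "A1A2"),
            (2, [(0, 1), (2, 2)], "triallelic"),
            (3, [(0, 1), (2, 3)], "quadallelic"),
            (1, [(0, 1), (MISSING, MISSING)], "RA"),
        ],
    )
    def test_classification(self, n_alts, calls, expected):
        assert vs.classify_allele_number(n_alts, np.array(calls)) == expected

    def test_degenerate_sites_rejected(self):
        with pytest.raises(ValueError):
            vs.classify_allele_number(1, np.array([(MISSING, MISSING)]))
        with pytest.raises(ValueError):
            vs.classify_allele_number(1, np.array([(0, 0)]))

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_census_classes_partition_sites(self, data):
        """Every site falls in exactly one class; counts sum to the total."""
        n_sites = data.draw(st.integers(2, 12))
        n_samples = data.draw(st.integers(2, 6))
        gt = np.zeros((n_sites, n_samples, 2), dtype=np.int8)
        sites = []
        for s in range(n_sites):
            n_alts = data.draw(st.integers(1, 3))
            col = data.draw(
                st.lists(
                    st.tuples(st.integers(0, n_alts), st.integers(0, n_alts)),
                    min_size=n_samples, max_size=n_samples,
                )
            )
            # ensure at least one non-ref call so the site is a variant
            col[0] = (n_alts, n_alts)
            gt[s] = [sorted(c) for c in col]
            sites.append(("1", s + 1, "A", tuple("CGT"[:n_alts])))
        m = build_matrix(sites, gt, [f"s{i}" for i in range(n_samples)],
                         {f"s{i}": "g" for i in range(n_samples)})
        result = vs.census(m)
        assert sum(result.counts.values()) == result.total == n_sites


class TestCallCounts:
    def test_histogram_and_missing_rates_on_small_matrix(self):
        gt = np.array([
            [(0, 1), (0, 0), (1, 1), (0, 1)],
            [(0, 1), (0, 0), (0, 1), (1, 1)],
            [(1, 1), (0, 1), (0, 0), (0, 1)],
            [(0, 1), (MISSING, MISSING), (MISSING, MISSING), (MISSING, MISSING)],
        ], dtype=np.int8)
        m = build_matrix(
            [("1", p, "A", ("G",)) for p in (1, 2, 3, 4)], gt,
            ["a", "b", "c", "d"], {s: "g" for s in "abcd"},
        )
        hist, cumulative, missing = vs.call_count_distribution(m)
        assert hist[4] == 3 and hist[1] == 1
        # "called in at least k samples" can only shrink as k grows
        assert (np.diff(cumulative.to_numpy()) <= 0).all()
        assert missing["a"] == 0.0
        assert missing["b"] == pytest.approx(0.25)

    def test_missing_rate_matches_binomial_dropout(self, rng):
        """Random per-sample dropout at rate p is recovered within 2 pp."""
        n_sites, p = 10_000, 0.3
        gt = np.tile(np.array([(0, 1)], dtype=np.int8), (n_sites, 3, 1))
        drop = rng.random((n_sites, 3)) < p
        gt[drop] = MISSING
        # keep every site a variant: force one called alt genotype
        gt[:, 0] = (1, 1)
        m = build_matrix(
            [("1", i + 1, "A", ("G",)) for i in range(n_sites)], gt,
            ["a", "b", "c"], {s: "g" for s in "abc"},
        )
        _, _, missing = vs.call_count_distribution(m)
        for s in ("b", "c"):
            assert missing[s] == pytest.approx(p, abs=0.02)


class TestConsequenceTally:
    def _matrix(self):
        gt = np.array([
            [(0, 1), (0, 0)],
            [(0, 0), (0, 1)],
            [(0, 1), (0, 2)],
        ], dtype=np.int8)
        return build_matrix(
            [("1", 10, "A", ("G",)), ("1", 20, "C", ("T",)), ("1", 30, "G", ("A", "C"))],
            gt, ["x", "y"], {"x": "P1", "y": "P2"},
        )

    def test_counts_per_group_and_deleterious(self):
        ann = pd.DataFrame({
            "chrom": ["1", "1", "1"],
            "pos": [10, 20, 10],
            "alt": ["G", "T", "G"],
            "consequence": ["missense_variant", "synonymous_variant",
                            "missense_variant"],
            "sift_score": [0.01, 0.2, np.nan],
        })
        out = vs.tally_consequences(ann, self._matrix())
        assert out["overall"]["missense_variant"] == 2
        assert out["deleterious"] == 1
        # only P1 carries the alt at pos 10; only P2 at pos 20
        assert out["per_group"]["P1"]["missense_variant"] == 2
        assert "missense_variant" not in out["per_group"]["P2"]
        assert out["per_group"]["P2"]["synonymous_variant"] == 1

    def test_multiallelic_alternatives_both_retained(self):
        ann = pd.DataFrame({
            "chrom": ["1", "1"], "pos": [30, 30], "alt": ["A", "C"],
            "consequence": ["missense_variant", "synonymous_variant"],
        })
        out = vs.tally_consequences(ann, self._matrix())
        assert out["overall"] == {"missense_variant": 1, "synonymous_variant": 1}
        # x carries alt 1 (A), y carries alt 2 (C)
        assert out["per_group"]["P1"] == {"missense_variant": 1}
        assert out["per_group"]["P2"] == {"synonymous_variant": 1}

    def test_unknown_term_warned_and_counted_as_other(self):
        ann = pd.DataFrame({
            "chrom": ["1"], "pos": [10], "alt": ["G"],
            "consequence": ["mystery_term"],
        })
        with pytest.warns(UserWarning, match="mystery_term"):
            out = vs.tally_consequences(ann, self._matrix())
        assert out["overall"] == {"other": 1}


class TestMergedVcfRoundTrip:
    def test_write_read_preserves_genotypes_and_missingness(self, tmp_path):
        gt = np.array([
            [(0, 1), (0, 0), (MISSING, MISSING)],
            [(1, 1), (MISSING, MISSING), (0, 0)],
        ], dtype=np.int8)
        m = build_matrix(
            [("1", 5, "A", ("G",)), ("1", 9, "C", ("T",))], gt,
            ["a", "b", "c"], {s: "g" for s in "abc"},
        )
        path = vs.write_merged_vcf(m, tmp_path / "merged.vcf", {"1": 100})
        back = vs.read_merged_vcf(path, m.groups)
        assert back.samples == m.samples
        assert np.array_equal(back.gt, m.gt)
        pd.testing.assert_frame_equal(back.sites, m.sites)
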