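"""Exclusive variants, Venn partition, joint SFS, extreme-frequency contrast."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from conftest import build_matrix
from suidcat import group_analysis as ga
from suidcat._panel import MISSING, PIG_GROUPS

GROUP_SIZES = {"EUWB": 3, "EUDM": 4, "ASWB": 4, "ASDM": 3}


def _polarized(rows):
    """Polarized table from (der_by_group, called_by_group[, site_class]) dicts."""
    out = []
    for i, r in enumerate(rows):
        rec = {"site": i, "chrom": "1", "pos": i + 1, "ref": "A", "alt": "G",
               "ancestral": "A", "derived": "G",
               "site_class": r.get("site_class", "RA")}
        for g in PIG_GROUPS:
            rec[f"der_{g}"] = r["der"].get(g, 0)
            rec[f"called_{g}"] = r["called"].get(g, GROUP_SIZES[g])
        out.append(rec)
    return pd.DataFrame(out)


def _random_polarized(rng, n_sites=300):
    rows = []
    for _ in range(n_sites):
        called = {g: int(rng.integers(0, GROUP_SIZES[g] + 1)) for g in PIG_GROUPS}
        der = {g: int(rng.integers(0, 2 * called[g] + 1)) for g in PIG_GROUPS}
        cls = "RA" if rng.random() > 0.1 else "AA"
        rows.append({"der": der, "called": called, "site_class": cls})
    return _polarized(rows)


class TestExclusiveVariants:
    def test_single_group_site_is_exclusive_segregating(self):
        pol = _polarized([{"der": {"ASWB": 3}, "called": {}}])
        res = ga.exclusive_variants(pol, GROUP_SIZES)
        per = res.per_group.set_index("group")
        assert per.loc["ASWB", "exclusive_segregating"] == 1
        assert per.loc["ASWB", "exclusive_fixed"] == 0
        assert res.venn.cell("ASWB") == 1

    def test_fixed_derived_absent_elsewhere_is_exclusive_fixed(self):
        pol = _polarized([{"der": {"EUWB": 6}, "called": {"EUWB": 3}}])
        res = ga.exclusive_variants(pol, GROUP_SIZES)
        per = res.per_group.set_index("group")
        assert per.loc["EUWB", "exclusive_fixed"] == 1
        assert per.loc["EUWB", "exclusive_segregating"] == 1

    def test_call_rate_filter_and_class_filter(self):
        rows = [
            {"der": {"ASWB": 1}, "called": {"EUWB": 1}},          # EUWB below 50%
            {"der": {"ASWB": 1}, "called": {}, "site_class": "AA"},
            {"der": {"ASWB": 1}, "called": {}},
        ]
        res = ga.exclusive_variants(_polarized(rows), GROUP_SIZES)
        assert res.n_eligible == 1

    def test_venn_matches_brute_force_subset_oracle(self, rng):
        pol = _random_polarized(rng, n_sites=600)
        res = ga.exclusive_variants(pol, GROUP_SIZES)

        # brute force: re-derive every cell with python sets
        cells = {frozenset(c): 0
                 for r in range(1, 5) for c in combinations(PIG_GROUPS, r)}
        eligible = with_derived = 0
        for _, row in pol.iterrows():
            if row["site_class"] != "RA":
                continue
            if any(row[f"called_{g}"] < 0.5 * GROUP_SIZES[g] for g in PIG_GROUPS):
                continue
            eligible += 1
            present = frozenset(g for g in PIG_GROUPS if row[f"der_{g}"] >= 1)
            if present:
                with_derived += 1
                cells[present] += 1
        assert res.n_eligible == eligible
        assert res.venn.total == with_derived
        for members, count in cells.items():
            assert res.venn.cell(*members) == count
        assert sum(res.venn.counts.values()) == res.venn.total

    def test_raising_call_rate_filter_never_adds_sites(self, rng):
        pol = _random_polarized(rng)
        counts = [
            ga.exclusive_variants(pol, GROUP_SIZES, min_called_frac=f).n_eligible
            for f in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ga.exclusive_variants(_polarized([]), {**GROUP_SIZES, "ASWB": 0})


class TestModalGroupSize:
    def _matrix(self, called_per_site, n=4):
        S = len(called_per_site)
        gt = np.full((S, n, 2), MISSING, dtype=np.int8)
        for s, k in enumerate(called_per_site):
            for j in range(k):
                gt[s, j] = (0, 1)
        samples = [f"s{i}" for i in range(n)]
        return build_matrix([("1", s + 1, "A", ("G",)) for s in range(S)], gt,
                            samples, {s: "grp" for s in samples})

    def test_modal_size_examples(self):
        assert ga.modal_group_size(self._matrix([3, 3, 2]), "grp") == 3
        assert ga.modal_group_size(self._matrix([4, 4, 4]), "grp") == 4

    def test_ties_break_toward_larger_size(self):
        assert ga.modal_group_size(self._matrix([2, 3, 2, 3]), "grp") == 3

    def test_histogram_cross_check(self, rng):
        counts = rng.integers(1, 5, size=50).tolist()
        m = self._matrix(counts)
        freq = {k: counts.count(k) for k in set(counts)}
        best = max(sorted(freq), key=lambda k: (freq[k], k))
        assert ga.modal_group_size(m, "grp") == best


class TestJointSFS:
    def test_single_site_spectrum(self):
        pol = _polarized([{"der": {"ASWB": 2}, "called": {"ASWB": 4, "EUWB": 3}}])
        spec = ga.joint_sfs(pol, "ASWB", "EUWB", n_a=4, n_b=3)
        assert spec.matrix.sum() == 1
        assert spec.matrix[2, 0] == 1
        assert spec.matrix[0, 0] == 0

    def test_swap_symmetry(self, rng):
        pol = _random_polarized(rng)
        ab = ga.joint_sfs(pol, "ASWB", "EUWB", n_a=3, n_b=2)
        ba = ga.joint_sfs(pol, "EUWB", "ASWB", n_a=2, n_b=3)
        assert np.array_equal(ab.matrix, ba.matrix.T)

    def test_marginals_equal_1d_sfs_exactly(self, rng):
        """Row/column sums reproduce the 1D spectra on the same site set."""
        pol = _random_polarized(rng, n_sites=500)
        na, nb = 3, 2
        spec = ga.joint_sfs(pol, "ASWB", "EUWB", n_a=na, n_b=nb)
        sel = (pol["called_ASWB"] == na) & (pol["called_EUWB"] == nb)
        da = pol.loc[sel, "der_ASWB"].to_numpy()
        db = pol.loc[sel, "der_EUWB"].to_numpy()
        keep = (da > 0) | (db > 0)
        sfs_a = np.bincount(da[keep], minlength=2 * na + 1)
        sfs_b = np.bincount(db[keep], minlength=2 * nb + 1)
        assert np.array_equal(spec.marginal("ASWB"), sfs_a)
        assert np.array_equal(spec.marginal("EUWB"), sfs_b)
        assert spec.matrix.sum() == keep.sum() == spec.n_sites

    def test_modal_sizes_inferred_from_table(self):
        rows = [{"der": {"ASWB": 1}, "called": {"ASWB": 4, "EUWB": 2}}] * 3
        rows += [{"der": {"ASWB": 1}, "called": {"ASWB": 3, "EUWB": 2}}]
        spec = ga.joint_sfs(_polarized(rows), "ASWB", "EUWB")
        assert (spec.n_a, spec.n_b) == (4, 2)

    def test_empty_selection_gives_zero_spectrum(self):
        pol = _polarized([{"der": {"ASWB": 1}, "called": {"ASWB": 4, "EUWB": 3}}])
        spec = ga.joint_sfs(pol, "ASWB", "EUWB", n_a=1, n_b=1)
        assert spec.matrix.sum() == 0 and spec.n_sites == 0


class TestDemographicSignature:
    def test_recent_split_correlates_deep_split_pushes_to_edges(self):
        """Within-continent pairs correlate; cross-continent mass sits at edges."""
        from suidcat import ancestral as anc
        from suidcat import pipeline_sim as ps
        from suidcat import synthetic_data as sd

        cfg = sd.SynthConfig(
            n_per_group={"EUWB": 6, "EUDM": 6, "ASWB": 6, "ASDM": 6},
            seq_length=60_000, theta=0.002, seed=21,
        )
        panel = sd.generate_truth_panel(cfg)
        dos = panel.genotypes().sum(axis=2)  # ancestral/derived dosage
        freq = {}
        for g in PIG_GROUPS:
            idx = panel.group_members(g)
            freq[g] = dos[:, idx].sum(axis=1) / (2 * idx.size)
        seg = (sum(freq.values()) > 0) & (sum(freq.values()) < 4)
        within = np.corrcoef(freq["EUWB"][seg], freq["EUDM"][seg])[0, 1]
        across = np.corrcoef(freq["ASWB"][seg], freq["EUWB"][seg])[0, 1]
        assert within > across
        assert within > 0.3


class TestExtremeFrequencyContrast:
    def test_extremeness_rule(self):
        res = ga.extreme_frequency_contrast(
            np.array([0.9, 0.5, 0.1]), np.array([0.1, 0.5, 0.9]),
            np.array([False, False, False]),
        )
        assert res.table[0, 0] == 2 and res.table[0, 1] == 1

    def test_odds_ratio_matches_cross_product_oracle(self):
        # target table: nonsyn (10 extreme, 20 not), syn (5 extreme, 40 not)
        fa = np.concatenate([
            np.full(10, 0.9), np.full(20, 0.5), np.full(5, 0.9), np.full(40, 0.5),
        ])
        fb = np.concatenate([
            np.full(10, 0.1), np.full(20, 0.5), np.full(5, 0.1), np.full(40, 0.5),
        ])
        syn = np.array([False] * 30 + [True] * 45)
        res = ga.extreme_frequency_contrast(fa, fb, syn)
        assert res.table.tolist() == [[10, 20], [5, 40]]
        assert res.odds_ratio == pytest.approx(4.0)
        assert not res.continuity_corrected
        assert 0.0 <= res.p_value <= 1.0

    def test_empty_cell_triggers_continuity_correction(self):
        res = ga.extreme_frequency_contrast(
            np.array([0.9, 0.5]), np.array([0.1, 0.5]), np.array([False, True]),
        )
        assert res.continuity_corrected
        assert np.isfinite(res.odds_ratio)
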