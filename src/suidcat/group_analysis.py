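"""Group-level allele sharing: exclusive variants, Venn partition, joint SFS.

All operations consume the polarized site table produced by
:func:`suidcat.ancestral.polarize` (per-group derived-allele and
called-sample counts).  A site is *eligible* for the sharing analyses when
it is a biallelic reference/alternative site and every group has at least
half of its members genotyped; it is *segregating* in a group when at least
one derived copy is observed there, and *exclusively fixed* when every
called chromosome of the target group is derived while no other group
carries the derived allele.

The joint site frequency spectrum between two groups is computed at the
modal group sizes — for each group, the called-sample count n at which the
largest number of SNPs was genotyped in exactly n individuals — which makes
counts comparable despite heterogeneous missingness.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._panel import PIG_GROUPS
from .variant_store import GenotypeMatrix

__all__ = [
    "GroupSpec",
    "VennPartition",
    "JointSFS",
    "exclusive_variants",
    "modal_group_size",
    "joint_sfs",
    "extreme_frequency_contrast",
    "ExclusiveVariantResult",
    "ContrastResult",
]


@dataclass(frozen=True)
class GroupSpec:
    """Disjoint sample groups with sizes."""

    membership: Mapping[str, str]       # sample -> group

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.membership.values()))

    def size(self, group: str) -> int:
        return sum(1 for g in self.membership.values() if g == group)

    def sizes(self) -> dict[str, int]:
        return {g: self.size(g) for g in self.labels}


@dataclass
class VennPartition:
    """Counts of eligible sites by the exact set of groups carrying the derived allele."""

    counts: dict[frozenset, int]
    groups: tuple[str, ...]
    total: int

    def cell(self, *groups: str) -> int:
        return self.counts.get(frozenset(groups), 0)

    def as_series(self) -> pd.Series:
        labels, values = [], []
        for r in range(1, len(self.groups) + 1):
            for combo in combinations(self.groups, r):
                labels.append("&".join(combo))
                values.append(self.cell(*combo))
        return pd.Series(values, index=labels, dtype=int)


@dataclass
class ExclusiveVariantResult:
    per_group: pd.DataFrame     # group, exclusive_segregating, exclusive_fixed
    venn: VennPartition
    n_eligible: int


def _eligibility(
    polarized: pd.DataFrame,
    groups: Sequence[str],
    group_sizes: Mapping[str, int],
    min_called_frac: float,
) -> pd.Series:
    elig = polarized["site_class"] == "RA"
    for g in groups:
        elig &= polarized[f"called_{g}"] >= min_called_frac * group_sizes[g]
    return elig


def exclusive_variants(
    polarized: pd.DataFrame,
    group_sizes: Mapping[str, int],
    groups: Sequence[str] = PIG_GROUPS,
    min_called_frac: float = 0.5,
) -> ExclusiveVariantResult:
    """Exclusive segregating/fixed counts per group and the full Venn partition.

    Parameters
    ----------
    polarized
        Polarized site table with ``der_<g>`` / ``called_<g>`` columns.
    group_sizes
        Number of individuals per group (denominator of the call-rate filter).
    min_called_frac
        Minimum fraction of each group's members genotyped for a site to be
        eligible (all groups must pass).
    """
    groups = tuple(groups)
    for g in groups:
        if group_sizes.get(g, 0) <= 0:
            raise ValueError(f"group {g} has no members")
    elig = _eligibility(polarized, groups, group_sizes, min_called_frac)
    sub = polarized[elig]

    der = np.column_stack([sub[f"der_{g}"].to_numpy() for g in groups])
    called = np.column_stack([sub[f"called_{g}"].to_numpy() for g in groups])
    present = der >= 1

    # Venn cells: one per nonempty subset of groups
    weights = 1 << np.arange(len(groups))
    codes = present @ weights
    counts: dict[frozenset, int] = {}
    binc = np.bincount(codes, minlength=1 << len(groups))
    for code in range(1, 1 << len(groups)):
        members = frozenset(g for i, g in enumerate(groups) if code >> i & 1)
        counts[members] = int(binc[code])
    total_with_derived = int(binc[1:].sum())
    venn = VennPartition(counts=counts, groups=groups, total=total_with_derived)

    rows = []
    for i, g in enumerate(groups):
        others = np.delete(present, i, axis=1).any(axis=1)
        excl_seg = int((present[:, i] & ~others).sum())
        fixed = (der[:, i] == 2 * called[:, i]) & (called[:, i] > 0)
        excl_fixed = int((fixed & ~others).sum())
        rows.append({"group": g, "exclusive_segregating": excl_seg,
                     "exclusive_fixed": excl_fixed})
    return ExclusiveVariantResult(
        per_group=pd.DataFrame(rows),
        venn=venn,
        n_eligible=int(elig.sum()),
    )


def modal_group_size(matrix: GenotypeMatrix, group: str) -> int:
    """The within-group called-sample count reached by the most sites.

    Ties are broken toward the larger count (better frequency resolution).
    Sites with no called member of the group do not vote.
    """
    members = matrix.group_members(group)
    if members.size == 0:
        raise ValueError(f"group {group!r} has no members")
    counts = matrix.called_mask()[:, members].sum(axis=1)
    hist = np.bincount(counts, minlength=members.size + 1)
    hist[0] = 0
    if hist.sum() == 0:
        raise ValueError(f"no site is called in any member of {group!r}")
    return int(len(hist) - 1 - np.argmax(hist[::-1]))


def _modal_from_table(polarized: pd.DataFrame, group: str) -> int:
    counts = polarized[f"called_{group}"].to_numpy()
    hist = np.bincount(counts)
    if len(hist) > 0:
        hist[0] = 0
    if hist.sum() == 0:
        raise ValueError(f"no polarized site is called in any member of {group!r}")
    return int(len(hist) - 1 - np.argmax(hist[::-1]))


@dataclass
class JointSFS:
    """2D histogram of derived-allele counts between two groups."""

    group_a: str
    group_b: str
    n_a: int                    # modal called-sample count of group A
    n_b: int
    matrix: np.ndarray          # (2*n_a + 1, 2*n_b + 1) int
    n_sites: int

    def marginal(self, which: str) -> np.ndarray:
        if which == self.group_a:
            return self.matrix.sum(axis=1)
        if which == self.group_b:
            return self.matrix.sum(axis=0)
        raise KeyError(which)


def joint_sfs(
    polarized: pd.DataFrame,
    group_a: str,
    group_b: str,
    n_a: int | None = None,
    n_b: int | None = None,
) -> JointSFS:
    """Joint SFS between two groups at their modal called-sample counts.

    Only sites genotyped in exactly the modal number of individuals in both
    groups enter; axes run from 0 to twice the modal count (fixed classes
    included) and the (0, 0) cell is empty by construction.  An empty
    eligible site set yields an all-zero spectrum.
    """
    if n_a is None:
        n_a = _modal_from_table(polarized, group_a)
    if n_b is None:
        n_b = _modal_from_table(polarized, group_b)
    sel = (
        (polarized[f"called_{group_a}"] == n_a)
        & (polarized[f"called_{group_b}"] == n_b)
    )
    da = polarized.loc[sel, f"der_{group_a}"].to_numpy()
    db = polarized.loc[sel, f"der_{group_b}"].to_numpy()
    keep = (da > 0) | (db > 0)
    da, db = da[keep], db[keep]
    mat = np.zeros((2 * n_a + 1, 2 * n_b + 1), dtype=np.int64)
    np.add.at(mat, (da, db), 1)
    return JointSFS(
        group_a=group_a, group_b=group_b, n_a=n_a, n_b=n_b,
        matrix=mat, n_sites=int(keep.sum()),
    )


@dataclass
class ContrastResult:
    """Synonymous vs non-synonymous contrast at extreme-frequency sites."""

    table: np.ndarray           # 2x2: rows (nonsyn, syn) x cols (extreme, other)
    odds_ratio: float
    p_value: float
    continuity_corrected: bool


def extreme_frequency_contrast(
    freq_a: np.ndarray,
    freq_b: np.ndarray,
    is_synonymous: np.ndarray,
    hi: float = 0.8,
    lo: float = 0.2,
) -> ContrastResult:
    """Association between annotation class and extreme frequency divergence.

    A site is *extreme* when one group's derived-allele frequency exceeds
    ``hi`` while the other's is below ``lo``.  Returns the 2x2 table of
    (non-synonymous, synonymous) x (extreme, not extreme), the cross-product
    odds ratio (Haldane 0.5 correction when a cell is empty, flagged) and the
    two-sided Fisher exact p-value.
    """
    freq_a = np.asarray(freq_a, dtype=float)
    freq_b = np.asarray(freq_b, dtype=float)
    syn = np.asarray(is_synonymous, dtype=bool)
    if not (freq_a.shape == freq_b.shape == syn.shape):
        raise ValueError("inputs must have identical shapes")
    extreme = ((freq_a > hi) & (freq_b < lo)) | ((freq_a < lo) & (freq_b > hi))
    table = np.array([
        [int((~syn & extreme).sum()), int((~syn & ~extreme).sum())],
        [int((syn & extreme).sum()), int((syn & ~extreme).sum())],
    ])
    corrected = bool((table == 0).any())
    t = table + 0.5 if corrected else table
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return ContrastResult(
        table=table, odds_ratio=float(odds), p_value=float(p),
        continuity_corrected=corrected,
    )
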