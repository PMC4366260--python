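"""Outgroup-based ancestral-allele inference and site polarization.

Eligible sites are mono- or biallelic with the reference among their alleles
(classes ``RA`` and ``AA``; at ``AA`` sites the unobserved reference base is
treated as the second allele).  Two rules are tried in strict order:

* **Rule A** — an allele supported by homozygous calls in at least two of the
  four *Sus* outgroup species, with no other *Sus* species homozygous for a
  different allele.  Heterozygous outgroup calls do not disqualify the site;
  they merely withdraw that species' support.
* **Rule B** — failing A, the warthog's allele if its call is homozygous.

If the winning allele is neither the reference nor the alternative allele of
the focal species (a third allele), or both rules fail, the ancestral state is
unknown.  Two *Sus* species homozygous for *different* alleles make rule A
undecidable; the site falls through to rule B and is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._panel import PIG_GROUPS, SUS_OUTGROUPS, WARTHOG
from .variant_store import GenotypeMatrix

__all__ = [
    "AncestralAssignment",
    "infer_ancestral",
    "assign_ancestral",
    "polarize",
    "ancestral_reference_fraction",
]


@dataclass(frozen=True)
class AncestralAssignment:
    """Outcome of the ancestral-allele rules at one site."""

    ancestral: str | None      # base letter, None = unknown
    is_reference: bool | None  # True if ancestral == reference allele
    rule: str                  # 'A', 'B' or 'none'
    conflict: bool = False     # rule-A conflict (two Sus alleles), fell to B


def _homozygous_allele(call: tuple[str, str] | None) -> str | None:
    if call is None:
        return None
    a, b = call
    return a if a == b else None


def infer_ancestral(
    ref: str,
    alt: str,
    sus_calls: Mapping[str, tuple[str, str] | None],
    warthog_call: tuple[str, str] | None,
) -> AncestralAssignment:
    """Apply the outgroup rules to one mono/biallelic site.

    Parameters
    ----------
    ref, alt
        The site's reference and alternative allele (base letters).  For
        monoallelic ``AA`` sites pass the reference base and the single
        observed alternative.
    sus_calls
        Genotype (pair of base letters) per *Sus* outgroup species; ``None``
        marks a missing call.
    warthog_call
        The warthog genotype, or ``None``.
    """
    # rule A: >= 2 Sus genomes called, homozygous, and mutually consistent
    hom_alleles = [
        a for a in (_homozygous_allele(c) for c in sus_calls.values())
        if a is not None
    ]
    conflict = False
    if hom_alleles:
        values, counts = np.unique(hom_alleles, return_counts=True)
        if len(values) > 1:
            conflict = True  # two Sus species fixed for different alleles
        elif counts[0] >= 2:
            anc = str(values[0])
            if anc in (ref, alt):
                return AncestralAssignment(anc, anc == ref, "A")
            return AncestralAssignment(None, None, "none")  # third allele
    # rule B: warthog homozygous
    anc = _homozygous_allele(warthog_call)
    if anc is not None:
        if anc in (ref, alt):
            return AncestralAssignment(anc, anc == ref, "B", conflict)
        return AncestralAssignment(None, None, "none", conflict)
    return AncestralAssignment(None, None, "none", conflict)


def _genotype_bases(
    matrix: GenotypeMatrix, site: int, sample_idx: int
) -> tuple[str, str] | None:
    g = matrix.gt[site, sample_idx]
    if g[0] < 0:
        return None
    alleles = matrix.site_alleles(site)
    return (alleles[g[0]], alleles[g[1]])


def assign_ancestral(
    matrix: GenotypeMatrix,
    sus_species: Sequence[str] = SUS_OUTGROUPS,
    warthog: str = WARTHOG,
) -> pd.DataFrame:
    """Infer the ancestral allele for every eligible site of a merged matrix.

    The matrix must include the outgroup individuals, labeled in
    ``matrix.groups`` by species name.  Sites that are not mono/biallelic
    with the reference among their alleles (``A1A2``, triallelic or
    quadallelic sites) are reported with rule ``'ineligible'``.

    Returns a data frame with one row per site: ``chrom, pos, ref, alt,
    ancestral, is_reference, rule, conflict``.
    """
    sus_cols = {}
    for sp in sus_species:
        members = matrix.group_members(sp)
        if members.size:
            sus_cols[sp] = int(members[0])
    wh_members = matrix.group_members(warthog)
    wh_col = int(wh_members[0]) if wh_members.size else None

    rows = []
    for s in range(matrix.n_sites):
        site = matrix.sites.iloc[s]
        alts = site["alts"]
        base = {
            "chrom": site["chrom"], "pos": site["pos"],
            "ref": site["ref"], "alt": alts[0] if alts else None,
        }
        if len(alts) != 1:
            rows.append({**base, "ancestral": None, "is_reference": None,
                         "rule": "ineligible", "conflict": False})
            continue
        sus_calls = {sp: _genotype_bases(matrix, s, c) for sp, c in sus_cols.items()}
        wh_call = None if wh_col is None else _genotype_bases(matrix, s, wh_col)
        a = infer_ancestral(site["ref"], alts[0], sus_calls, wh_call)
        rows.append({**base, "ancestral": a.ancestral, "is_reference": a.is_reference,
                     "rule": a.rule, "conflict": a.conflict})
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "ancestral", "is_reference",
                 "rule", "conflict"],
    )
    df.index.name = "site"
    return df


def polarize(
    matrix: GenotypeMatrix,
    assignments: pd.DataFrame,
    groups: Sequence[str] = PIG_GROUPS,
) -> pd.DataFrame:
    """Derived-allele counts per group at sites with a known ancestral state.

    Sites with unknown or ineligible ancestral assignment are excluded.  For
    each retained site the derived allele is the site allele that is not
    ancestral; counts are over non-missing genotypes of each group's samples
    only.

    Returns a frame with columns ``chrom, pos, ref, alt, ancestral, derived,
    site_class`` plus, per group ``g``, ``der_<g>`` (derived copies) and
    ``called_<g>`` (samples genotyped).
    """
    group_cols = {g: matrix.group_members(g) for g in groups}
    rows = []
    for s, a in assignments.iterrows():
        if a["rule"] in ("none", "ineligible") or a["ancestral"] is None:
            continue
        site = matrix.sites.iloc[s]
        anc_idx = 0 if a["ancestral"] == site["ref"] else 1
        der_idx = 1 - anc_idx
        derived = site["ref"] if der_idx == 0 else site["alts"][0]
        g_row = matrix.gt[s]
        ref_observed = np.any(g_row == 0)
        row = {
            "site": s, "chrom": site["chrom"], "pos": site["pos"],
            "ref": site["ref"], "alt": site["alts"][0],
            "ancestral": a["ancestral"], "derived": derived,
            "site_class": "RA" if ref_observed else "AA",
        }
        for g, cols in group_cols.items():
            sub = g_row[cols]
            called = sub[:, 0] >= 0
            row[f"der_{g}"] = int((sub[called] == der_idx).sum())
            row[f"called_{g}"] = int(called.sum())
        rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)


def ancestral_reference_fraction(
    assignments: pd.DataFrame,
) -> tuple[float, int, int]:
    """Fraction of assigned sites whose ancestral allele is the reference.

    Returns ``(fraction, n_reference_ancestral, n_assigned)``.
    """
    assigned = assignments[assignments["ancestral"].notna()]
    if len(assigned) == 0:
        raise ValueError("no site has an assigned ancestral allele")
    num = int(assigned["is_reference"].sum())
    return num / len(assigned), num, len(assigned)
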