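"""Multi-sample genotype matrix built from per-individual VCFs.

The merge reproduces the conventions of single-sample calling followed by a
custom merge step: the site list is the union of variant positions across
individuals; at each union position every individual is coded as

* its called genotype, when it has a variant record passing the depth and
  quality filters;
* ``0/0`` when the position is confidently callable non-variant in that
  individual (a reference record passing the same filters);
* ``./.`` (missing) otherwise.

Filters follow the minimum-depth-5 convention with a per-sample maximum depth
of twice the sample's mean depth plus one, and genotypes whose high-quality
read depth falls below the minimum are set missing even when raw depth passes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam

from ._panel import MISSING

__all__ = [
    "SiteCall",
    "GenotypeMatrix",
    "AlleleClassCensus",
    "merge_individual_vcfs",
    "classify_allele_number",
    "census",
    "call_count_distribution",
    "tally_consequences",
    "write_merged_vcf",
    "read_merged_vcf",
    "default_max_depth",
]

ALLELE_CLASSES = ("AA", "RA", "A1A2", "triallelic", "quadallelic")


def default_max_depth(mean_depth: float) -> float:
    """Per-sample maximum depth cutoff: twice the mean depth plus one."""
    return 2.0 * mean_depth + 1.0


class SiteCall(NamedTuple):
    """One sample's call at one site, after filtering."""

    genotype: tuple[int, int] | None   # allele indices, None = missing
    raw_depth: int
    hq_depth: int
    base_quality_ok: bool = True
    map_quality_ok: bool = True


@dataclass
class GenotypeMatrix:
    """Sites x samples genotype calls with group labels and depths.

    ``gt`` has shape ``(n_sites, n_samples, 2)`` holding allele indices into
    ``sites.ref``/``sites.alts`` (0 = reference); ``MISSING`` (-1) marks no
    confident call.  The ``'./.'`` vs ``'0/0'`` distinction of the merged VCF
    is therefore preserved exactly.
    """

    sites: pd.DataFrame          # columns: chrom, pos (1-based), ref, alts (tuple)
    gt: np.ndarray               # (S, n, 2) int8
    samples: list[str]
    groups: dict[str, str]
    depth: np.ndarray | None = None      # (S, n) raw depth, -1 unknown
    hq_depth: np.ndarray | None = None
    mean_depth: np.ndarray | None = None  # (n,)
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.shape[:2] != (len(self.sites), len(self.samples)):
            raise ValueError("gt shape does not match sites x samples")
        missing = set(self.samples) - set(self.groups)
        if missing:
            raise ValueError(f"samples absent from group map: {sorted(missing)}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def called_mask(self) -> np.ndarray:
        """(S, n) boolean, True where the genotype is non-missing."""
        return (self.gt >= 0).all(axis=2)

    def sample_index(self, name: str) -> int:
        return self.samples.index(name)

    def group_members(self, group: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if self.groups[s] == group],
            dtype=np.intp,
        )

    def call(self, site: int, sample: int) -> SiteCall:
        g = self.gt[site, sample]
        geno = None if g[0] < 0 else (int(g[0]), int(g[1]))
        dp = int(self.depth[site, sample]) if self.depth is not None else -1
        hq = int(self.hq_depth[site, sample]) if self.hq_depth is not None else dp
        return SiteCall(geno, dp, hq)

    def site_alleles(self, site: int) -> tuple[str, ...]:
        row = self.sites.iloc[site]
        return (row["ref"], *row["alts"])


@dataclass
class AlleleClassCensus:
    """Counts of variant positions by number/kind of alleles observed."""

    counts: dict[str, int]
    total: int

    def as_series(self) -> pd.Series:
        s = pd.Series({c: self.counts.get(c, 0) for c in ALLELE_CLASSES}, dtype=int)
        s["total"] = self.total
        return s


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def _read_sample_vcf(path: str | Path) -> tuple[str, dict, list[int], str]:
    """Read one single-sample VCF into {(chrom,pos): record-dict}."""
    vf = pysam.VariantFile(str(path))
    if len(vf.header.samples) != 1:
        raise ValueError(f"{path}: expected a single-sample VCF")
    sample = vf.header.samples[0]
    contig_order = list(vf.header.contigs)
    records: dict[tuple[str, int], dict] = {}
    depths: list[int] = []
    for rec in vf:
        sc = rec.samples[0]
        dp = sc.get("DP")
        dp = -1 if dp is None else int(dp)
        hq = sc.get("HQD")
        hq = dp if hq is None else int(hq)
        gq = sc.get("GQ")
        gq = None if gq is None else float(gq)
        gt = sc.get("GT")
        alts = tuple(a for a in (rec.alts or ()) if a not in (None, "."))
        records[(rec.chrom, rec.pos)] = {
            "ref": rec.ref,
            "alts": alts,
            "gt": gt,
            "dp": dp,
            "hq": hq,
            "gq": gq,
        }
        if dp >= 0:
            depths.append(dp)
    vf.close()
    return sample, records, depths, contig_order


def merge_individual_vcfs(
    vcf_paths: Sequence[str | Path],
    group_map: Mapping[str, str],
    min_depth: int = 5,
    max_depth_rule: Callable[[float], float] | None = None,
    min_quality: float = 20.0,
) -> GenotypeMatrix:
    """Merge per-individual VCFs into one genotype matrix.

    Parameters
    ----------
    vcf_paths
        Single-sample VCF files (plain text or bgzipped), one per individual.
        Reference (``ALT='.'``) records, when present, mark positions that are
        confidently callable non-variant in that individual.
    group_map
        Sample name -> group label; every sample must be present.
    min_depth
        Minimum raw and high-quality depth for a call to be kept.
    max_depth_rule
        Mean depth -> maximum depth cutoff; default ``2 * mean + 1``.
    min_quality
        Minimum genotype quality (GQ) when the field is present.
    """
    if max_depth_rule is None:
        max_depth_rule = default_max_depth

    per_sample: dict[str, dict] = {}
    mean_depths: dict[str, float] = {}
    contig_order: list[str] = []
    for path in vcf_paths:
        sample, records, depths, contigs = _read_sample_vcf(path)
        if sample in per_sample:
            raise ValueError(f"duplicate sample {sample!r}")
        if sample not in group_map:
            raise ValueError(f"sample {sample!r} absent from group map")
        per_sample[sample] = records
        mean_depths[sample] = float(np.mean(depths)) if depths else 0.0
        for c in contigs:
            if c not in contig_order:
                contig_order.append(c)

    samples = list(per_sample)

    # union of variant positions; check ref consistency
    union: dict[tuple[str, int], dict] = {}
    for sample, records in per_sample.items():
        for key, rec in records.items():
            if not rec["alts"]:
                continue
            entry = union.setdefault(key, {"ref": rec["ref"], "alts": set()})
            if entry["ref"] != rec["ref"]:
                raise ValueError(
                    f"reference allele mismatch at {key}: "
                    f"{entry['ref']!r} vs {rec['ref']!r} ({sample})"
                )
            entry["alts"].update(rec["alts"])

    contig_rank = {c: i for i, c in enumerate(contig_order)}
    keys = sorted(union, key=lambda k: (contig_rank.get(k[0], len(contig_rank)), k[1]))

    n_sites, n = len(keys), len(samples)
    gt = np.full((n_sites, n, 2), MISSING, dtype=np.int8)
    depth = np.full((n_sites, n), -1, dtype=np.int32)
    hq_depth = np.full((n_sites, n), -1, dtype=np.int32)
    site_rows = []

    for s, key in enumerate(keys):
        ref = union[key]["ref"]
        alts = tuple(sorted(union[key]["alts"]))  # deterministic allele order
        allele_index = {ref: 0, **{a: i + 1 for i, a in enumerate(alts)}}
        for j, sample in enumerate(samples):
            rec = per_sample[sample].get(key)
            if rec is None:
                continue
            depth[s, j] = rec["dp"]
            hq_depth[s, j] = rec["hq"]
            max_d = max_depth_rule(mean_depths[sample])
            passing = (
                rec["dp"] >= min_depth
                and rec["dp"] <= max_d
                and rec["hq"] >= min_depth
                and (rec["gq"] is None or rec["gq"] >= min_quality)
                and rec["gt"] is not None
                and None not in rec["gt"]
            )
            if not passing:
                continue
            local = (rec["ref"], *rec["alts"])
            try:
                mapped = tuple(allele_index[local[a]] for a in rec["gt"])
            except KeyError:
                continue  # genotype uses an allele not in the union (malformed)
            gt[s, j] = sorted(mapped)
        site_rows.append({"chrom": key[0], "pos": key[1], "ref": ref, "alts": alts})

    sites = pd.DataFrame(site_rows, columns=["chrom", "pos", "ref", "alts"])
    matrix = GenotypeMatrix(
        sites=sites,
        gt=gt,
        samples=samples,
        groups=dict(group_map),
        depth=depth,
        hq_depth=hq_depth,
        mean_depth=np.array([mean_depths[s] for s in samples]),
    )
    return _prune_unobserved(matrix)


def _prune_unobserved(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Drop alt alleles never observed in a passing call, and non-variant sites.

    Sites where every non-missing genotype is homozygous reference are not
    variants and are removed from the matrix (they would otherwise distort the
    census).
    """
    keep_sites = []
    new_rows = []
    gt = matrix.gt.copy()
    for s in range(matrix.n_sites):
        g = gt[s]
        called = g[g[:, 0] >= 0]
        observed = set(called.ravel().tolist())
        nonref = sorted(a for a in observed if a > 0)
        if not nonref:
            continue
        row = matrix.sites.iloc[s]
        alts = row["alts"]
        remap = {0: 0}
        new_alts = []
        for new_idx, old_idx in enumerate(nonref, start=1):
            remap[old_idx] = new_idx
            new_alts.append(alts[old_idx - 1])
        if len(new_alts) != len(alts):
            lut = np.full(len(alts) + 1, MISSING, dtype=np.int8)
            for old, new in remap.items():
                lut[old] = new
            mask = g[:, 0] >= 0
            g[mask] = lut[g[mask]]
            gt[s] = g
        keep_sites.append(s)
        new_rows.append(
            {"chrom": row["chrom"], "pos": row["pos"], "ref": row["ref"],
             "alts": tuple(new_alts)}
        )
    idx = np.array(keep_sites, dtype=np.intp)
    return GenotypeMatrix(
        sites=pd.DataFrame(new_rows, columns=["chrom", "pos", "ref", "alts"]),
        gt=gt[idx],
        samples=matrix.samples,
        groups=matrix.groups,
        depth=None if matrix.depth is None else matrix.depth[idx],
        hq_depth=None if matrix.hq_depth is None else matrix.hq_depth[idx],
        mean_depth=matrix.mean_depth,
    )


# ---------------------------------------------------------------------------
# census
# ---------------------------------------------------------------------------

def classify_allele_number(n_alts: int, calls: np.ndarray) -> str:
    """Classify a site by the alleles observed among non-missing genotypes.

    Classes: ``AA`` (one alternative allele only, reference never observed),
    ``RA`` (reference + one alt), ``A1A2`` (two alts, no reference),
    ``triallelic`` (three alleles observed), ``quadallelic`` (four).

    Parameters
    ----------
    n_alts
        Number of alternative alleles declared at the site.
    calls
        (n, 2) array of allele indices, MISSING allowed.
    """
    calls = np.asarray(calls)
    called = calls[calls[:, 0] >= 0]
    if called.size == 0:
        raise ValueError("site has no non-missing call")
    observed = set(int(a) for a in called.ravel())
    if max(observed, default=0) > n_alts:
        raise ValueError("genotype refers to an undeclared allele")
    ref_seen = 0 in observed
    n_alt_seen = len(observed - {0})
    if n_alt_seen == 0:
        raise ValueError("site has no observed alternative allele (not a variant)")
    n_obs = n_alt_seen + (1 if ref_seen else 0)
    if n_obs > 4:
        raise ValueError("more than four alleles observed")
    if n_obs == 1:
        return "AA"
    if n_obs == 2:
        return "RA" if ref_seen else "A1A2"
    return "triallelic" if n_obs == 3 else "quadallelic"


def census(matrix: GenotypeMatrix) -> AlleleClassCensus:
    """Tabulate the allele-number classes over all sites of the matrix."""
    counts: dict[str, int] = {c: 0 for c in ALLELE_CLASSES}
    for s in range(matrix.n_sites):
        cls = classify_allele_number(len(matrix.sites.iloc[s]["alts"]), matrix.gt[s])
        counts[cls] += 1
    return AlleleClassCensus(counts=counts, total=matrix.n_sites)


def call_count_distribution(
    matrix: GenotypeMatrix,
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Distribution of the number of samples genotyped per site.

    Returns
    -------
    histogram
        Site counts indexed by number of non-missing genotypes (0..n).
    cumulative
        Number of sites genotyped in at least k samples, indexed by k.
    missing_rate
        Per-sample fraction of sites with a missing genotype.
    """
    if matrix.n_sites == 0:
        raise ValueError("empty matrix")
    called = matrix.called_mask()
    per_site = called.sum(axis=1)
    hist = pd.Series(np.bincount(per_site, minlength=matrix.n_samples + 1))
    hist.index.name = "n_called"
    cumulative = hist[::-1].cumsum()[::-1]
    missing_rate = pd.Series(1.0 - called.mean(axis=0), index=matrix.samples)
    return hist, cumulative, missing_rate


# ---------------------------------------------------------------------------
# consequence tallies
# ---------------------------------------------------------------------------

KNOWN_CONSEQUENCES = frozenset({
    "splice_donor_variant", "splice_acceptor_variant", "stop_gained",
    "stop_lost", "initiator_codon_variant", "missense_variant",
    "splice_region_variant", "synonymous_variant", "stop_retained_variant",
    "intron_variant", "intergenic_variant", "upstream_gene_variant",
    "downstream_gene_variant", "5_prime_UTR_variant", "3_prime_UTR_variant",
    "non_coding_transcript_variant", "coding_sequence_variant",
})

DELETERIOUS_SIFT = 0.05


def tally_consequences(
    annotation: pd.DataFrame,
    matrix: GenotypeMatrix,
    groups: Iterable[str] | None = None,
) -> dict:
    """Count annotation consequences overall and per group.

    ``annotation`` must carry columns ``chrom, pos, alt, consequence`` and
    optionally ``sift_score``.  A group's counts are restricted to entries
    whose alternative allele is carried (>= 1 copy among non-missing
    genotypes) by at least one member of the group.  Multiallelic sites
    contribute one entry per annotated alternative.  Unknown consequence
    terms are counted under ``"other"`` with a warning.
    """
    required = {"chrom", "pos", "alt", "consequence"}
    if not required.issubset(annotation.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    if groups is None:
        groups = sorted(set(matrix.groups.values()))
    groups = list(groups)

    site_lookup = {
        (row["chrom"], row["pos"]): s for s, row in matrix.sites.iterrows()
    }
    group_cols = {g: matrix.group_members(g) for g in groups}

    unknown: set[str] = set()
    overall: dict[str, int] = {}
    per_group: dict[str, dict[str, int]] = {g: {} for g in groups}
    deleterious = 0
    per_group_deleterious = {g: 0 for g in groups}

    for _, row in annotation.iterrows():
        term = str(row["consequence"])
        if term not in KNOWN_CONSEQUENCES:
            unknown.add(term)
            term = "other"
        overall[term] = overall.get(term, 0) + 1
        score = row.get("sift_score", np.nan)
        is_del = pd.notna(score) and float(score) < DELETERIOUS_SIFT
        if is_del:
            deleterious += 1
        s = site_lookup.get((row["chrom"], row["pos"]))
        if s is None:
            continue
        site = matrix.sites.iloc[s]
        try:
            alt_idx = site["alts"].index(str(row["alt"])) + 1
        except ValueError:
            continue
        for g in groups:
            sub = matrix.gt[s, group_cols[g]]
            carried = np.any(sub == alt_idx)
            if carried:
                per_group[g][term] = per_group[g].get(term, 0) + 1
                if is_del:
                    per_group_deleterious[g] += 1

    if unknown:
        warnings.warn(
            f"unknown consequence terms counted as 'other': {sorted(unknown)}",
            stacklevel=2,
        )
    return {
        "overall": overall,
        "per_group": per_group,
        "deleterious": deleterious,
        "per_group_deleterious": per_group_deleterious,
    }


# ---------------------------------------------------------------------------
# merged VCF round trip
# ---------------------------------------------------------------------------

def _merged_header(matrix: GenotypeMatrix, contig_lengths: Mapping[str, int] | None):
    header = pysam.VariantHeader()
    contigs = dict.fromkeys(matrix.sites["chrom"])
    for c in contigs:
        length = None if contig_lengths is None else contig_lengths.get(c)
        if length:
            header.add_line(f"##contig=<ID={c},length={length}>")
        else:
            header.add_line(f"##contig=<ID={c}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">')
    for s in matrix.samples:
        header.add_sample(s)
    return header


def write_merged_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> Path:
    """Write the matrix as a multi-sample VCF preserving ``./.`` vs ``0/0``."""
    path = Path(path)
    header = _merged_header(matrix, contig_lengths)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for s in range(matrix.n_sites):
            row = matrix.sites.iloc[s]
            rec = out.new_record(
                contig=row["chrom"], start=row["pos"] - 1,
                alleles=(row["ref"], *row["alts"]),
            )
            for j, sample in enumerate(matrix.samples):
                g = matrix.gt[s, j]
                rec.samples[sample]["GT"] = (
                    (None, None) if g[0] < 0 else (int(g[0]), int(g[1]))
                )
                if matrix.depth is not None and matrix.depth[s, j] >= 0:
                    rec.samples[sample]["DP"] = int(matrix.depth[s, j])
            out.write(rec)
    return path


def read_merged_vcf(path: str | Path, group_map: Mapping[str, str]) -> GenotypeMatrix:
    """Read a multi-sample VCF written by :func:`write_merged_vcf`."""
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    absent = set(samples) - set(group_map)
    if absent:
        raise ValueError(f"samples absent from group map: {sorted(absent)}")
    rows, gts, depths = [], [], []
    for rec in vf:
        alts = tuple(a for a in (rec.alts or ()) if a not in (None, "."))
        rows.append({"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alts": alts})
        g = np.full((len(samples), 2), MISSING, dtype=np.int8)
        d = np.full(len(samples), -1, dtype=np.int32)
        for j, sample in enumerate(samples):
            sc = rec.samples[sample]
            gt = sc.get("GT")
            if gt is not None and None not in gt:
                g[j] = sorted(gt)
            dp = sc.get("DP")
            if dp is not None:
                d[j] = int(dp)
        gts.append(g)
        depths.append(d)
    vf.close()
    return GenotypeMatrix(
        sites=pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alts"]),
        gt=np.array(gts, dtype=np.int8).reshape(len(rows), len(samples), 2),
        samples=samples,
        groups=dict(group_map),
        depth=np.array(depths, dtype=np.int32).reshape(len(rows), len(samples)),
    )
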