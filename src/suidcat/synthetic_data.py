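"""Truth-labeled synthetic fixtures for the whole analysis stack.

Generates a reference sequence with controllable GC fraction and CpG
enrichment, gene and recombination tracks, a structured coalescent truth
panel for four pig groups (plus directly generated outgroup genotypes), and
serializes everything as FASTA / GFF3 / TSV / per-sample VCF so the readers
in :mod:`suidcat.variant_store` can round-trip it.

The sequence generator is a first-order Markov chain whose stationary base
composition equals the requested GC target while the C->G transition
probability is scaled by ``cpg_enrichment``; the realized CpG dinucleotide
count is therefore ``enrichment * freq(C) * freq(G) * (L - 1)`` in
expectation, against the product-of-frequencies baseline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from ._panel import (
    MISSING,
    OUTGROUP_SPECIES,
    PIG_GROUPS,
    SUS_OUTGROUPS,
    WARTHOG,
    TruthPanel,
)
from .pipeline_sim import DemographyModel, simulate_truth

__all__ = [
    "SynthConfig",
    "Reference",
    "TruthPanel",
    "generate_reference",
    "generate_truth_panel",
    "write_fixture_bundle",
]

BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SynthConfig:
    """Knobs of the synthetic study.

    Defaults emulate the study conditions: four groups of diploid pigs
    (down-scalable via ``n_per_group``), five outgroup individuals,
    ``theta = rho = 0.0005`` per bp, per-sample mean depths uniform in the
    3x-22x range, and a pig-like base composition (42% GC, CpG depleted to
    about a quarter of the iid expectation).
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"EUWB": 9, "EUDM": 55, "ASWB": 41, "ASDM": 23}
    )
    seq_length: int = 100_000
    theta: float = 0.0005
    rho: float = 0.0005
    gc_target: float = 0.42
    cpg_enrichment: float = 0.25
    n_genes: int = 20
    window_size: int = 1_000_000
    mean_depth_range: tuple[float, float] = (3.0, 22.0)
    missing_profile: dict[str, float] | None = None   # sample -> extra dropout prob
    min_depth: int = 5
    outgroup_mean_depth: float = 10.0
    outgroup_discordance: float = 0.0   # per-site prob an outgroup shows the derived allele
    outgroup_missing: float = 0.0       # per-site prob an outgroup call is absent
    kappa: float = 4.0                  # transition bias of derived-base choice (Ts/Tv = kappa/2)
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seq_length <= 0:
            raise ValueError("seq_length must be positive")
        if not (0.0 <= self.gc_target <= 1.0):
            raise ValueError(f"gc_target must lie in [0, 1], got {self.gc_target}")
        if self.cpg_enrichment < 0:
            raise ValueError("cpg_enrichment must be >= 0")
        unknown = set(self.n_per_group) - set(PIG_GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        pi = self._stationary()
        if self.cpg_enrichment * pi[2] > 1.0 or self.cpg_enrichment * pi[1] > 1.0:
            raise ValueError(
                "cpg_enrichment too large for the requested GC content"
            )

    def _stationary(self) -> np.ndarray:
        gc = self.gc_target
        return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    #: fixed registry of named substreams spawned from the single seed;
    #: the registry index is the spawn key, so each name always maps to the
    #: same independent stream no matter which subset is requested.
    _STREAMS = ("reference", "coalescent", "bases", "outgroups", "depths", "dropout")

    def rngs(self, *streams: str) -> dict[str, np.random.Generator]:
        """Named, independent substreams derived from the single seed."""
        out: dict[str, np.random.Generator] = {}
        for s in streams:
            key = self._STREAMS.index(s)
            out[s] = np.random.default_rng(
                np.random.SeedSequence(self.seed, spawn_key=(key,))
            )
        return out


@dataclass
class Reference:
    """Reference sequence plus gene and recombination-rate tracks."""

    seq: str
    genes: pd.DataFrame       # gene_id, start, end (0-based half-open)
    recmap: pd.DataFrame      # chrom, window_start, window_end, cm_per_mb
    chrom: str = "1"

    @property
    def length(self) -> int:
        return len(self.seq)


def _markov_sequence(
    length: int, pi: np.ndarray, enrichment: float, rng: np.random.Generator
) -> str:
    """Stationary-preserving chain with P(G | C) = enrichment * pi_G.

    Rows are built so every base keeps its marginal frequency: the G deficit
    (or excess) created from state C is redistributed over the other states
    proportionally to ``pi``.
    """
    pi = pi.astype(float)
    pi_g = pi[2]
    trans = np.zeros((4, 4))
    if pi_g < 1.0:
        g_from_c = enrichment * pi_g
        g_from_other = (
            pi_g * (1.0 - enrichment * pi[1]) / (1.0 - pi[1]) if pi[1] < 1.0 else pi_g
        )
        for s in range(4):
            g = g_from_c if s == 1 else g_from_other
            trans[s, 2] = g
            for b in (0, 1, 3):
                trans[s, b] = (1.0 - g) * pi[b] / (1.0 - pi_g)
    else:  # all-G degenerate composition
        trans[:, 2] = 1.0

    cum = np.cumsum(trans, axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int8)
    out[0] = state = int(np.searchsorted(np.cumsum(pi), u[0], side="right"))
    for i in range(1, length):
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        out[i] = state
    return "".join(BASES[out])


def generate_reference(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> Reference:
    """Reference sequence, non-overlapping gene intervals, recombination map."""
    if config.seq_length < 2000:
        raise ValueError("seq_length must be at least 2 kb")
    if rng is None:
        rng = config.rngs("reference")["reference"]
    seq = _markov_sequence(
        config.seq_length, config._stationary(), config.cpg_enrichment, rng
    )

    # genes: non-overlapping intervals occupying roughly a third of the sequence
    L, n_genes = config.seq_length, config.n_genes
    genes = pd.DataFrame(columns=["gene_id", "start", "end"])
    if n_genes > 0:
        mean_len = max(200, L // (3 * n_genes))
        lengths = np.clip(
            rng.poisson(mean_len, size=n_genes), 100, None
        )
        free = L - int(lengths.sum())
        if free <= n_genes:
            raise ValueError("n_genes too large for seq_length")
        gaps = rng.multinomial(free - n_genes, np.full(n_genes + 1, 1 / (n_genes + 1)))
        starts, cursor = [], 0
        for i in range(n_genes):
            cursor += gaps[i] + 1
            starts.append(cursor)
            cursor += int(lengths[i])
        genes = pd.DataFrame({
            "gene_id": [f"G{i + 1:04d}" for i in range(n_genes)],
            "start": starts,
            "end": [s + int(l) for s, l in zip(starts, lengths)],
        })

    # recombination map: positive, right-skewed rates (hence log-transformed later)
    edges = list(range(0, L, config.window_size)) + [L]
    edges = sorted(set(edges))
    rates = rng.lognormal(mean=0.0, sigma=0.7, size=len(edges) - 1)
    recmap = pd.DataFrame({
        "chrom": config.chrom,
        "window_start": edges[:-1],
        "window_end": edges[1:],
        "cm_per_mb": rates,
    })
    return Reference(seq=seq, genes=genes, recmap=recmap, chrom=config.chrom)


def generate_truth_panel(
    config: SynthConfig,
    demography: DemographyModel | None = None,
    reference: Reference | None = None,
) -> TruthPanel:
    """Simulate a truth panel with nucleotide states and outgroup genotypes.

    The coalescent stage reuses the structured pig demography (scaled to
    ``config.n_per_group``); ancestral bases are taken from the generated
    reference sequence and derived bases drawn with transition bias
    ``kappa``.  The assembly handed to downstream tools is the background
    sequence with the designated reference haplotype's alleles substituted,
    so at some sites the reference carries the derived allele.  Outgroup
    genotypes are generated directly: homozygous ancestral, flipped to
    homozygous derived with probability ``outgroup_discordance`` and dropped
    with probability ``outgroup_missing``.
    """
    for g, n in config.n_per_group.items():
        if n <= 0:
            raise ValueError(f"group {g} has no samples")
    rngs = config.rngs("reference", "coalescent", "bases", "outgroups")
    if reference is None:
        reference = generate_reference(config, rngs["reference"])

    if demography is None:
        labels = tuple(g for g in PIG_GROUPS if g in config.n_per_group)
        base = DemographyModel()
        demography = base.replace(
            labels=labels,
            sample_sizes={g: 2 * config.n_per_group[g] for g in labels},
            sizes={g: base.sizes[g] for g in labels},
            theta=config.theta,
            rho=config.rho,
            length=config.seq_length,
            reference_group="EUDM" if "EUDM" in labels else labels[0],
        )
    coal_seed = int(rngs["coalescent"].integers(1, 2**31 - 1))
    panel = simulate_truth(demography, seed=coal_seed, chrom=config.chrom)

    # nucleotide states: ancestral base from the background sequence,
    # derived base transition-biased (P(ts) = kappa / (kappa + 2))
    rng_b = rngs["bases"]
    seq = np.frombuffer(reference.seq.encode(), dtype="S1").astype("U1")
    anc = seq[panel.positions]
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    transversions = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    p_ts = config.kappa / (config.kappa + 2.0)
    der = np.empty(panel.n_sites, dtype="U1")
    u = rng_b.random(panel.n_sites)
    pick = rng_b.integers(0, 2, size=panel.n_sites)
    for s in range(panel.n_sites):
        a = str(anc[s])
        der[s] = transition[a] if u[s] < p_ts else transversions[a][pick[s]]
    panel.anc_base = anc
    panel.der_base = der

    # outgroups: direct generation, no outgroup coalescent
    rng_o = rngs["outgroups"]
    S = panel.n_sites
    for name in OUTGROUP_SPECIES:
        gt = np.zeros((S, 2), dtype=np.int8)
        flip = rng_o.random(S) < config.outgroup_discordance
        gt[flip] = 1
        miss = rng_o.random(S) < config.outgroup_missing
        gt[miss] = MISSING
        panel.outgroup_gt[name] = gt

    # assembly: background sequence with the reference haplotype's alleles
    assembly = seq.copy()
    assembly[panel.positions] = panel.ref_base()
    panel.reference_seq = "".join(assembly)
    panel.flags = {"reference": reference}  # type: ignore[attr-defined]
    return panel


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _vcf_header(chrom: str, length: int, sample: str) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    h.add_line(f"##contig=<ID={chrom},length={length}>")
    h.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    h.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">')
    h.add_line('##FORMAT=<ID=HQD,Number=1,Type=Integer,Description="High-quality read depth">')
    h.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    h.add_sample(sample)
    return h


def _write_sample_vcf(
    path: Path,
    sample: str,
    panel: TruthPanel,
    refspace_gt: np.ndarray,     # (S, 2) int8, -1 missing
    depths: np.ndarray,          # (S,) int
    keep: np.ndarray,            # (S,) bool: emit a record at this site
) -> None:
    header = _vcf_header(panel.chrom, panel.seq_length, sample)
    ref_b, alt_b = panel.ref_base(), panel.alt_base()
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for s in range(panel.n_sites):
            if not keep[s]:
                continue
            g = refspace_gt[s]
            is_variant = g.max() > 0
            # '.' ALT marks a confident homozygous-reference (non-variant) record
            alleles = (
                (str(ref_b[s]), str(alt_b[s])) if is_variant else (str(ref_b[s]), ".")
            )
            rec = out.new_record(
                contig=panel.chrom,
                start=int(panel.positions[s]),
                alleles=alleles,
            )
            rec.samples[sample]["GT"] = (int(g[0]), int(g[1]))
            rec.samples[sample]["DP"] = int(depths[s])
            rec.samples[sample]["HQD"] = int(depths[s])
            rec.samples[sample]["GQ"] = 99
            out.write(rec)


def write_fixture_bundle(
    panel: TruthPanel, config: SynthConfig, directory: str | Path
) -> dict[str, Path]:
    """Serialize a truth panel as a complete file bundle.

    Writes the reference FASTA, gene GFF3, recombination TSV, group map TSV,
    a merged truth table, and one VCF per individual (pigs and outgroups).
    Per-sample dropouts are simulated from the configured depth model: a
    site is absent from an individual's VCF when its simulated depth leaves
    ``[min_depth, 2*mean + 1]`` (or by the extra ``missing_profile``
    probability); otherwise a variant or confident-reference record is
    emitted.  No genotype errors are introduced, so a merge of the bundle
    reproduces the truth genotypes exactly under the dropout mask.
    """
    if panel.n_sites == 0:
        raise ValueError("panel has no variant sites")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vcf_dir = directory / "vcf"
    vcf_dir.mkdir(exist_ok=True)

    reference: Reference | None = getattr(panel, "flags", {}).get("reference")
    paths: dict[str, Path] = {}

    # FASTA
    fasta = directory / "reference.fa"
    seq = panel.reference_seq or "N" * panel.seq_length
    with open(fasta, "w") as fh:
        fh.write(f">{panel.chrom}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i:i + 60] + "\n")
    paths["reference"] = fasta

    # GFF3 + recombination map
    if reference is not None:
        gff = directory / "genes.gff3"
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for _, g in reference.genes.iterrows():
                fh.write(
                    f"{panel.chrom}\tsuidcat\tgene\t{g['start'] + 1}\t{g['end']}\t."
                    f"\t+\t.\tID={g['gene_id']}\n"
                )
        paths["genes"] = gff
        rec = directory / "recmap.tsv"
        reference.recmap.to_csv(rec, sep="\t", index=False)
        paths["recmap"] = rec

    # group map (outgroups labeled by species)
    groups = directory / "groups.tsv"
    rows = [{"sample": s, "group": panel.group_of[s]} for s in panel.samples]
    rows += [{"sample": sp, "group": sp} for sp in panel.outgroup_gt]
    pd.DataFrame(rows).to_csv(groups, sep="\t", index=False)
    paths["groups"] = groups

    # truth table
    truth_tsv = directory / "truth.tsv"
    dosage = panel.refspace_dosage()
    truth_df = pd.DataFrame({
        "chrom": panel.chrom,
        "pos": panel.positions + 1,
        "ref": panel.ref_base(),
        "alt": panel.alt_base(),
        "ancestral": panel.anc_base,
        "derived": panel.der_base,
    })
    for i, s in enumerate(panel.samples):
        truth_df[s] = dosage[:, i]
    truth_df.to_csv(truth_tsv, sep="\t", index=False)
    paths["truth"] = truth_tsv

    # per-sample VCFs with simulated dropouts
    rngs = config.rngs("depths", "dropout")
    rng_d, rng_m = rngs["depths"], rngs["dropout"]
    low, high = config.mean_depth_range
    refspace = panel.refspace_genotypes()
    S = panel.n_sites
    vcf_paths = []
    for i, sample in enumerate(panel.samples):
        mean_d = rng_d.uniform(low, high)
        depths = rng_d.poisson(mean_d, size=S)
        keep = (depths >= config.min_depth) & (depths <= 2 * mean_d + 1)
        extra = (config.missing_profile or {}).get(sample, 0.0)
        if extra > 0:
            keep &= rng_m.random(S) >= extra
        path = vcf_dir / f"{sample}.vcf"
        _write_sample_vcf(path, sample, panel, refspace[:, i], depths, keep)
        vcf_paths.append(path)

    flip = panel.ref_is_derived
    for sp, og in panel.outgroup_gt.items():
        depths = rng_d.poisson(config.outgroup_mean_depth, size=S)
        keep = (
            (og[:, 0] >= 0)
            & (depths >= config.min_depth)
            & (depths <= 2 * config.outgroup_mean_depth + 1)
        )
        og_ref = np.where(flip[:, None], 1 - og, og).astype(np.int8)
        og_ref[og < 0] = MISSING
        path = vcf_dir / f"{sp}.vcf"
        _write_sample_vcf(path, sp, panel, og_ref, depths, keep)
        vcf_paths.append(path)

    paths["vcf_dir"] = vcf_dir
    paths["vcfs"] = vcf_paths  # type: ignore[assignment]
    return paths
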