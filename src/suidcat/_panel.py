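"""Truth panel container shared by the simulator and the fixture generator.

A :class:`TruthPanel` stores the ground truth of a simulated resequencing
experiment: diploid haplotypes at segregating sites (coded as ancestral/derived
indicators), the designated reference haplotype, optional nucleotide states and
outgroup genotypes.  Downstream code evaluates variant calls against it or
serializes it into per-sample VCF fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: genotype code for "no confident call" in genotype arrays
MISSING = -1

PIG_GROUPS = ("EUWB", "EUDM", "ASWB", "ASDM")
SUS_OUTGROUPS = ("S.barbatus", "S.cebifrons", "S.verrucosus", "S.celebensis")
WARTHOG = "P.africanus"
OUTGROUP_SPECIES = SUS_OUTGROUPS + (WARTHOG,)


@dataclass
class TruthPanel:
    """Ground-truth genotypes at segregating sites of one simulated region.

    Haplotypes are stored site-major: ``haplotypes[s, 2*i]`` and
    ``haplotypes[s, 2*i + 1]`` are the two alleles of diploid sample ``i`` at
    site ``s``, coded 0 for the ancestral and 1 for the derived allele.
    Positions are 0-based internally; they are emitted 1-based in VCF.
    """

    positions: np.ndarray              # (S,) int, 0-based bp
    haplotypes: np.ndarray             # (S, 2n) uint8, 0 = ancestral / 1 = derived
    samples: list[str]
    group_of: dict[str, str]
    seq_length: int
    chrom: str = "1"
    ref_hap: int = 0                   # haplotype column used as the assembly
    anc_base: np.ndarray | None = None  # (S,) '<U1'
    der_base: np.ndarray | None = None
    outgroup_gt: dict[str, np.ndarray] = field(default_factory=dict)
    # (S, 2) int8 per outgroup sample, 0/1 in ancestral/derived coding, -1 missing
    reference_seq: str | None = None   # assembly-like sequence incl. ref-hap alleles

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a (sites, 2n) matrix")
        if self.haplotypes.shape[0] != self.positions.shape[0]:
            raise ValueError("positions and haplotypes disagree on site count")
        if self.haplotypes.shape[1] != 2 * len(self.samples):
            raise ValueError("haplotype columns must be 2 x samples")

    # -- basic shape -------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return int(self.positions.shape[0])

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def genotypes(self) -> np.ndarray:
        """Diploid genotypes, shape (S, n, 2), in ancestral(0)/derived(1) coding."""
        S, two_n = self.haplotypes.shape
        return self.haplotypes.reshape(S, two_n // 2, 2)

    # -- reference-space views --------------------------------------------
    @property
    def ref_is_derived(self) -> np.ndarray:
        """True where the designated reference haplotype carries the derived allele."""
        return self.haplotypes[:, self.ref_hap] == 1

    def refspace_genotypes(self) -> np.ndarray:
        """Genotypes recoded relative to the reference haplotype.

        0 = reference allele, 1 = alternative allele: at sites where the
        reference haplotype carries the derived allele the coding is flipped,
        exactly as when calling variants against that assembly.
        """
        gt = self.genotypes().astype(np.int8)
        flip = self.ref_is_derived[:, None, None]
        return np.where(flip, 1 - gt, gt)

    def refspace_dosage(self) -> np.ndarray:
        """Alternative-allele dosage per sample (S, n) in {0, 1, 2}."""
        return self.refspace_genotypes().sum(axis=2)

    def ref_base(self) -> np.ndarray:
        """Reference-assembly base at each site (requires nucleotide states)."""
        if self.anc_base is None or self.der_base is None:
            raise ValueError("panel carries no nucleotide states")
        return np.where(self.ref_is_derived, self.der_base, self.anc_base)

    def alt_base(self) -> np.ndarray:
        """The non-reference allele at each site."""
        if self.anc_base is None or self.der_base is None:
            raise ValueError("panel carries no nucleotide states")
        return np.where(self.ref_is_derived, self.anc_base, self.der_base)

    def sample_index(self, name: str) -> int:
        return self.samples.index(name)

    def group_members(self, group: str) -> np.ndarray:
        """Indices of the samples belonging to ``group``."""
        return np.array(
            [i for i, s in enumerate(self.samples) if self.group_of[s] == group],
            dtype=np.intp,
        )
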