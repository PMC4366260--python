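"""In-silico evaluation of the resequencing genotype-calling pipeline.

The evaluation has three stages, mirroring how a real multi-sample SNP
catalog is produced and audited:

1. **Truth** — a structured-coalescent simulation of 128 diploid pigs in four
   population groups (two continents, wild and domestic in each), under a
   demography translated from an ms/MaCS-style command: an old split between
   the Asian and European clades, recent wild/domestic splits within each
   continent, a pulse of migration from European domestics into Asian
   domestics, and ancestral size changes.  One European-domestic haplotype is
   designated the reference assembly, so "reference" and "ancestral" do not
   coincide at every site.
2. **Calling** — read-level sequencing is abstracted to a per-site, per-sample
   model: depth is drawn around the sample's mean (default means uniform in
   the 3x-22x range), reads sample the true alleles with a fixed per-base
   error rate (default 0.01, the Q20 bound), and a maximum-likelihood
   biallelic caller with a small variant prior and a phred-20 posterior-odds
   threshold emits ``0/0``, ``0/1``, ``1/1`` or missing.  Calls outside the
   depth window ``[5, 2*mean + 1]`` are missing.
3. **Scoring** — recovery / sensitivity / FDR at the genotype level (overall,
   by true genotype class and by group) and recovery / FDR at the SNP level,
   aggregated over replicates.

All coalescent quantities are expressed in ms units: time in ``4*N0``
generations, ``theta`` and ``rho`` scaled per base pair.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from ._panel import MISSING, PIG_GROUPS, TruthPanel
from .variant_store import GenotypeMatrix

__all__ = [
    "DemographyModel",
    "CallingModel",
    "SimMetrics",
    "EvaluationResult",
    "simulate_truth",
    "simulate_calling",
    "evaluate",
    "run_evaluation",
]

GENOTYPE_CLASSES = ("RR", "RA", "AA")


# ---------------------------------------------------------------------------
# demography
# ---------------------------------------------------------------------------

@dataclass
class DemographyModel:
    """Structured 4-population model in ms/MaCS scaling.

    ``sizes`` are population sizes relative to ``N0``; event times are in
    units of ``4*N0`` generations; migration rates are ``4*N0*m``.  The
    defaults encode the pig model::

        -I 4 18 110 82 46  -n 1 0.2 -n 2 0.5 -n 3 2.5 -n 4 3
        -em 0.049 2 4 5  -eM 0.06 0
        -ej 0.07 2 1  -ej 0.08 3 4
        -en 0.09 1 5  -en 0.2 1 7  -en 0.21 4 10
        -ej 10 1 4

    with populations 1..4 = EUWB, EUDM, ASWB, ASDM and ``theta = rho =
    0.0005`` per bp over 100 kb.
    """

    labels: tuple[str, ...] = PIG_GROUPS                  # EUWB, EUDM, ASWB, ASDM
    sample_sizes: dict[str, int] = field(
        default_factory=lambda: {"EUWB": 18, "EUDM": 110, "ASWB": 82, "ASDM": 46}
    )  # haploid
    sizes: dict[str, float] = field(
        default_factory=lambda: {"EUWB": 0.2, "EUDM": 0.5, "ASWB": 2.5, "ASDM": 3.0}
    )
    theta: float = 0.0005
    rho: float = 0.0005
    length: int = 100_000
    # (time, kind, args); kinds: migration(source,dest,rate),
    # migration_all(rate), join(source,dest), size(pop,size)
    events: tuple = (
        (0.049, "migration", ("EUDM", "ASDM", 5.0)),
        (0.06, "migration_all", (0.0,)),
        (0.07, "join", ("EUDM", "EUWB")),
        (0.08, "join", ("ASWB", "ASDM")),
        (0.09, "size", ("EUWB", 5.0)),
        (0.20, "size", ("EUWB", 7.0)),
        (0.21, "size", ("ASDM", 10.0)),
        (10.0, "join", ("EUWB", "ASDM")),
    )
    reference_group: str = "EUDM"   # group providing the reference haplotype

    def __post_init__(self) -> None:
        for label, n in self.sample_sizes.items():
            if n < 0 or n % 2:
                raise ValueError(f"haploid sample size of {label} must be even, got {n}")
        if any(t < 0 for t, _, _ in self.events):
            raise ValueError("event times must be non-negative")
        if self.theta < 0 or self.rho < 0 or self.length <= 0:
            raise ValueError("theta, rho must be >= 0 and length > 0")

    @classmethod
    def panmictic(
        cls,
        n_diploid: int,
        theta: float = 0.0005,
        rho: float = 0.0005,
        length: int = 100_000,
        label: str = "POP",
    ) -> "DemographyModel":
        """Single neutral population of constant size ``N0``."""
        return cls(
            labels=(label,),
            sample_sizes={label: 2 * n_diploid},
            sizes={label: 1.0},
            theta=theta,
            rho=rho,
            length=length,
            events=(),
            reference_group=label,
        )

    def replace(self, **kw) -> "DemographyModel":
        return dataclasses.replace(self, **kw)

    def to_msprime(self) -> msprime.Demography:
        """Translate to an msprime demography with time in ``4*N0`` units.

        A diploid deme of size ``x/4`` has pairwise coalescence rate
        ``2/x`` per time unit, matching a relative size ``x`` in ms scaling,
        so event times and scaled rates carry over numerically.
        """
        dem = msprime.Demography()
        for label in self.labels:
            dem.add_population(name=label, initial_size=self.sizes[label] / 4.0)
        for time, kind, args in sorted(self.events, key=lambda e: e[0]):
            if kind == "migration":
                source, dest, rate = args
                dem.add_migration_rate_change(
                    time=time, source=source, dest=dest, rate=rate
                )
            elif kind == "migration_all":
                dem.add_migration_rate_change(time=time, rate=args[0])
            elif kind == "join":
                source, dest = args
                dem.add_mass_migration(time=time, source=source, dest=dest, proportion=1.0)
            elif kind == "size":
                pop, size = args
                dem.add_population_parameters_change(
                    time=time, population=pop, initial_size=size / 4.0
                )
            else:
                raise ValueError(f"unknown event kind {kind!r}")
        return dem


def simulate_truth(
    demography: DemographyModel,
    seed: int,
    chrom: str = "1",
) -> TruthPanel:
    """Simulate diploid truth genotypes at segregating sites.

    Returns a :class:`TruthPanel` in ancestral/derived coding, with the first
    haplotype of the reference group designated as the assembly.  Sites that
    are monomorphic in the sample (possible under recurrent mutation) are
    dropped.
    """
    rng = np.random.default_rng(seed)
    anc_seed = int(rng.integers(1, 2**31 - 1))
    mut_seed = int(rng.integers(1, 2**31 - 1))

    dem = demography.to_msprime()
    samples = [
        msprime.SampleSet(demography.sample_sizes[g] // 2, population=g, ploidy=2)
        for g in demography.labels
        if demography.sample_sizes[g] > 0
    ]
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=demography.length,
        recombination_rate=demography.rho,
        discrete_genome=True,
        random_seed=anc_seed,
    )
    mts = msprime.sim_mutations(
        ts,
        rate=demography.theta,
        model=msprime.BinaryMutationModel(),
        random_seed=mut_seed,
    )

    positions, rows = [], []
    for var in mts.variants():
        alleles = var.alleles
        if "1" not in alleles:
            continue
        derived = np.asarray(var.genotypes) == alleles.index("1")
        n_der = int(derived.sum())
        if n_der == 0 or n_der == derived.size:
            continue
        positions.append(int(var.site.position))
        rows.append(derived.astype(np.uint8))

    sample_names: list[str] = []
    group_of: dict[str, str] = {}
    for g in demography.labels:
        for i in range(demography.sample_sizes[g] // 2):
            name = f"{g}_{i:03d}"
            sample_names.append(name)
            group_of[name] = g

    n_hap = 2 * len(sample_names)
    haps = (
        np.array(rows, dtype=np.uint8).reshape(len(rows), n_hap)
        if rows else np.zeros((0, n_hap), dtype=np.uint8)
    )
    ref_group_start = 0
    for g in demography.labels:
        if g == demography.reference_group:
            break
        ref_group_start += demography.sample_sizes[g]
    return TruthPanel(
        positions=np.array(positions, dtype=np.int64),
        haplotypes=haps,
        samples=sample_names,
        group_of=group_of,
        seq_length=demography.length,
        chrom=chrom,
        ref_hap=ref_group_start,
    )


# ---------------------------------------------------------------------------
# calling model
# ---------------------------------------------------------------------------

@dataclass
class CallingModel:
    """Per-site depth/error/genotyping model standing in for read-level steps.

    The caller compares binomial likelihoods of ``0/0``, ``0/1`` and ``1/1``
    given the observed ref/alt read counts.  A variant genotype is emitted
    when its posterior odds against ``0/0`` — with prior ``variant_prior`` on
    a site being variant in an individual — exceed ``min_variant_odds``
    (100 = phred 20, consistent with the pipeline's quality-20 conventions);
    a confident ``0/0`` requires those odds to fall below 1; anything between
    is missing, as are calls outside ``[min_depth, 2*mean_depth + 1]``.
    Sequencing errors hit each of the three non-true bases equally, so only
    same-base error pileups can mimic an alternative allele.
    """

    mean_depth_range: tuple[float, float] = (3.0, 22.0)
    mean_depths: np.ndarray | None = None      # per-sample means, overrides range
    depth_distribution: str = "poisson"        # 'poisson' or 'fixed'
    error_rate: float = 0.01
    min_depth: int = 5
    variant_prior: float = 1e-3
    min_variant_odds: float = 100.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.depth_distribution not in ("poisson", "fixed"):
            raise ValueError("depth_distribution must be 'poisson' or 'fixed'")
        if self.mean_depths is not None:
            self.mean_depths = np.asarray(self.mean_depths, dtype=float)

    def draw_mean_depths(self, n_samples: int, rng: np.random.Generator) -> np.ndarray:
        if self.mean_depths is not None:
            if len(self.mean_depths) != n_samples:
                raise ValueError("mean_depths length does not match sample count")
            return self.mean_depths
        low, high = self.mean_depth_range
        return rng.uniform(low, high, size=n_samples)

    def max_depth(self, mean_depth: np.ndarray) -> np.ndarray:
        return 2.0 * np.asarray(mean_depth) + 1.0


def _genotype_loglik(k: np.ndarray, r: np.ndarray, error_rate: float):
    """Log-likelihoods (lRR, lRA, lAA) given alt reads ``k`` and ref reads ``r``."""
    n = k + r
    with np.errstate(divide="ignore"):
        log_eb = np.log(error_rate / 3.0) if error_rate > 0 else -np.inf
        log_1me = np.log1p(-error_rate / 3.0)
    kk = k.astype(float)
    rr = r.astype(float)
    with np.errstate(invalid="ignore"):  # 0 * -inf handled by the where masks
        l_rr = np.where(kk > 0, kk * log_eb, 0.0) + rr * log_1me
        l_aa = np.where(rr > 0, rr * log_eb, 0.0) + kk * log_1me
    l_ra = n * np.log(0.5)
    return l_rr, l_ra, l_aa


def _call_from_reads(
    k: np.ndarray, r: np.ndarray, model: CallingModel
) -> np.ndarray:
    """Genotype decision per entry: -1 missing, 0 RR, 1 RA, 2 AA.

    Depth-window filtering is applied by the caller of this function.
    """
    l_rr, l_ra, l_aa = _genotype_loglik(k, r, model.error_rate)
    l_var = np.maximum(l_ra, l_aa)
    log_prior_odds = np.log(model.variant_prior) - np.log1p(-model.variant_prior)
    odds = l_var + log_prior_odds - l_rr
    out = np.full(k.shape, MISSING, dtype=np.int8)
    is_var = odds >= np.log(model.min_variant_odds)
    out[is_var] = np.where(l_ra[is_var] >= l_aa[is_var], 1, 2)
    out[(~is_var) & (odds <= 0.0)] = 0
    return out


def simulate_calling(
    truth: TruthPanel,
    model: CallingModel,
    seed: int,
    include_invariant: bool = True,
) -> GenotypeMatrix:
    """Push truth genotypes through the depth/error/calling model.

    Returns a genotype matrix in reference space covering every truth site
    (rows may be variant-free when no sample reached a confident variant
    call) plus any invariant position where sequencing errors produced a
    spurious variant call.  ``matrix.flags['false_positive_pos']`` lists
    those spurious positions;  ``flags['truth_pos']`` the truth positions.
    """
    rng = np.random.default_rng(seed)
    n = truth.n_samples
    S = truth.n_sites
    means = model.draw_mean_depths(n, rng)
    max_d = model.max_depth(means)
    e = model.error_rate

    # --- truth sites -----------------------------------------------------
    dosage = truth.refspace_dosage()                    # (S, n) in {0,1,2}
    if model.depth_distribution == "fixed":
        D = np.broadcast_to(np.round(means).astype(np.int64), (S, n)).copy()
    else:
        D = rng.poisson(np.broadcast_to(means, (S, n)))
    p_alt = dosage / 2.0
    t_alt = rng.binomial(D, p_alt)
    t_ref = D - t_alt
    if e > 0:
        obs_ref = rng.binomial(t_ref, 1.0 - e) + rng.binomial(t_alt, e / 3.0)
        obs_alt = rng.binomial(t_alt, 1.0 - e) + rng.binomial(t_ref, e / 3.0)
    else:
        obs_ref, obs_alt = t_ref, t_alt
    calls = _call_from_reads(obs_alt, obs_ref, model)
    depth_ok = (D >= model.min_depth) & (D <= max_d[None, :])
    calls = np.where(depth_ok, calls, MISSING).astype(np.int8)
    truth_depth = D.astype(np.int32)

    # --- invariant sites: spurious variants from same-base error pileups --
    fp_pos: list[int] = []
    fp_calls: dict[int, np.ndarray] = {}
    if include_invariant and e > 0:
        truth_set = set(int(p) for p in truth.positions)
        inv_pos = np.array(
            [p for p in range(truth.seq_length) if p not in truth_set],
            dtype=np.int64,
        )
        n_inv = inv_pos.size
        for j in range(n):
            m = rng.poisson(means[j] * e, size=n_inv)
            cand = np.nonzero(m >= 3)[0]     # a variant call needs >=3 agreeing reads
            if cand.size == 0:
                continue
            mc = m[cand]
            rest = rng.poisson(means[j] * (1.0 - e), size=cand.size)
            Dc = mc + rest
            # split the error reads over the three non-reference bases
            b1 = rng.binomial(mc, 1.0 / 3.0)
            b2 = rng.binomial(mc - b1, 0.5)
            kmax = np.maximum(np.maximum(b1, b2), mc - b1 - b2)
            rrds = Dc - mc                   # non-error reads support the reference
            call = _call_from_reads(kmax, rrds, model)
            ok = (Dc >= model.min_depth) & (Dc <= max_d[j]) & (call > 0)
            for idx, c in zip(cand[ok], call[ok]):
                pos = int(inv_pos[idx])
                if pos not in fp_calls:
                    fp_calls[pos] = np.full(n, MISSING, dtype=np.int8)
                    fp_pos.append(pos)
                fp_calls[pos][j] = c

    # --- assemble matrix --------------------------------------------------
    has_bases = truth.anc_base is not None
    ref_bases = truth.ref_base() if has_bases else np.full(S, "A")
    alt_bases = truth.alt_base() if has_bases else np.full(S, "C")

    order = np.argsort(truth.positions, kind="stable")
    rows, gts, depths = [], [], []
    fp_sorted = sorted(fp_pos)
    fp_iter = iter(fp_sorted + [None])
    next_fp = next(fp_iter)

    def _push_fp(limit: int | None) -> None:
        nonlocal next_fp
        while next_fp is not None and (limit is None or next_fp < limit):
            rows.append({"chrom": truth.chrom, "pos": next_fp + 1,
                         "ref": "N", "alts": ("N",)})
            gts.append(fp_calls[next_fp])
            depths.append(np.full(n, -1, dtype=np.int32))
            next_fp = next(fp_iter)

    for s in order:
        _push_fp(int(truth.positions[s]))
        rows.append({
            "chrom": truth.chrom, "pos": int(truth.positions[s]) + 1,
            "ref": str(ref_bases[s]), "alts": (str(alt_bases[s]),),
        })
        gts.append(calls[s])
        depths.append(truth_depth[s])
    _push_fp(None)

    code_to_gt = np.array(
        [[MISSING, MISSING], [0, 0], [0, 1], [1, 1]], dtype=np.int8
    )
    gt_codes = np.array(gts, dtype=np.int8).reshape(len(rows), n)
    gt = code_to_gt[gt_codes + 1]
    matrix = GenotypeMatrix(
        sites=pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alts"]),
        gt=gt,
        samples=list(truth.samples),
        groups=dict(truth.group_of),
        depth=np.array(depths, dtype=np.int32).reshape(len(rows), n),
        mean_depth=np.asarray(means, dtype=float),
    )
    matrix.flags["false_positive_pos"] = fp_sorted
    matrix.flags["truth_pos"] = [int(p) for p in truth.positions]
    return matrix


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class SimMetrics:
    """Truth-vs-called accuracy, all rates as fractions in [0, 1].

    Genotype-level definitions: *recovery* divides correct calls by all true
    genotypes (uncalled ones count against it); *sensitivity* divides by
    non-missing calls of the same true class; *FDR* is the fraction of
    emitted calls of a class whose truth differs.  SNP-level: *recovery* is
    the fraction of truly segregating sites with a variant call in at least
    one sample, *FDR* the fraction of variant-called sites that are not truly
    segregating.
    """

    genotype_recovery: float
    genotype_sensitivity: float
    genotype_fdr: float
    genotype_recovery_by_class: dict[str, float]
    genotype_sensitivity_by_class: dict[str, float]
    genotype_fdr_by_class: dict[str, float]
    genotype_recovery_by_group: dict[str, float]
    snp_recovery: float
    snp_fdr: float
    snp_recovery_by_group: dict[str, float]
    n_true_snps: int
    n_called_snps: int
    n_false_snps: int
    no_calls: bool = False   # flagged when no genotype call was emitted at all

    def as_series(self) -> pd.Series:
        d: dict[str, float] = {
            "genotype_recovery": self.genotype_recovery,
            "genotype_sensitivity": self.genotype_sensitivity,
            "genotype_fdr": self.genotype_fdr,
            "snp_recovery": self.snp_recovery,
            "snp_fdr": self.snp_fdr,
            "n_true_snps": self.n_true_snps,
            "n_called_snps": self.n_called_snps,
            "n_false_snps": self.n_false_snps,
        }
        for c in GENOTYPE_CLASSES:
            d[f"genotype_recovery_{c}"] = self.genotype_recovery_by_class.get(c, np.nan)
            d[f"genotype_sensitivity_{c}"] = self.genotype_sensitivity_by_class.get(c, np.nan)
            d[f"genotype_fdr_{c}"] = self.genotype_fdr_by_class.get(c, np.nan)
        for g, v in self.snp_recovery_by_group.items():
            d[f"snp_recovery_{g}"] = v
        for g, v in self.genotype_recovery_by_group.items():
            d[f"genotype_recovery_{g}"] = v
        return pd.Series(d)


def _safe_div(num: float, den: float) -> float:
    return float(num) / float(den) if den else float("nan")


def evaluate(
    truth: TruthPanel,
    called: GenotypeMatrix,
    groups: tuple[str, ...] | None = None,
) -> SimMetrics:
    """Score a called matrix against its truth panel.

    Genotype-level metrics are computed over the truth's segregating sites;
    SNP-level FDR additionally uses variant calls at positions absent from
    the truth (sequencing-error artifacts).
    """
    if truth.samples != called.samples:
        raise ValueError("truth and called matrices have different samples")
    if groups is None:
        groups = tuple(dict.fromkeys(truth.group_of[s] for s in truth.samples))

    pos_to_row = {int(p): i for i, p in enumerate(called.sites["pos"])}
    truth_rows = []
    for p in truth.positions:
        row = pos_to_row.get(int(p) + 1)
        if row is None:
            raise ValueError("called matrix does not cover all truth sites")
        truth_rows.append(row)
    truth_rows = np.array(truth_rows, dtype=np.intp)

    true_dos = truth.refspace_dosage()                       # (S, n)
    called_gt = called.gt[truth_rows]                         # (S, n, 2)
    is_called = (called_gt >= 0).all(axis=2)
    called_dos = np.where(is_called, called_gt.sum(axis=2), MISSING)

    correct = is_called & (called_dos == true_dos)
    total = true_dos.size
    n_called = int(is_called.sum())

    by_class_rec, by_class_sens, by_class_fdr = {}, {}, {}
    for c, name in enumerate(GENOTYPE_CLASSES):
        tmask = true_dos == c
        cmask = called_dos == c
        by_class_rec[name] = _safe_div((tmask & correct).sum(), tmask.sum())
        by_class_sens[name] = _safe_div((tmask & correct).sum(), (tmask & is_called).sum())
        by_class_fdr[name] = _safe_div((cmask & ~correct).sum(), cmask.sum())

    member_idx = {g: truth.group_members(g) for g in groups}
    by_group_rec = {
        g: _safe_div(correct[:, idx].sum(), correct[:, idx].size)
        for g, idx in member_idx.items()
    }

    # SNP level
    variant_call = is_called & (called_dos > 0)
    detected = variant_call.any(axis=1)
    n_true = truth.n_sites
    n_detected = int(detected.sum())

    fp_rows = np.setdiff1d(
        np.arange(called.n_sites), truth_rows, assume_unique=False
    )
    fp_variant = 0
    if fp_rows.size:
        fp_gt = called.gt[fp_rows]
        fp_called = (fp_gt >= 0).all(axis=2)
        fp_variant = int((fp_called & (fp_gt.sum(axis=2) > 0)).any(axis=1).sum())

    n_called_snps = n_detected + fp_variant
    snp_by_group = {}
    for g, idx in member_idx.items():
        if idx.size == 0:
            snp_by_group[g] = float("nan")
            continue
        true_g = (true_dos[:, idx] > 0).any(axis=1)
        det_g = variant_call[:, idx].any(axis=1)
        snp_by_group[g] = _safe_div((true_g & det_g).sum(), true_g.sum())

    return SimMetrics(
        genotype_recovery=_safe_div(correct.sum(), total),
        genotype_sensitivity=_safe_div(correct.sum(), n_called),
        genotype_fdr=(
            _safe_div((is_called & ~correct).sum(), n_called) if n_called else 0.0
        ),
        genotype_recovery_by_class=by_class_rec,
        genotype_sensitivity_by_class=by_class_sens,
        genotype_fdr_by_class=by_class_fdr,
        genotype_recovery_by_group=by_group_rec,
        snp_recovery=_safe_div(n_detected, n_true),
        snp_fdr=_safe_div(fp_variant, n_called_snps) if n_called_snps else 0.0,
        snp_recovery_by_group=snp_by_group,
        n_true_snps=n_true,
        n_called_snps=n_called_snps,
        n_false_snps=fp_variant,
        no_calls=n_called == 0,
    )


@dataclass
class EvaluationResult:
    """Replicate-level and aggregated pipeline-accuracy metrics."""

    per_replicate: pd.DataFrame
    mean: pd.Series
    sd: pd.Series
    n_replicates: int
    mean_depths: np.ndarray

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})


def run_evaluation(
    demography: DemographyModel | None = None,
    calling_model: CallingModel | None = None,
    n_replicates: int = 20,
    seed: int = 1,
) -> EvaluationResult:
    """Repeat truth simulation + calling + scoring and aggregate.

    Per-sample mean depths are drawn once (seeded) and held fixed across
    replicates, emulating a panel of individuals sequenced at heterogeneous
    but known depths.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    demography = demography or DemographyModel()
    calling_model = calling_model or CallingModel()

    rng = np.random.default_rng(seed)
    n_samples = sum(demography.sample_sizes[g] // 2 for g in demography.labels)
    means = calling_model.draw_mean_depths(n_samples, rng)
    model = dataclasses.replace(calling_model, mean_depths=means)

    records = []
    for _ in range(n_replicates):
        truth_seed = int(rng.integers(1, 2**31 - 1))
        call_seed = int(rng.integers(1, 2**31 - 1))
        truth = simulate_truth(demography, seed=truth_seed)
        called = simulate_calling(truth, model, seed=call_seed)
        records.append(evaluate(truth, called).as_series())
    per_rep = pd.DataFrame(records).reset_index(drop=True)
    return EvaluationResult(
        per_replicate=per_rep,
        mean=per_rep.mean(),
        sd=per_rep.std(ddof=1) if n_replicates > 1 else per_rep.iloc[0] * 0.0,
        n_replicates=n_replicates,
        mean_depths=means,
    )
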