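"""Shared fixtures: tiny hand-built VCFs and a session-scoped synthetic bundle."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import pytest

from suidcat import synthetic_data as sd
from suidcat import variant_store as vs
from suidcat._panel import MISSING


def write_vcf(
    path: Path,
    sample: str,
    records: list[dict],
    contig: str = "1",
    length: int = 100_000,
) -> Path:
    """Write a single-sample VCF from record dicts.

    Each record: ``pos`` (1-based), ``ref``, ``alts`` (tuple, empty for a
    confident hom-ref record), ``gt``, and optional ``dp``/``hqd``/``gq``.
    """
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">')
    header.add_line('##FORMAT=<ID=HQD,Number=1,Type=Integer,Description="HQ depth">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            alts = tuple(r.get("alts", ()))
            alleles = (r["ref"], *alts) if alts else (r["ref"], ".")
            rec = out.new_record(contig=contig, start=r["pos"] - 1, alleles=alleles)
            rec.samples[sample]["GT"] = tuple(r.get("gt", (0, 0)))
            rec.samples[sample]["DP"] = int(r.get("dp", 10))
            rec.samples[sample]["HQD"] = int(r.get("hqd", r.get("dp", 10)))
            rec.samples[sample]["GQ"] = int(r.get("gq", 99))
            out.write(rec)
    return path


def build_matrix(
    sites: list[tuple], gt: np.ndarray, samples: list[str], groups: dict[str, str]
) -> vs.GenotypeMatrix:
    """GenotypeMatrix from (chrom, pos, ref, alts) tuples and a gt array."""
    frame = pd.DataFrame(sites, columns=["chrom", "pos", "ref", "alts"])
    return vs.GenotypeMatrix(
        sites=frame, gt=np.asarray(gt, dtype=np.int8), samples=samples, groups=groups
    )


@pytest.fixture(scope="session")
def bundle_config() -> sd.SynthConfig:
    return sd.SynthConfig(
        n_per_group={"EUWB": 3, "EUDM": 4, "ASWB": 4, "ASDM": 3},
        seq_length=30_000,
        theta=0.002,
        window_size=2_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def bundle(bundle_config, tmp_path_factory):
    """Truth panel + serialized fixture bundle + merged genotype matrix."""
    out = tmp_path_factory.mktemp("bundle")
    panel = sd.generate_truth_panel(bundle_config)
    paths = sd.write_fixture_bundle(panel, bundle_config, out)
    group_map = {**panel.group_of, **{s: s for s in panel.outgroup_gt}}
    matrix = vs.merge_individual_vcfs(paths["vcfs"], group_map)
    return {"config": bundle_config, "panel": panel, "paths": paths,
            "matrix": matrix, "group_map": group_map}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def truth_index(panel) -> dict[int, int]:
    """Map 1-based VCF position -> truth-panel site index."""
    return {int(p) + 1: i for i, p in enumerate(panel.positions)}


MISSING_GT = (MISSING, MISSING)
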