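"""Shared fixtures: a small simulated cohort written to disk once per session."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from somaticnet.encoder import PileupConfig, ReadRecord
from somaticnet.simdata import SimConfig, simulate_cohort, write_fixtures


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 3-sample cohort with reads and on-disk fixtures (seeded)."""
    cfg = SimConfig(seed=11, n_samples=3, n_somatic=40, n_germline=50, n_artifact=25, genome_length=120_000)
    cohort = simulate_cohort(cfg)
    outdir = tmp_path_factory.mktemp("cohort")
    paths = write_fixtures(cohort, str(outdir))
    return cohort, paths


@pytest.fixture(scope="session")
def clean_cohort(tmp_path_factory):
    """Error-free cohort (no sequencing errors, no duplicates): planted reads only."""
    cfg = SimConfig(
        seed=23,
        n_samples=1,
        n_somatic=15,
        n_germline=20,
        n_artifact=0,
        genome_length=60_000,
        error_free=True,
        duplicate_read_fraction=0.0,
        mate_unmapped_fraction=0.0,
    )
    cohort = simulate_cohort(cfg)
    outdir = tmp_path_factory.mktemp("clean_cohort")
    paths = write_fixtures(cohort, str(outdir))
    return cohort, paths


@pytest.fixture()
def pileup_cfg():
    return PileupConfig()


def make_read(
    seq: str,
    start: int = 0,
    quals: int | list = 30,
    flags: int = 0x2,
    cigar=None,
    name: str = "r",
) -> ReadRecord:
    """Convenience constructor for hand-built reads in unit tests."""
    if isinstance(quals, int):
        quals = [quals] * len(seq)
    return ReadRecord(
        name=name,
        sequence=seq,
        qualities=np.asarray(quals, dtype=float),
        flags=flags,
        reference_start=start,
        cigartuples=tuple(cigar) if cigar else ((0, len(seq)),),
    )


def write_vcf(path, records, contigs=None, af_field=False):
    """Write a minimal VCF from (chrom, pos, ref, alts[, af]) tuples."""
    header = pysam.VariantHeader()
    if af_field:
        header.info.add("AF", "A", "Float", "allele frequency")
    contigs = contigs or {"chr1": 1_000_000}
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            chrom, pos, ref, alts = rec[:4]
            r = out.new_record(contig=chrom, start=pos - 1, alleles=(ref, *alts))
            if af_field and len(rec) > 4:
                r.info["AF"] = rec[4]
            out.write(r)
    return str(path)
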