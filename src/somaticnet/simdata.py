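"""Seeded synthetic tumor cohorts with known ground truth.

The simulator emulates the statistical structure a tumor-only somatic
classifier exploits, without pretending to be a sequencer model:

* three variant classes with overlapping VAF distributions — somatic sites
  at low VAF (Beta), germline sites at diploid VAF (heterozygous ~0.5 with
  per-block local shifts standing in for copy-number alterations, or
  homozygous 1.0), artifacts at low VAF with degraded base qualities and
  reverse-strand-enriched flags;
* class-specific trinucleotide mutational signatures — the 3-bp context of
  each planted SNV is written into the reference so the drawn signature is
  exactly recoverable from the FASTA;
* Phred-calibrated base errors (substitution probability ``10^(-Q/10)``);
* a mock population database holding a configured fraction of the germline
  (and a little of the somatic) variants, with AFs above the flanking
  qualification cutoff so flanking annotation is exercised.

Each sample lives on its own contig; planted sites are spaced at least two
read lengths apart so per-site read groups never overlap and the planted
depth is exact. Alt reads per site are Binomial(depth, VAF). One seed gives
byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pysam

from somaticnet.signatures import mutation_classes
from somaticnet.variants import CandidateVariant, write_candidate_vcf

_BASES = "ACGT"


def default_signature(kind: str) -> np.ndarray:
    """Built-in 192-class signature for one variant class.

    Each class mixes a characteristic mutation process with a uniform floor:
    somatic — C>T at CpG sites (deamination-like); germline — A>G
    transitions; artifact — G>T transversions (oxidative-damage-like).
    """
    classes = mutation_classes(collapse=False)
    probs = np.full(len(classes), 1.0, dtype=float)
    if kind == "somatic":
        focus = [(i, 3.0) for i, (ctx, alt) in enumerate(classes) if ctx[1] == "C" and alt == "T" and ctx[2] == "G"]
        weight = 0.75
    elif kind == "germline":
        focus = [(i, 1.0) for i, (ctx, alt) in enumerate(classes) if ctx[1] == "A" and alt == "G"]
        weight = 0.50
    elif kind == "artifact":
        focus = [(i, 1.0) for i, (ctx, alt) in enumerate(classes) if ctx[1] == "G" and alt == "T"]
        weight = 0.60
    else:
        raise ValueError(f"unknown class {kind!r}")
    probs /= probs.sum()
    probs *= 1.0 - weight
    fw = np.array([w for _, w in focus], dtype=float)
    fw /= fw.sum()
    for (i, _), w in zip(focus, fw):
        probs[i] += weight * w
    return probs


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic cohort (all rates per sample)."""

    seed: int = 0
    n_samples: int = 12
    genome_length: int = 400_000
    n_somatic: int = 120
    n_germline: int = 150
    n_artifact: int = 80
    coverage: float = 40.0
    read_length: int = 100
    base_quality: float = 36.0
    quality_jitter: float = 3.0
    artifact_quality_delta: float = 15.0
    artifact_reverse_strand_prob: float = 0.85
    somatic_vaf_beta: tuple[float, float] = (4.0, 14.0)  # mean ~0.22
    artifact_vaf_beta: tuple[float, float] = (2.5, 30.0)  # mean ~0.08
    germline_hom_fraction: float = 0.2
    germline_het_vaf_sd: float = 0.06  # per-block local shift of the 0.5 center
    vaf_block_bp: int = 50_000
    indel_fraction: float = 0.10  # of somatic and germline variants
    max_indel_len: int = 3
    fraction_germline_in_db: float = 0.9
    fraction_somatic_in_db: float = 0.1
    germline_db_af_range: tuple[float, float] = (0.12, 0.60)
    somatic_db_af_range: tuple[float, float] = (1e-4, 0.01)
    duplicate_read_fraction: float = 0.02
    mate_unmapped_fraction: float = 0.01
    error_free: bool = False

    def __post_init__(self) -> None:
        for frac in (
            self.germline_hom_fraction,
            self.indel_fraction,
            self.fraction_germline_in_db,
            self.fraction_somatic_in_db,
            self.duplicate_read_fraction,
            self.mate_unmapped_fraction,
            self.artifact_reverse_strand_prob,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if min(self.n_samples, self.n_somatic + self.n_germline + self.n_artifact) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class SimRead:
    name: str
    start: int  # 0-based leftmost reference position
    sequence: str
    qualities: np.ndarray
    flags: int
    cigartuples: tuple[tuple[int, int], ...]


@dataclass
class TruthRecord:
    variant: CandidateVariant
    true_vaf: float
    depth: int
    n_alt: int  # planted alt reads (before sequencing errors)
    in_db: bool
    db_af: float


@dataclass
class SimSample:
    sample_id: str
    truth: list[TruthRecord]
    reads: list[SimRead] = field(default_factory=list)

    @property
    def variants(self) -> list[CandidateVariant]:
        return [t.variant for t in self.truth]


@dataclass
class Cohort:
    cfg: SimConfig
    reference: dict[str, str]  # contig name (== sample id) -> sequence
    samples: list[SimSample]
    population: dict[tuple[str, int, str, str], float]


def _plant_sites(cfg: SimConfig, rng: np.random.Generator, sample_id: str, genome: np.ndarray) -> list[TruthRecord]:
    """Plant all variants of one sample into its contig, editing the genome."""
    classes = mutation_classes(collapse=False)
    sigs = {k: default_signature(k) for k in ("somatic", "germline", "artifact")}
    margin = cfg.read_length + 10
    spacing = 2 * cfg.read_length + 20
    usable = cfg.genome_length - 2 * margin
    n_slots = usable // spacing
    n_total = cfg.n_somatic + cfg.n_germline + cfg.n_artifact
    if n_total > n_slots:
        raise ValueError(
            f"{n_total} variants do not fit {n_slots} sites; increase genome_length"
        )
    slots = rng.choice(n_slots, size=n_total, replace=False)
    offsets = rng.integers(0, spacing - 2 * cfg.read_length, size=n_total)
    positions = margin + slots * spacing + offsets  # 0-based variant columns
    labels = ["somatic"] * cfg.n_somatic + ["germline"] * cfg.n_germline + ["artifact"] * cfg.n_artifact

    # per-block heterozygous VAF centers (local copy-number-like shifts)
    n_blocks = cfg.genome_length // cfg.vaf_block_bp + 1
    het_centers = np.clip(rng.normal(0.5, cfg.germline_het_vaf_sd, size=n_blocks), 0.30, 0.70)

    truth: list[TruthRecord] = []
    for pos0, label in zip(positions, labels):
        pos0 = int(pos0)
        is_indel = label != "artifact" and rng.random() < cfg.indel_fraction
        if is_indel:
            k = int(rng.integers(1, cfg.max_indel_len + 1))
            anchor = _BASES[genome[pos0]]
            if rng.random() < 0.5:  # insertion
                ins = "".join(_BASES[i] for i in rng.integers(0, 4, size=k))
                ref_a, alt_a = anchor, anchor + ins
            else:  # deletion
                deleted = "".join(_BASES[i] for i in genome[pos0 + 1 : pos0 + 1 + k])
                ref_a, alt_a = anchor + deleted, anchor
                if alt_a == ref_a:  # degenerate; cannot happen but keep the guard
                    continue
        else:
            ci = rng.choice(len(classes), p=sigs[label])
            ctx, alt_a = classes[ci]
            for j, b in enumerate(ctx):  # write the drawn context into the reference
                genome[pos0 - 1 + j] = _BASES.index(b)
            ref_a = ctx[1]
        if label == "somatic":
            a, b = cfg.somatic_vaf_beta
            vaf = float(rng.beta(a, b))
        elif label == "artifact":
            a, b = cfg.artifact_vaf_beta
            vaf = float(rng.beta(a, b))
        else:
            if rng.random() < cfg.germline_hom_fraction:
                vaf = 1.0
            else:
                vaf = float(het_centers[pos0 // cfg.vaf_block_bp])
        in_db, db_af = False, 0.0
        if label == "germline" and rng.random() < cfg.fraction_germline_in_db:
            in_db, db_af = True, float(rng.uniform(*cfg.germline_db_af_range))
        elif label == "somatic" and rng.random() < cfg.fraction_somatic_in_db:
            in_db, db_af = True, float(rng.uniform(*cfg.somatic_db_af_range))
        variant = CandidateVariant(
            chrom=sample_id, pos=pos0 + 1, ref=ref_a, alt=alt_a, sample_id=sample_id, truth_label=label
        )
        truth.append(TruthRecord(variant, vaf, depth=0, n_alt=0, in_db=in_db, db_af=db_af))
    truth.sort(key=lambda t: t.variant.pos)
    return truth


def _site_reads(cfg: SimConfig, rng: np.random.Generator, genome: np.ndarray, rec: TruthRecord, site_idx: int) -> list[SimRead]:
    """Simulate the read stack of one planted site; updates depth/n_alt in place."""
    v = rec.variant
    pos0 = v.pos - 1
    L = cfg.read_length
    depth = int(rng.poisson(cfg.coverage))
    rec.depth = depth
    if depth == 0:
        return []
    n_alt = int(rng.binomial(depth, rec.true_vaf))
    rec.n_alt = n_alt
    is_alt = np.zeros(depth, dtype=bool)
    is_alt[rng.permutation(depth)[:n_alt]] = True
    is_artifact = v.truth_label == "artifact"
    reads: list[SimRead] = []
    for i in range(depth):
        alt = bool(is_alt[i])
        # the read must cover pos0 and pos0+1 (and hold the full insertion)
        max_off = L - 2 - (len(v.alt) - 1 if alt and v.variant_type == "INS" else 0)
        offset = int(rng.integers(1, max_off + 1))
        start = pos0 - offset
        if alt and v.variant_type == "INS":
            k = len(v.alt) - 1
            left = "".join(_BASES[b] for b in genome[start : pos0 + 1])
            rest = L - len(left) - k
            right = "".join(_BASES[b] for b in genome[pos0 + 1 : pos0 + 1 + rest])
            seq = left + v.alt[1:] + right
            cigar = ((0, len(left)), (1, k), (0, rest))
        elif alt and v.variant_type == "DEL":
            k = len(v.ref) - 1
            left = "".join(_BASES[b] for b in genome[start : pos0 + 1])
            rest = L - len(left)
            right = "".join(_BASES[b] for b in genome[pos0 + 1 + k : pos0 + 1 + k + rest])
            seq = left + right
            cigar = ((0, len(left)), (2, k), (0, rest))
        else:
            chars = [_BASES[b] for b in genome[start : start + L]]
            if alt:  # SNP
                chars[offset] = v.alt
            seq = "".join(chars)
            cigar = ((0, L),)
        quals = np.clip(np.rint(rng.normal(cfg.base_quality, cfg.quality_jitter, size=len(seq))), 2, 41)
        if is_artifact and alt:
            quals = np.clip(quals - cfg.artifact_quality_delta, 2, 41)
        if not cfg.error_free:
            e = np.power(10.0, -quals / 10.0)
            err = rng.random(len(seq)) < e
            if err.any():
                arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                lut = {65: "CGT", 67: "AGT", 71: "ACT", 84: "ACG"}
                for j in np.nonzero(err)[0]:
                    arr[j] = ord(rng.choice(list(lut.get(arr[j], "ACGT"))))
                seq = arr.tobytes().decode()
        rev_p = cfg.artifact_reverse_strand_prob if (is_artifact and alt) else 0.5
        reverse = rng.random() < rev_p
        if rng.random() < cfg.mate_unmapped_fraction:
            flags = 0x1 | 0x8 | (0x10 if reverse else 0)
        else:
            flags = 0x1 | 0x2 | (0x10 if reverse else 0x20)
        read = SimRead(
            name=f"{v.sample_id}_s{site_idx}_r{i}",
            start=start,
            sequence=seq,
            qualities=quals.astype(np.uint8),
            flags=flags,
            cigartuples=cigar,
        )
        reads.append(read)
        if rng.random() < cfg.duplicate_read_fraction:
            reads.append(
                SimRead(
                    name=read.name + "_dup",
                    start=start,
                    sequence=seq,
                    qualities=read.qualities.copy(),
                    flags=flags | 0x400,
                    cigartuples=cigar,
                )
            )
    return reads


def simulate_cohort(cfg: SimConfig, with_reads: bool = True) -> Cohort:
    """Simulate a full cohort; identical configs give identical cohorts.

    ``with_reads=False`` plants variants and truth only (cheap mode for
    signature and VAF-distribution checks).
    """
    rng = np.random.default_rng(cfg.seed)
    reference: dict[str, str] = {}
    samples: list[SimSample] = []
    population: dict[tuple[str, int, str, str], float] = {}
    for s in range(cfg.n_samples):
        sid = f"S{s + 1}"
        genome = rng.integers(0, 4, size=cfg.genome_length, dtype=np.int8)
        truth = _plant_sites(cfg, rng, sid, genome)
        sample = SimSample(sample_id=sid, truth=truth)
        if with_reads:
            for site_idx, rec in enumerate(truth):
                sample.reads.extend(_site_reads(cfg, rng, genome, rec, site_idx))
            sample.reads.sort(key=lambda r: r.start)
        reference[sid] = "".join(_BASES[b] for b in genome)
        for rec in truth:
            if rec.in_db:
                population[rec.variant.key] = rec.db_af
        samples.append(sample)
    return Cohort(cfg=cfg, reference=reference, samples=samples, population=population)


def write_fixtures(cohort: Cohort, outdir: str) -> dict[str, object]:
    """Write the cohort as standards-conformant files.

    Produces ``ref.fa`` (+ .fai), one sorted+indexed BAM and one candidate
    VCF per sample, a shared ``population.vcf`` and ``truth.tsv``. Returns a
    dict of the paths.
    """
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, object] = {}

    fasta_path = os.path.join(outdir, "ref.fa")
    with open(fasta_path, "w") as fh:
        for name, seq in cohort.reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    pysam.faidx(fasta_path)
    paths["fasta"] = fasta_path

    contigs = {name: len(seq) for name, seq in cohort.reference.items()}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
    }
    tids = {name: i for i, name in enumerate(contigs)}

    bam_paths, vcf_paths = {}, {}
    for sample in cohort.samples:
        bam_path = os.path.join(outdir, f"{sample.sample_id}.bam")
        with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
            for read in sample.reads:
                a = pysam.AlignedSegment(bam.header)
                a.query_name = read.name
                a.query_sequence = read.sequence
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in read.qualities)
                )
                a.flag = read.flags
                a.reference_id = tids[sample.sample_id]
                a.reference_start = read.start
                a.mapping_quality = 60
                a.cigartuples = list(read.cigartuples)
                a.next_reference_id = tids[sample.sample_id]
                a.next_reference_start = read.start
                a.template_length = 0
                bam.write(a)
        pysam.index(bam_path)
        bam_paths[sample.sample_id] = bam_path

        vcf_path = os.path.join(outdir, f"{sample.sample_id}.candidates.vcf")
        write_candidate_vcf(sorted(sample.variants, key=lambda v: v.pos), vcf_path, contigs=contigs)
        vcf_paths[sample.sample_id] = vcf_path
    paths["bam"] = bam_paths
    paths["candidates"] = vcf_paths

    pop_path = os.path.join(outdir, "population.vcf")
    pop_header = pysam.VariantHeader()
    pop_header.info.add("AF", "A", "Float", "Population allele frequency")
    for name, length in contigs.items():
        pop_header.contigs.add(name, length=length)
    keys = sorted(cohort.population, key=lambda k: (tids[k[0]], k[1], k[2], k[3]))
    with pysam.VariantFile(pop_path, "w", header=pop_header) as out:
        for key in keys:
            chrom, pos, ref, alt = key
            rec = out.new_record(contig=chrom, start=pos - 1, alleles=(ref, alt))
            rec.info["AF"] = cohort.population[key]
            out.write(rec)
    paths["population"] = pop_path

    truth_path = os.path.join(outdir, "truth.tsv")
    with open(truth_path, "w") as fh:
        fh.write("sample_id\tchrom\tpos\tref\talt\ttruth_label\ttrue_vaf\tdepth\tn_alt\tin_db\tdb_af\n")
        for sample in cohort.samples:
            for t in sample.truth:
                v = t.variant
                fh.write(
                    f"{v.sample_id}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.truth_label}\t"
                    f"{t.true_vaf:.6g}\t{t.depth}\t{t.n_alt}\t{int(t.in_db)}\t{t.db_af:.6g}\n"
                )
    paths["truth"] = truth_path
    return paths
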