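"""Candidate-variant I/O, normalization and population-AF filtering.

Coordinates are 1-based inclusive at the API boundary (VCF convention) and
0-based half-open internally; the conversion happens only in this module and
in :mod:`somaticnet.encoder` where reads are addressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pysam

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")
TRUTH_LABELS = ("somatic", "germline", "artifact", "unknown")


@dataclass
class CandidateVariant:
    """One candidate site in VCF-style representation.

    ``pos`` is the 1-based position of the first base of ``ref``. INDELs are
    left-anchored: an insertion ``C>CT`` and a deletion ``CA>C`` both sit on
    the anchor base ``C``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str = ""
    truth_label: str = "unknown"
    pop_af: float | None = None
    in_population_db: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValueError(f"{name} allele {allele!r} is not a non-empty ACGT string")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if self.truth_label not in TRUTH_LABELS:
            raise ValueError(f"unknown truth label {self.truth_label!r}")

    @property
    def variant_type(self) -> str:
        """``SNP``, ``INS`` or ``DEL``, derived from allele lengths."""
        if len(self.ref) == len(self.alt) == 1:
            return "SNP"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_somatic(self) -> bool:
        return self.truth_label == "somatic"


def normalize_variant(v: CandidateVariant) -> CandidateVariant:
    """Reduce a variant to its minimal left-anchored VCF representation.

    The shared allele suffix is trimmed first, then the shared prefix (the
    position advances by one per trimmed prefix base); each allele always
    keeps at least one base so INDELs stay anchored. The operation is
    idempotent.
    """
    ref, alt, pos = v.ref, v.alt, v.pos
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (ref, alt, pos) == (v.ref, v.alt, v.pos):
        return v
    return replace(v, pos=pos, ref=ref, alt=alt)


def read_candidate_vcf(path: str, sample_id: str = "") -> list[CandidateVariant]:
    """Read a VCF into normalized candidates, one per (record, ALT) pair.

    Multiallelic records are decomposed per ALT. Symbolic, spanning-deletion
    and otherwise non-ACGT ALT alleles are skipped with a logged count. FILTER
    status is logged but all records are consumed.
    """
    variants: list[CandidateVariant] = []
    n_skipped = 0
    n_filtered = 0
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read VCF {path!r}: {exc}") from exc
    with vcf:
        for rec in vcf:
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                n_filtered += 1
            for alt in rec.alts or ():
                if alt is None or not set(alt) <= _VALID_BASES or not rec.ref or not set(rec.ref) <= _VALID_BASES:
                    n_skipped += 1
                    continue
                variants.append(
                    normalize_variant(
                        CandidateVariant(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt, sample_id=sample_id)
                    )
                )
    if n_skipped:
        logger.info("skipped %d symbolic/non-ACGT ALT alleles in %s", n_skipped, path)
    if n_filtered:
        logger.info("consumed %d records with non-PASS FILTER in %s", n_filtered, path)
    return variants


def write_candidate_vcf(
    variants: Sequence[CandidateVariant],
    path: str,
    contigs: dict[str, int] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write candidates to a VCF with ``POP_AF`` and ``DEEPSOM_SCORE`` INFO fields."""
    header = pysam.VariantHeader()
    header.add_meta("source", "somaticnet")
    header.info.add("POP_AF", 1, "Float", "Population allele frequency of the matching germline record")
    header.info.add("DEEPSOM_SCORE", 1, "Float", "Somatic pseudoprobability from the CNN classifier")
    if contigs is None:
        contigs = {}
        for v in variants:
            contigs[v.chrom] = max(contigs.get(v.chrom, 0), v.pos + len(v.ref) + 1000)
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    if scores is not None and len(scores) != len(variants):
        raise ValueError("scores length does not match variants length")
    with pysam.VariantFile(path, "w", header=header) as out:
        for i, v in enumerate(variants):
            rec = out.new_record(contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt))
            if v.pop_af is not None:
                rec.info["POP_AF"] = float(v.pop_af)
            if scores is not None:
                rec.info["DEEPSOM_SCORE"] = float(scores[i])
            out.write(rec)


@dataclass
class PopulationDB:
    """Exact lookup from normalized (chrom, pos, ref, alt) to population AF.

    ``has_af`` is False when the source VCF carried no AF INFO field, in
    which case every entry has AF 0 and the database acts as a presence set.
    """

    entries: dict[tuple[str, int, str, str], float] = field(default_factory=dict)
    has_af: bool = True

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self.entries

    def af(self, key: tuple[str, int, str, str]) -> float | None:
        """AF for a normalized key, or None when the key is absent."""
        return self.entries.get(key)

    def add(self, key: tuple[str, int, str, str], af: float) -> None:
        if not 0.0 <= af <= 1.0:
            raise ValueError(f"AF {af} outside [0, 1] for {key}")
        prev = self.entries.get(key)
        # duplicate keys keep the maximum AF (conservative filtering)
        self.entries[key] = af if prev is None else max(prev, af)


def load_population_db(path: str) -> PopulationDB:
    """Load a gnomAD-style population VCF into an AF lookup.

    Per-ALT AF values are read from the AF INFO field. Records without AF are
    stored with AF 0 (presence only); if the header lacks AF entirely the
    database switches to presence-only mode with a warning.
    """
    db = PopulationDB()
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read population VCF {path!r}: {exc}") from exc
    with vcf:
        if "AF" not in vcf.header.info:
            logger.warning("population VCF %s has no AF INFO field; presence-only mode", path)
            db.has_af = False
        for rec in vcf:
            afs = rec.info.get("AF", None) if db.has_af else None
            if afs is not None and not isinstance(afs, (tuple, list)):
                afs = (afs,)
            for i, alt in enumerate(rec.alts or ()):
                if alt is None or not set(alt) <= _VALID_BASES or not rec.ref or not set(rec.ref) <= _VALID_BASES:
                    continue
                af = 0.0
                if afs is not None and i < len(afs) and afs[i] is not None:
                    af = float(afs[i])
                key = normalize_variant(CandidateVariant(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt)).key
                db.add(key, min(max(af, 0.0), 1.0))
    return db


def population_filter(
    variants: Iterable[CandidateVariant],
    db: PopulationDB,
    max_af: float = 0.0,
) -> tuple[list[CandidateVariant], list[CandidateVariant]]:
    """Split candidates into (retained, removed) by population AF.

    A candidate is removed when it is present in the database with AF above
    ``max_af``; at the default ``max_af = 0`` every database-present candidate
    is removed regardless of its recorded AF (including presence-only entries).
    All database-present candidates get ``pop_af`` annotated in place.
    """
    retained: list[CandidateVariant] = []
    removed: list[CandidateVariant] = []
    for v in variants:
        af = db.af(v.key)
        if af is not None:
            v.pop_af = af
            v.in_population_db = True
            drop = af > max_af or max_af <= 0.0
        else:
            drop = False
        (removed if af is not None and drop else retained).append(v)
    return retained, removed


def enumerate_candidates(
    bam_path: str,
    fasta_path: str,
    min_alt_reads: int = 1,
    exclude_flags: int = 0x4 | 0x200 | 0x400,
    sample_id: str = "",
) -> list[CandidateVariant]:
    """Naively enumerate candidate variants straight from a BAM.

    Every position where at least ``min_alt_reads`` filtered reads support a
    non-reference base, insertion or deletion yields one candidate. This
    bypasses any upstream caller at maximal sensitivity; the downstream
    classifier is expected to absorb the resulting noise.
    """
    bam = pysam.AlignmentFile(bam_path)
    if not bam.has_index():
        raise OSError(f"BAM {bam_path!r} has no index; run samtools index first")
    fasta = pysam.FastaFile(fasta_path)
    out: list[CandidateVariant] = []
    with bam, fasta:
        for col in bam.pileup(stepper="nofilter", min_base_quality=0):
            pos0 = col.reference_pos
            chrom = col.reference_name
            refbase = fasta.fetch(chrom, pos0, pos0 + 1).upper()
            if refbase not in _VALID_BASES:
                continue
            snv_counts: dict[str, int] = {}
            ins_counts: dict[str, int] = {}
            del_counts: dict[int, int] = {}
            for pr in col.pileups:
                aln = pr.alignment
                if aln.flag & exclude_flags:
                    continue
                if pr.is_refskip or pr.is_del or pr.query_position is None:
                    continue
                base = aln.query_sequence[pr.query_position].upper()
                if base in _VALID_BASES and base != refbase:
                    snv_counts[base] = snv_counts.get(base, 0) + 1
                if pr.indel > 0:
                    ins = aln.query_sequence[pr.query_position + 1 : pr.query_position + 1 + pr.indel].upper()
                    if set(ins) <= _VALID_BASES:
                        ins_counts[ins] = ins_counts.get(ins, 0) + 1
                elif pr.indel < 0:
                    k = -pr.indel
                    del_counts[k] = del_counts.get(k, 0) + 1
            for base, n in sorted(snv_counts.items()):
                if n >= min_alt_reads:
                    out.append(CandidateVariant(chrom, pos0 + 1, refbase, base, sample_id=sample_id))
            for ins, n in sorted(ins_counts.items()):
                if n >= min_alt_reads:
                    out.append(CandidateVariant(chrom, pos0 + 1, refbase, refbase + ins, sample_id=sample_id))
            for k, n in sorted(del_counts.items()):
                if n >= min_alt_reads:
                    deleted = fasta.fetch(chrom, pos0 + 1, pos0 + 1 + k).upper()
                    if set(deleted) <= _VALID_BASES and len(deleted) == k:
                        out.append(CandidateVariant(chrom, pos0 + 1, refbase + deleted, refbase, sample_id=sample_id))
    return out
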