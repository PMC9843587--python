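"""Read-pileup tensor encoding.

Each candidate variant is converted into a ``C x W x H`` tensor built from
the reads overlapping the site:

* channels 0-3: one-hot encoding of the reference sequence over the W-bp
  region of interest (ROI), replicated into every real read row; insertion
  columns carry all-zero reference;
* channels 4-7: "p-hot" encoding of read base calls — the called base's
  channel holds ``1 - e`` and the three other bases ``e / 3`` with
  ``e = 10^(-Q/10)`` from the Phred quality ``Q``, so the four channels
  conserve probability mass;
* channels 8-13: constant binary read-flag channels for the six SAM flag
  masks 0x2, 0x8, 0x10, 0x20, 0x100, 0x800.

The variant column sits at index ``W // 2``. For a k-bp insertion, k
reference columns of zeros are inserted after the anchor base and reads that
lack the insertion show gaps there. Tensors are padded with all-zero rows up
to height ``H``, or cropped down to ``H`` reads such that the variant allele
fraction moves by at most ``1/H``. Rows are sorted by the symbol each read
shows in the variant column (A, C, G, T, gap; padding last).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pysam

from somaticnet.variants import CandidateVariant

BASE_TO_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
GAP_CODE = 4  # read spans the column but shows no base (deletion / missing insertion)
UNCOVERED = -2  # column outside the read's aligned span

# query-index sentinel values used in the per-read column map
_QGAP = -1

_SEQ_LUT = np.full(256, GAP_CODE, dtype=np.int8)
for _b, _i in BASE_TO_INDEX.items():
    _SEQ_LUT[ord(_b)] = _i
    _SEQ_LUT[ord(_b.lower())] = _i


@dataclass(frozen=True)
class PileupConfig:
    """Constants of the tensor encoding.

    ``C`` is fixed by construction to ``8 + len(flag_set)``: four reference
    channels, four quality channels and one channel per encoded SAM flag.
    """

    W: int = 150
    H: int = 70
    flag_set: tuple[int, ...] = (0x2, 0x8, 0x10, 0x20, 0x100, 0x800)
    exclude_flags: int = 0x4 | 0x200 | 0x400

    def __post_init__(self) -> None:
        if self.W < 1 or self.H < 1:
            raise ValueError("W and H must be >= 1")

    @property
    def C(self) -> int:
        return 8 + len(self.flag_set)

    @property
    def variant_col(self) -> int:
        """0-based index of the variant column inside the ROI."""
        return self.W // 2

    def config_hash(self) -> str:
        payload = json.dumps(
            {"W": self.W, "H": self.H, "flags": list(self.flag_set), "excl": self.exclude_flags}
        )
        return hashlib.md5(payload.encode()).hexdigest()


@dataclass
class ReadRecord:
    """The slice of a SAM record the encoder needs."""

    name: str
    sequence: str
    qualities: np.ndarray
    flags: int
    reference_start: int  # 0-based leftmost aligned reference position
    cigartuples: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.float64)
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities length mismatch")

    @classmethod
    def from_alignment(cls, aln: pysam.AlignedSegment) -> "ReadRecord":
        return cls(
            name=aln.query_name or "",
            sequence=aln.query_sequence or "",
            qualities=np.asarray(aln.query_qualities or [], dtype=np.float64),
            flags=aln.flag,
            reference_start=aln.reference_start,
            cigartuples=tuple(aln.cigartuples or ()),
        )


@dataclass
class VariantTensor:
    """Encoded pileup plus meta features for one candidate."""

    tensor: np.ndarray  # (C, W, H) float32
    meta: np.ndarray  # (10,) float32
    vaf_precrop: float
    dp_precrop: int
    truth_label: str = "unknown"
    low_coverage: bool = False
    variant: CandidateVariant | None = None


def variant_anchor(variant: CandidateVariant) -> tuple[int, int]:
    """0-based reference position of the variant column and insertion length k.

    SNPs anchor on the substituted base, deletions on the first deleted base,
    insertions on the base preceding the inserted sequence (k > 0).
    """
    pos0 = variant.pos - 1
    vtype = variant.variant_type
    if vtype == "SNP":
        return pos0, 0
    if vtype == "DEL":
        return pos0 + len(variant.alt), 0
    return pos0, len(variant.alt) - len(variant.ref)


def column_ref_positions(variant: CandidateVariant, cfg: PileupConfig) -> np.ndarray:
    """Reference position of every ROI column; -1 marks insertion columns.

    The variant column is placed at ``cfg.variant_col``. For a k-bp insertion
    the columns ``variant_col .. variant_col+k-1`` are insertion slots whose
    reference one-hot is all zero.
    """
    vc = cfg.variant_col
    anchor, k = variant_anchor(variant)
    cols = np.empty(cfg.W, dtype=np.int64)
    if k == 0:
        cols[:] = anchor - vc + np.arange(cfg.W)
    else:
        # left part ends on the anchor base; k insertion slots; then anchor+1 ...
        cols[:vc] = anchor - (vc - 1) + np.arange(vc)
        n_slots = min(k, cfg.W - vc)
        cols[vc : vc + n_slots] = -1
        n_right = cfg.W - vc - n_slots
        cols[vc + n_slots :] = anchor + 1 + np.arange(n_right)
    return cols


def fetch_site_reads(
    bam: pysam.AlignmentFile | str,
    variant: CandidateVariant,
    cfg: PileupConfig,
) -> list[ReadRecord]:
    """All reads overlapping the variant column, minus excluded flags.

    Excluded flags default to unmapped (0x4), QC-fail (0x200) and PCR/optical
    duplicate (0x400) reads.
    """
    own = isinstance(bam, str)
    handle = pysam.AlignmentFile(bam) if own else bam
    anchor, _k = variant_anchor(variant)
    if variant.chrom not in handle.references:
        if own:
            handle.close()
        raise ValueError(f"contig {variant.chrom!r} absent from BAM")
    reads = [
        ReadRecord.from_alignment(aln)
        for aln in handle.fetch(variant.chrom, anchor, anchor + 1)
        if not (aln.flag & cfg.exclude_flags) and aln.cigartuples
    ]
    if own:
        handle.close()
    return reads


def _read_column_map(
    read: ReadRecord,
    cols: np.ndarray,
    variant: CandidateVariant,
) -> tuple[np.ndarray, bool]:
    """Map ROI columns to query indices for one read.

    Returns ``(qmap, supports_alt)`` where ``qmap[w]`` is the query index of
    the base shown in column ``w``, ``-1`` for an alignment gap (deleted base
    or absent insertion) and ``-2`` for columns outside the read. Soft-clipped
    bases are never placed.
    """
    qmap = np.full(cols.shape[0], UNCOVERED, dtype=np.int64)
    anchor, k_ins = variant_anchor(variant)
    ins_len_at_anchor = 0
    del_span = False  # deletion spanning the variant column
    ref_pos = read.reference_start
    q = 0
    ins_slots = np.nonzero(cols == -1)[0]
    for op, ln in read.cigartuples:
        if op in (0, 7, 8):  # M, =, X consume both
            m = (cols >= ref_pos) & (cols < ref_pos + ln)
            qmap[m] = q + (cols[m] - ref_pos)
            ref_pos += ln
            q += ln
        elif op == 1:  # I consumes query
            if k_ins and ref_pos - 1 == anchor:
                ins_len_at_anchor = ln
                n = min(ln, ins_slots.shape[0])
                qmap[ins_slots[:n]] = q + np.arange(n)
            q += ln
        elif op == 2:  # D consumes reference
            m = (cols >= ref_pos) & (cols < ref_pos + ln)
            qmap[m] = _QGAP
            if k_ins == 0 and ref_pos <= anchor < ref_pos + ln:
                del_span = True
            ref_pos += ln
        elif op == 3:  # N: skipped region, leave uncovered
            ref_pos += ln
        elif op == 4:  # S consumes query, bases not placed
            q += ln
        # H (5) and P (6) consume nothing we track
    # a read spanning the anchor without the insertion shows gaps in the slots
    if k_ins and ins_len_at_anchor == 0 and ins_slots.size:
        left_ok = np.any((cols == anchor) & (qmap >= 0))
        right_ok = np.any((cols == anchor + 1) & (qmap >= 0))
        if left_ok and right_ok:
            qmap[ins_slots[qmap[ins_slots] == UNCOVERED]] = _QGAP
    if variant.variant_type == "SNP":
        vc_q = qmap[np.nonzero(cols == anchor)[0]]
        supports = bool(
            vc_q.size
            and vc_q[0] >= 0
            and read.sequence[vc_q[0]].upper() == variant.alt
        )
    elif variant.variant_type == "INS":
        supports = ins_len_at_anchor == k_ins
    else:  # DEL: a CIGAR deletion spans the first deleted base
        supports = del_span
    return qmap, supports


def read_supports_alt(read: ReadRecord, variant: CandidateVariant, cfg: PileupConfig) -> bool:
    """Whether one read carries the candidate's alternate allele."""
    cols = column_ref_positions(variant, cfg)
    _, supports = _read_column_map(read, cols, variant)
    return supports


def encode_read(read: ReadRecord, ref_window: str, cfg: PileupConfig) -> np.ndarray:
    """Encode one read as a C x L matrix (L = read length).

    ``ref_window`` is the reference sequence aligned column-by-column to the
    read's bases ('-' where the reference has no base, e.g. under an
    insertion). Channels: 0-3 reference one-hot, 4-7 p-hot base qualities,
    8-13 constant flag bits.
    """
    L = len(read.sequence)
    if len(ref_window) != L:
        raise ValueError("ref_window must align to the read (one char per read base)")
    mat = np.zeros((cfg.C, L), dtype=np.float32)
    ref_codes = _SEQ_LUT[np.frombuffer(ref_window.encode(), dtype=np.uint8)]
    read_codes = _SEQ_LUT[np.frombuffer(read.sequence.encode(), dtype=np.uint8)]
    for b in range(4):
        mat[b, ref_codes == b] = 1.0
    e = np.power(10.0, -read.qualities / 10.0)
    for b in range(4):
        called = read_codes == b
        mat[4 + b, called] = 1.0 - e[called]
        other = (read_codes != b) & (read_codes < 4)
        mat[4 + b, other] = e[other] / 3.0
    for j, mask in enumerate(cfg.flag_set):
        if read.flags & mask:
            mat[8 + j, :] = 1.0
    return mat


def roi_overlap(read: ReadRecord, cols: np.ndarray, variant: CandidateVariant) -> int:
    """Number of ROI columns on which the read shows a base."""
    qmap, _ = _read_column_map(read, cols, variant)
    return int(np.count_nonzero(qmap >= 0))


def select_crop(
    reads: Sequence,
    alt_support: Sequence[bool],
    H: int,
    vaf_precrop: float,
    overlaps: Sequence[int] | None = None,
) -> list[int]:
    """Indices of the H reads kept when the pileup exceeds the tensor height.

    The split between removed alt-supporting and removed other reads is
    chosen to minimize ``|VAF_after - vaf_precrop|`` (ties resolved toward
    keeping fewer alt reads), which bounds the VAF shift by ``1/H``. Within
    each class, reads with the smallest ROI overlap are removed first, then
    earlier input positions; the result preserves input order.
    """
    dp = len(reads)
    if dp <= H:
        return list(range(dp))
    alt_idx = [i for i, a in enumerate(alt_support) if a]
    other_idx = [i for i, a in enumerate(alt_support) if not a]
    n_alt, n_other = len(alt_idx), len(other_idx)
    lo, hi = max(0, H - n_other), min(H, n_alt)
    best_a, best_err = lo, float("inf")
    for a in range(lo, hi + 1):
        err = abs(a / H - vaf_precrop)
        if err < best_err - 1e-15:
            best_a, best_err = a, err
    if overlaps is None:
        overlaps = [0] * dp
    removal_rank = lambda i: (overlaps[i], i)  # noqa: E731 - smallest overlap, then input order
    drop: set[int] = set()
    drop.update(sorted(alt_idx, key=removal_rank)[: n_alt - best_a])
    drop.update(sorted(other_idx, key=removal_rank)[: n_other - (H - best_a)])
    return [i for i in range(dp) if i not in drop]


def reference_window(fasta: pysam.FastaFile, variant: CandidateVariant, cfg: PileupConfig) -> str:
    """Reference base per ROI column; '-' on insertion slots and off-contig columns."""
    cols = column_ref_positions(variant, cfg)
    contig_len = fasta.get_reference_length(variant.chrom)
    lo = int(cols[cols >= 0].min())
    hi = int(cols.max()) + 1
    seq = fasta.fetch(variant.chrom, max(lo, 0), min(hi, contig_len)).upper()
    out = []
    for c in cols:
        if c < 0 or c >= contig_len:
            out.append("-")
        else:
            j = c - max(lo, 0)
            out.append(seq[j] if 0 <= j < len(seq) else "-")
    return "".join(out)


def assemble_tensor(
    variant: CandidateVariant,
    reads: Sequence[ReadRecord],
    ref_window: str,
    cfg: PileupConfig,
    meta: np.ndarray | None = None,
) -> VariantTensor:
    """Build the C x W x H tensor for one candidate from its site reads.

    ``ref_window`` comes from :func:`reference_window`. ``meta`` is the
    10-value meta vector; when omitted it is filled with the candidate's own
    VAF and DP/H and zeroed flanking entries.
    """
    cols = column_ref_positions(variant, cfg)
    W, H, C = cfg.W, cfg.H, cfg.C
    vc = cfg.variant_col

    qmaps: list[np.ndarray] = []
    alt_flags: list[bool] = []
    for read in reads:
        qmap, supports = _read_column_map(read, cols, variant)
        qmaps.append(qmap)
        alt_flags.append(supports)
    dp = len(reads)
    n_alt = int(sum(alt_flags))
    vaf_precrop = n_alt / dp if dp else 0.0

    keep = list(range(dp))
    if dp > H:
        overlaps = [int(np.count_nonzero(q >= 0)) for q in qmaps]
        keep = select_crop(reads, alt_flags, H, vaf_precrop, overlaps)

    ref_codes = _SEQ_LUT[np.frombuffer(ref_window.encode(), dtype=np.uint8)].copy()
    ref_codes[np.frombuffer(ref_window.encode(), dtype=np.uint8) == ord("-")] = GAP_CODE
    ref_onehot = np.zeros((4, W), dtype=np.float32)
    for b in range(4):
        ref_onehot[b, ref_codes == b] = 1.0

    rows = np.zeros((len(keep), C, W), dtype=np.float32)
    sort_symbols = np.empty(len(keep), dtype=np.int8)
    for r, i in enumerate(keep):
        read, qmap = reads[i], qmaps[i]
        rows[r, 0:4] = ref_onehot
        covered = qmap >= 0
        if covered.any():
            qidx = qmap[covered]
            codes = _SEQ_LUT[np.frombuffer(read.sequence.encode(), dtype=np.uint8)][qidx]
            e = np.power(10.0, -read.qualities[qidx] / 10.0).astype(np.float32)
            cw = np.nonzero(covered)[0]
            base_ok = codes < 4
            for b in range(4):
                called = base_ok & (codes == b)
                rows[r, 4 + b, cw[called]] = 1.0 - e[called]
                other = base_ok & (codes != b)
                rows[r, 4 + b, cw[other]] = e[other] / 3.0
        span = qmap != UNCOVERED
        for j, mask in enumerate(cfg.flag_set):
            if read.flags & mask:
                rows[r, 8 + j, span] = 1.0
        vq = qmap[vc]
        if vq >= 0:
            code = _SEQ_LUT[ord(read.sequence[vq])]
            sort_symbols[r] = code if code < 4 else GAP_CODE
        else:
            sort_symbols[r] = GAP_CODE

    order = np.argsort(sort_symbols, kind="stable")
    tensor = np.zeros((C, W, H), dtype=np.float32)
    for h, r in enumerate(order):
        tensor[:, :, h] = rows[r]

    if meta is None:
        meta = np.zeros(10, dtype=np.float32)
        meta[0] = vaf_precrop
        meta[1] = dp / H
    meta = np.asarray(meta, dtype=np.float32)
    if meta.shape != (10,):
        raise ValueError("meta vector must have exactly 10 values")

    return VariantTensor(
        tensor=tensor,
        meta=meta,
        vaf_precrop=float(vaf_precrop),
        dp_precrop=dp,
        truth_label=variant.truth_label,
        low_coverage=dp == 0,
        variant=variant,
    )


def variant_allele_stats(
    bam: pysam.AlignmentFile | str,
    variant: CandidateVariant,
    cfg: PileupConfig,
) -> tuple[float, int]:
    """(VAF, DP) of a variant measured from the BAM with the encoder's read filters."""
    reads = fetch_site_reads(bam, variant, cfg)
    if not reads:
        return 0.0, 0
    cols = column_ref_positions(variant, cfg)
    n_alt = sum(_read_column_map(r, cols, variant)[1] for r in reads)
    return n_alt / len(reads), len(reads)
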