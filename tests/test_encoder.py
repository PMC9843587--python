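"""Pileup tensor encoding: p-hot channels, cropping, assembly, sorting."""

import numpy as np
import pysam
import pytest

from somaticnet.encoder import (
    PileupConfig,
    assemble_tensor,
    column_ref_positions,
    encode_read,
    fetch_site_reads,
    read_supports_alt,
    reference_window,
    select_crop,
    variant_allele_stats,
)
from somaticnet.variants import CandidateVariant

from conftest import make_read


# --------------------------------------------------------------------- config
def test_channel_count_follows_flag_set():
    assert PileupConfig().C == 14
    assert PileupConfig(flag_set=(0x2, 0x10)).C == 10
    assert PileupConfig().variant_col == 75


# ----------------------------------------------------------------- encode_read
def test_phot_high_quality_limit():
    read = make_read("A", quals=90)
    mat = encode_read(read, "A", PileupConfig())
    assert mat[4:8, 0] == pytest.approx([1.0, 0.0, 0.0, 0.0], abs=1e-6)


def test_phot_q10_closed_form():
    read = make_read("A", quals=10)  # e = 0.1
    mat = encode_read(read, "C", PileupConfig())
    assert mat[4, 0] == pytest.approx(0.9, abs=1e-6)
    assert mat[5:8, 0] == pytest.approx([0.1 / 3] * 3, abs=1e-6)
    # reference one-hot goes to the C channel
    assert mat[0:4, 0].tolist() == [0.0, 1.0, 0.0, 0.0]


def test_phot_mass_conservation_random_quals():
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), 60))
    read = make_read(seq, quals=list(rng.integers(2, 42, size=60)))
    mat = encode_read(read, seq, PileupConfig())
    np.testing.assert_allclose(mat[4:8].sum(axis=0), 1.0, atol=1e-6)


def test_flag_channels_follow_mask_order():
    cfg = PileupConfig()
    read = make_read("ACGT", flags=0x2 | 0x10)
    mat = encode_read(read, "ACGT", cfg)
    assert mat[8:14, 0].tolist() == [1.0, 0.0, 1.0, 0.0, 0.0, 0.0]
    read2 = make_read("ACGT", flags=0x8 | 0x800)
    mat2 = encode_read(read2, "ACGT", cfg)
    assert mat2[8:14, 2].tolist() == [0.0, 1.0, 0.0, 0.0, 0.0, 1.0]


# ----------------------------------------------------------------- select_crop
def test_crop_keeps_vaf_exact_when_possible():
    reads = list(range(100))
    alt = [True] * 30 + [False] * 70  # VAF 0.30
    kept = select_crop(reads, alt, H=70, vaf_precrop=0.30)
    assert len(kept) == 70
    kept_alt = sum(1 for i in kept if alt[i])
    assert kept_alt == 21  # 21/70 = 0.30 exactly


def test_crop_zero_alt_stays_zero():
    reads = list(range(71))
    alt = [False] * 71
    kept = select_crop(reads, alt, H=70, vaf_precrop=0.0)
    assert len(kept) == 70
    assert sum(1 for i in kept if alt[i]) == 0


def test_crop_matches_bruteforce_over_random_pileups():
    """|VAF_after - VAF_before| <= 1/H, and the split is the brute-force optimum."""
    rng = np.random.default_rng(17)
    H = 70
    for _ in range(1000):
        dp = int(rng.integers(H + 1, 4 * H))
        n_alt = int(rng.integers(0, dp + 1))
        vaf = n_alt / dp
        alt = np.zeros(dp, bool)
        alt[rng.permutation(dp)[:n_alt]] = True
        kept = select_crop(np.arange(dp), alt, H, vaf)
        assert len(kept) == H
        vaf_after = alt[kept].sum() / H
        assert abs(vaf_after - vaf) <= 1.0 / H + 1e-12
        # brute force over all removal splits (a alt reads kept)
        lo, hi = max(0, H - (dp - n_alt)), min(H, n_alt)
        best = min(abs(a / H - vaf) for a in range(lo, hi + 1))
        assert abs(vaf_after - vaf) == pytest.approx(best, abs=1e-12)


def test_crop_removes_smallest_overlap_first():
    reads = list(range(5))
    alt = [False] * 5
    overlaps = [50, 10, 50, 5, 50]
    kept = select_crop(reads, alt, H=3, vaf_precrop=0.0, overlaps=overlaps)
    assert kept == [0, 2, 4]  # indices 3 (overlap 5) and 1 (overlap 10) dropped


# ------------------------------------------------------------- assemble_tensor
def _snp_site(n_ref=3, n_alt=2, W=150):
    """Hand-built SNP site: reads of length 20 over a 200-bp toy reference."""
    rng = np.random.default_rng(1)
    ref_seq = "".join(rng.choice(list("ACGT"), 300))
    pos0 = 150
    ref_base = ref_seq[pos0]
    alt_base = next(b for b in "TACG" if b != ref_base)
    variant = CandidateVariant("chr1", pos0 + 1, ref_base, alt_base)
    reads = []
    for i in range(n_ref):
        reads.append(make_read(ref_seq[pos0 - 10 : pos0 + 10], start=pos0 - 10, name=f"ref{i}"))
    for i in range(n_alt):
        seq = ref_seq[pos0 - 10 : pos0] + alt_base + ref_seq[pos0 + 1 : pos0 + 10]
        reads.append(make_read(seq, start=pos0 - 10, name=f"alt{i}"))
    return variant, reads, ref_seq


def _window(ref_seq, variant, cfg):
    cols = column_ref_positions(variant, cfg)
    return "".join(ref_seq[c] if 0 <= c < len(ref_seq) else "-" for c in cols)


def test_tensor_dimensions_and_vaf():
    cfg = PileupConfig()
    variant, reads, ref_seq = _snp_site(n_ref=3, n_alt=2)
    vt = assemble_tensor(variant, reads, _window(ref_seq, variant, cfg), cfg)
    assert vt.tensor.shape == (14, 150, 70)
    assert vt.meta.shape == (10,)
    assert vt.vaf_precrop == pytest.approx(0.4)
    assert vt.dp_precrop == 5


def test_rows_sorted_by_variant_column_symbol():
    cfg = PileupConfig()
    variant, reads, ref_seq = _snp_site(n_ref=3, n_alt=2)
    vt = assemble_tensor(variant, reads, _window(ref_seq, variant, cfg), cfg)
    vc = cfg.variant_col
    ref_i = "ACGT".index(variant.ref)
    alt_i = "ACGT".index(variant.alt)
    symbols = []
    for h in range(5):
        col = vt.tensor[4:8, vc, h]
        symbols.append(int(np.argmax(col)))
    groups = [s for s in symbols]
    assert groups == sorted(groups)  # A,C,G,T group order, contiguous
    assert groups.count(ref_i) == 3 and groups.count(alt_i) == 2


def test_padding_rows_all_zero():
    cfg = PileupConfig()
    variant, reads, ref_seq = _snp_site()
    vt = assemble_tensor(variant, reads, _window(ref_seq, variant, cfg), cfg)
    assert np.all(vt.tensor[:, :, 5:] == 0)


def test_quality_columns_sum_zero_or_one():
    cfg = PileupConfig()
    variant, reads, ref_seq = _snp_site()
    vt = assemble_tensor(variant, reads, _window(ref_seq, variant, cfg), cfg)
    sums = vt.tensor[4:8].sum(axis=0)
    near0 = np.abs(sums) < 1e-6
    near1 = np.abs(sums - 1) < 1e-6
    assert np.all(near0 | near1)


def test_encoding_deterministic():
    cfg = PileupConfig()
    variant, reads, ref_seq = _snp_site()
    w = _window(ref_seq, variant, cfg)
    t1 = assemble_tensor(variant, reads, w, cfg).tensor
    t2 = assemble_tensor(variant, reads, w, cfg).tensor
    assert t1.tobytes() == t2.tobytes()


def test_zero_reads_low_coverage_tensor():
    cfg = PileupConfig()
    variant, _, ref_seq = _snp_site()
    vt = assemble_tensor(variant, [], _window(ref_seq, variant, cfg), cfg)
    assert vt.low_coverage
    assert vt.vaf_precrop == 0.0 and vt.dp_precrop == 0
    assert np.all(vt.tensor == 0)


def test_insertion_columns_and_gaps():
    cfg = PileupConfig()
    rng = np.random.default_rng(2)
    ref_seq = "".join(rng.choice(list("ACGT"), 300))
    pos0 = 150
    anchor = ref_seq[pos0]
    variant = CandidateVariant("chr1", pos0 + 1, anchor, anchor + "TT")  # 2-bp insertion
    cols = column_ref_positions(variant, cfg)
    vc = cfg.variant_col
    assert cols[vc] == -1 and cols[vc + 1] == -1  # two insertion slots
    assert cols[vc - 1] == pos0 and cols[vc + 2] == pos0 + 1
    # carrier read: 10M 2I 10M; non-carrier plain 20M
    left = ref_seq[pos0 - 9 : pos0 + 1]
    right = ref_seq[pos0 + 1 : pos0 + 11]
    carrier = make_read(left + "TT" + right, start=pos0 - 9, cigar=[(0, 10), (1, 2), (0, 10)])
    plain = make_read(ref_seq[pos0 - 9 : pos0 + 11], start=pos0 - 9)
    assert read_supports_alt(carrier, variant, cfg)
    assert not read_supports_alt(plain, variant, cfg)
    w = _window(ref_seq, variant, cfg)
    vt = assemble_tensor(variant, [carrier, plain], w, cfg)
    # reference one-hot zero on insertion slots for every real read row
    assert np.all(vt.tensor[0:4, vc : vc + 2, :2] == 0)
    # carrier shows bases (T) in the slots, the plain read a gap (zero quality)
    order_symbols = vt.tensor[4:8, vc, :2].sum(axis=0)
    assert order_symbols[0] > 0.5  # carrier row sorted before gap row
    assert order_symbols[1] == 0.0
    assert vt.vaf_precrop == pytest.approx(0.5)


def test_deletion_support_and_gap_group():
    cfg = PileupConfig()
    rng = np.random.default_rng(3)
    ref_seq = "".join(rng.choice(list("ACGT"), 300))
    pos0 = 150
    variant = CandidateVariant("chr1", pos0 + 1, ref_seq[pos0 : pos0 + 3], ref_seq[pos0])  # 2-bp deletion
    carrier = make_read(
        ref_seq[pos0 - 9 : pos0 + 1] + ref_seq[pos0 + 3 : pos0 + 13],
        start=pos0 - 9,
        cigar=[(0, 10), (2, 2), (0, 10)],
    )
    plain = make_read(ref_seq[pos0 - 9 : pos0 + 11], start=pos0 - 9)
    assert read_supports_alt(carrier, variant, cfg)
    assert not read_supports_alt(plain, variant, cfg)
    cols = column_ref_positions(variant, cfg)
    assert cols[cfg.variant_col] == pos0 + 1  # first deleted base
    vt = assemble_tensor(variant, [carrier, plain], _window(ref_seq, variant, cfg), cfg)
    # gap rows sort after base rows: row 0 is the plain read (a base), row 1 the deletion
    assert vt.tensor[4:8, cfg.variant_col, 0].sum() > 0.5
    assert vt.tensor[4:8, cfg.variant_col, 1].sum() == 0.0


# ------------------------------------------------------------------ BAM access
def test_fetch_site_reads_excludes_flagged(small_cohort):
    cohort, paths = small_cohort
    cfg = PileupConfig()
    sample = cohort.samples[0]
    bam = pysam.AlignmentFile(paths["bam"][sample.sample_id])
    rec = sample.truth[0]
    reads = fetch_site_reads(bam, rec.variant, cfg)
    assert all(not (r.flags & cfg.exclude_flags) for r in reads)
    assert len(reads) == rec.depth  # duplicates excluded, planted depth exact


def test_fetch_unknown_contig_raises(small_cohort):
    cohort, paths = small_cohort
    bam = pysam.AlignmentFile(paths["bam"]["S1"])
    v = CandidateVariant("chrUnknown", 100, "A", "T")
    with pytest.raises(ValueError):
        fetch_site_reads(bam, v, PileupConfig())


def test_encoded_vaf_matches_planted(clean_cohort):
    cohort, paths = clean_cohort
    cfg = PileupConfig()
    sample = cohort.samples[0]
    bam = pysam.AlignmentFile(paths["bam"][sample.sample_id])
    fasta = pysam.FastaFile(paths["fasta"])
    for rec in sample.truth[:10]:
        reads = fetch_site_reads(bam, rec.variant, cfg)
        vt = assemble_tensor(rec.variant, reads, reference_window(fasta, rec.variant, cfg), cfg)
        assert vt.dp_precrop == rec.depth
        assert vt.vaf_precrop == pytest.approx(rec.n_alt / rec.depth)
        vaf, dp = variant_allele_stats(bam, rec.variant, cfg)
        assert (vaf, dp) == (pytest.approx(vt.vaf_precrop), vt.dp_precrop)
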