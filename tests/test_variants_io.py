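"""Candidate VCF I/O, allele normalization and population filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somaticnet.variants import (
    CandidateVariant,
    PopulationDB,
    enumerate_candidates,
    load_population_db,
    normalize_variant,
    population_filter,
    read_candidate_vcf,
    write_candidate_vcf,
)

from conftest import write_vcf


# ---------------------------------------------------------------- construction
def test_variant_type_derivation():
    assert CandidateVariant("chr1", 100, "A", "T").variant_type == "SNP"
    assert CandidateVariant("chr1", 100, "A", "AT").variant_type == "INS"
    assert CandidateVariant("chr1", 100, "AT", "A").variant_type == "DEL"


@pytest.mark.parametrize(
    "kwargs",
    [
        {"pos": 0, "ref": "A", "alt": "T"},
        {"pos": 1, "ref": "", "alt": "T"},
        {"pos": 1, "ref": "A", "alt": "N"},
        {"pos": 1, "ref": "A", "alt": "A"},
    ],
)
def test_invalid_variants_rejected(kwargs):
    with pytest.raises(ValueError):
        CandidateVariant("chr1", **kwargs)


# ---------------------------------------------------------------- normalization
def _brute_force_minimal(pos, ref, alt):
    """Independent oracle: exhaustively apply single trim moves to a fixpoint."""
    state = (pos, ref, alt)
    while True:
        pos, ref, alt = state
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            state = (pos, ref[:-1], alt[:-1])
            continue
        if len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            state = (pos + 1, ref[1:], alt[1:])
            continue
        return state


@pytest.mark.parametrize(
    "pos,ref,alt,exp_pos,exp_ref,exp_alt",
    [
        (100, "AT", "GT", 100, "A", "G"),  # shared suffix
        (100, "CA", "CTA", 100, "C", "CT"),  # suffix then prefix, re-anchored
        (100, "A", "T", 100, "A", "T"),  # already minimal
        (50, "TCC", "TTC", 51, "C", "T"),  # prefix + suffix both
    ],
)
def test_normalize_examples(pos, ref, alt, exp_pos, exp_ref, exp_alt):
    v = normalize_variant(CandidateVariant("chr1", pos, ref, alt))
    assert (v.pos, v.ref, v.alt) == (exp_pos, exp_ref, exp_alt)


def test_normalize_idempotent_and_matches_bruteforce():
    rng = np.random.default_rng(7)
    bases = "ACGT"
    for _ in range(1000):
        ref = "".join(rng.choice(list(bases), size=rng.integers(1, 6)))
        alt = "".join(rng.choice(list(bases), size=rng.integers(1, 6)))
        if ref == alt:
            continue
        v = CandidateVariant("chr1", 500, ref, alt)
        n1 = normalize_variant(v)
        assert normalize_variant(n1).key == n1.key  # idempotent
        assert (n1.pos, n1.ref, n1.alt) == _brute_force_minimal(500, ref, alt)


_alleles = st.text(alphabet="ACGT", min_size=1, max_size=8)


@settings(derandomize=True, max_examples=300)
@given(ref=_alleles, alt=_alleles, pos=st.integers(min_value=1, max_value=10**6))
def test_normalize_property(ref, alt, pos):
    if ref == alt:
        return
    v = normalize_variant(CandidateVariant("chr1", pos, ref, alt))
    assert normalize_variant(v).key == v.key
    assert (v.pos, v.ref, v.alt) == _brute_force_minimal(pos, ref, alt)
    # trimming never destroys the allele-length difference (variant type)
    assert len(ref) - len(alt) == len(v.ref) - len(v.alt)


# ----------------------------------------------------------------------- VCF IO
def test_empty_vcf_gives_empty_list(tmp_path):
    path = write_vcf(tmp_path / "empty.vcf", [])
    assert read_candidate_vcf(path) == []


def test_single_snp_record(tmp_path):
    path = write_vcf(tmp_path / "one.vcf", [("chr1", 100, "A", ["T"])])
    (v,) = read_candidate_vcf(path, sample_id="s1")
    assert v.key == ("chr1", 100, "A", "T")
    assert v.variant_type == "SNP"
    assert v.sample_id == "s1"


def test_multiallelic_decomposed(tmp_path):
    path = write_vcf(tmp_path / "multi.vcf", [("chr1", 100, "A", ["T", "G"])])
    variants = read_candidate_vcf(path)
    assert len(variants) == 2
    assert {v.alt for v in variants} == {"T", "G"}
    assert all(v.pos == 100 for v in variants)


def test_unreadable_vcf_raises(tmp_path):
    bad = tmp_path / "bad.vcf"
    bad.write_text("this is not a vcf\n")
    with pytest.raises(OSError):
        read_candidate_vcf(str(bad))


def test_roundtrip_preserves_keys(tmp_path, small_cohort):
    cohort, paths = small_cohort
    variants = read_candidate_vcf(paths["candidates"]["S1"])
    out = tmp_path / "rt.vcf"
    write_candidate_vcf(variants, str(out))
    back = read_candidate_vcf(str(out))
    assert [v.key for v in back] == [v.key for v in variants]


# ------------------------------------------------------------------ population
def test_population_db_size_and_af(tmp_path):
    path = write_vcf(
        tmp_path / "pop.vcf",
        [("chr1", 10, "A", ["T"], (0.5,)), ("chr1", 20, "C", ["G"], (0.01,)), ("chr1", 30, "G", ["A"], (0.2,))],
        af_field=True,
    )
    db = load_population_db(path)
    assert len(db) == 3
    assert db.af(("chr1", 10, "A", "T")) == pytest.approx(0.5)


def test_population_db_duplicate_keeps_max(tmp_path):
    path = write_vcf(
        tmp_path / "dup.vcf",
        [("chr1", 10, "A", ["T"], (0.1,)), ("chr1", 10, "A", ["T"], (0.4,))],
        af_field=True,
    )
    db = load_population_db(path)
    assert len(db) == 1
    assert db.af(("chr1", 10, "A", "T")) == pytest.approx(0.4)


def test_population_db_empty_and_presence_only(tmp_path):
    empty = write_vcf(tmp_path / "e.vcf", [], af_field=True)
    assert len(load_population_db(empty)) == 0
    no_af = write_vcf(tmp_path / "n.vcf", [("chr1", 10, "A", ["T"])])
    db = load_population_db(no_af)
    assert not db.has_af
    assert db.af(("chr1", 10, "A", "T")) == 0.0


def _toy_filter_setup():
    db = PopulationDB()
    db.add(("chr1", 20, "C", "G"), 0.001)
    db.add(("chr1", 30, "G", "A"), 0.2)
    variants = [
        CandidateVariant("chr1", 10, "A", "T"),  # absent
        CandidateVariant("chr1", 20, "C", "G"),  # AF 0.001
        CandidateVariant("chr1", 30, "G", "A"),  # AF 0.2
    ]
    return variants, db


@pytest.mark.parametrize("max_af,n_retained", [(0.0, 1), (0.05, 2), (1.0, 3)])
def test_population_filter_thresholds(max_af, n_retained):
    variants, db = _toy_filter_setup()
    retained, removed = population_filter(variants, db, max_af=max_af)
    assert len(retained) == n_retained
    assert len(retained) + len(removed) == 3


def test_population_filter_annotates_af_and_is_monotone():
    rng = np.random.default_rng(3)
    db = PopulationDB()
    variants = []
    for i in range(50):
        v = CandidateVariant("chr1", 10 + i * 5, "A", "T")
        variants.append(v)
        if i % 2:
            db.add(v.key, float(rng.uniform(0, 1)))
    sizes = []
    for max_af in [0.0, 0.1, 0.3, 0.6, 1.0]:
        retained, _ = population_filter(variants, db, max_af=max_af)
        sizes.append(len(retained))
    assert sizes == sorted(sizes)
    _, removed = population_filter(variants, db, max_af=0.0)
    assert all(v.pop_af is not None for v in removed)


# ----------------------------------------------------------------- enumeration
def test_enumerate_recovers_planted_variants(clean_cohort):
    cohort, paths = clean_cohort
    sample = cohort.samples[0]
    found = enumerate_candidates(paths["bam"][sample.sample_id], paths["fasta"], min_alt_reads=1)
    planted = {t.variant.key for t in sample.truth if t.n_alt >= 1}
    assert {v.key for v in found} == planted


def test_enumerate_high_threshold_empty(clean_cohort):
    cohort, paths = clean_cohort
    sid = cohort.samples[0].sample_id
    found = enumerate_candidates(paths["bam"][sid], paths["fasta"], min_alt_reads=10_000)
    assert found == []


def test_enumerate_empty_bam(tmp_path):
    from somaticnet.simdata import SimConfig, simulate_cohort, write_fixtures

    cfg = SimConfig(seed=1, n_samples=1, n_somatic=0, n_germline=0, n_artifact=0, genome_length=20_000)
    paths = write_fixtures(simulate_cohort(cfg), str(tmp_path / "empty"))
    assert enumerate_candidates(paths["bam"]["S1"], paths["fasta"]) == []


def test_enumerate_requires_index(tmp_path, clean_cohort):
    import shutil

    cohort, paths = clean_cohort
    sid = cohort.samples[0].sample_id
    unindexed = tmp_path / "noindex.bam"
    shutil.copy(paths["bam"][sid], unindexed)
    with pytest.raises(OSError):
        enumerate_candidates(str(unindexed), paths["fasta"])
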