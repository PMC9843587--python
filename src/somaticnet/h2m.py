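"""Hard-to-map (H2M) region annotation from user-supplied BED tracks.

A variant is flagged H2M when it falls in at least one of four categories:
(i) inside a repeat, more than one read length away from both repeat edges;
(ii) inside a variant hotspot; (iii) overlapping a mappability interval with
score below 1.0; (iv) inside a problematic ("H2M") gene. Tracks are consumed
as BED files (0-based half-open); the mappability track carries the score in
its fourth column.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from somaticnet.variants import CandidateVariant


@dataclass
class H2MAnnotation:
    repeat: bool = False
    hotspot: bool = False
    low_mappability: bool = False
    h2m_gene: bool = False

    @property
    def is_h2m(self) -> bool:
        return self.repeat or self.hotspot or self.low_mappability or self.h2m_gene


def _read_bed(path: str, with_score: bool = False) -> dict[str, IntervalTree]:
    """Parse a BED file into per-contig interval trees.

    With ``with_score`` the fourth column is parsed as a float and stored as
    the interval payload. Malformed lines raise with the offending line
    number.
    """
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                if end < start:
                    raise ValueError("end < start")
                score = float(fields[3]) if with_score else None
            except (IndexError, ValueError) as exc:
                raise ValueError(f"malformed BED line {lineno} in {path!r}: {line!r} ({exc})") from exc
            if end == start:
                continue
            trees.setdefault(chrom, IntervalTree()).addi(start, end, score)
    return trees


@dataclass
class H2MTracks:
    """The four region tracks, loaded once and queried per variant."""

    repeats: dict[str, IntervalTree]
    hotspots: dict[str, IntervalTree]
    mappability: dict[str, IntervalTree]
    genes: dict[str, IntervalTree]

    @classmethod
    def load(
        cls,
        repeat_bed: str | None = None,
        hotspot_bed: str | None = None,
        mappability_bed: str | None = None,
        gene_bed: str | None = None,
    ) -> "H2MTracks":
        return cls(
            repeats=_read_bed(repeat_bed) if repeat_bed else {},
            hotspots=_read_bed(hotspot_bed) if hotspot_bed else {},
            mappability=_read_bed(mappability_bed, with_score=True) if mappability_bed else {},
            genes=_read_bed(gene_bed) if gene_bed else {},
        )


def annotate_h2m(variant: CandidateVariant, tracks: H2MTracks, read_length: int = 100) -> H2MAnnotation:
    """Flag one variant against the four H2M categories.

    The repeat flag requires the variant to sit more than ``read_length``
    bases from both edges of at least one overlapping repeat (a read
    anchored outside the repeat cannot span it). The mappability flag fires
    on any overlapping interval with score < 1.0; hotspot and gene flags on
    simple overlap.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    pos0 = variant.pos - 1  # 0-based position of the variant column
    ann = H2MAnnotation()
    for iv in tracks.repeats.get(variant.chrom, IntervalTree()).at(pos0):
        if pos0 - iv.begin > read_length and iv.end - 1 - pos0 > read_length:
            ann.repeat = True
            break
    if tracks.hotspots.get(variant.chrom, IntervalTree()).at(pos0):
        ann.hotspot = True
    for iv in tracks.mappability.get(variant.chrom, IntervalTree()).at(pos0):
        if iv.data is not None and iv.data < 1.0:
            ann.low_mappability = True
            break
    if tracks.genes.get(variant.chrom, IntervalTree()).at(pos0):
        ann.h2m_gene = True
    return ann


def stratify_by_h2m(
    variants: list[CandidateVariant],
    tracks: H2MTracks,
    read_length: int = 100,
) -> tuple[list[CandidateVariant], list[CandidateVariant]]:
    """Partition variants into (h2m, non_h2m); every variant lands in exactly one."""
    h2m, non = [], []
    for v in variants:
        (h2m if annotate_h2m(v, tracks, read_length).is_h2m else non).append(v)
    return h2m, non
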