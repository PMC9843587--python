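"""Flanking germline variants and the 10-value meta vector.

The average VAF of heterozygous germline variants is ~50% genome-wide, but
copy-number alterations shift it locally. Nearby germline variants ("flanking
variants") carry that local baseline: if a candidate's VAF matches the VAF of
flanking germline variants on both sides, the candidate is more likely
germline itself. Up to two flanking variants per side are annotated, searched
within a window around the candidate (default 4 Mbp total span) among
candidates whose population AF exceeds 10%. Flanking annotation happens
before population filtering, so flanks that will later be filtered out still
contribute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pysam

from somaticnet.encoder import PileupConfig, variant_allele_stats
from somaticnet.variants import CandidateVariant, PopulationDB


@dataclass
class FlankingSlot:
    """VAF/DP of one flanking germline variant; zeroed when absent."""

    vaf: float = 0.0
    dp: int = 0
    distance: int = 0
    present: bool = False


def find_flanking(
    candidate: CandidateVariant,
    germline_candidates: Sequence[CandidateVariant],
    db: PopulationDB,
    bam: pysam.AlignmentFile | str | None,
    cfg: PileupConfig | None = None,
    window_bp: int = 4_000_000,
    af_min: float = 0.10,
    stats_cache: dict | None = None,
) -> tuple[list[FlankingSlot], list[FlankingSlot]]:
    """Select up to two flanking germline variants on each side of a candidate.

    ``germline_candidates`` is the pre-filter candidate list of the same
    sample. A neighbor qualifies when its population AF exceeds ``af_min``
    and it lies within ``window_bp / 2`` of the candidate on the same contig;
    the nearest qualifying neighbors fill the slots. Slot VAF/DP are measured
    from the tumor BAM with the encoder's read filters (``stats_cache`` may
    be shared across candidates of the same sample to avoid re-pileups).
    Returns ``(left, right)``, each a list of exactly two slots.
    """
    cfg = cfg or PileupConfig()
    half = window_bp // 2
    left_pool: list[tuple[int, CandidateVariant]] = []
    right_pool: list[tuple[int, CandidateVariant]] = []
    for g in germline_candidates:
        if g.chrom != candidate.chrom or g.key == candidate.key:
            continue
        af = db.af(g.key)
        if af is None or af <= af_min:
            continue
        dist = g.pos - candidate.pos
        if dist == 0 or abs(dist) > half:
            continue
        (left_pool if dist < 0 else right_pool).append((abs(dist), g))

    def fill(pool: list[tuple[int, CandidateVariant]]) -> list[FlankingSlot]:
        pool.sort(key=lambda t: (t[0], t[1].pos))
        slots = [FlankingSlot(), FlankingSlot()]
        for slot_i, (dist, g) in enumerate(pool[:2]):
            vaf, dp = (0.0, 0)
            if bam is not None:
                key = ("stats", g.key)
                if stats_cache is not None and key in stats_cache:
                    vaf, dp = stats_cache[key]
                else:
                    vaf, dp = variant_allele_stats(bam, g, cfg)
                    if stats_cache is not None:
                        stats_cache[key] = (vaf, dp)
            slots[slot_i] = FlankingSlot(vaf=vaf, dp=dp, distance=dist, present=True)
        return slots

    return fill(left_pool), fill(right_pool)


def build_meta_vector(
    candidate_vaf: float,
    candidate_dp: int,
    left: Sequence[FlankingSlot],
    right: Sequence[FlankingSlot],
    H: int = 70,
    zero_flanking: bool = False,
) -> np.ndarray:
    """The 10-value meta vector [cand, L1, L2, R1, R2] x (VAF, DP/H).

    Depth entries are scaled by ``1/H`` so all ten values live on comparable
    scales. ``zero_flanking`` zeroes the eight flanking entries regardless of
    the slots — the flanking-ablation configuration.
    """
    slots = list(left) + list(right)
    if len(slots) != 4:
        raise ValueError("expected exactly two slots per side")
    out = np.zeros(10, dtype=np.float32)
    out[0] = candidate_vaf
    out[1] = candidate_dp / H
    if not zero_flanking:
        for i, s in enumerate(slots):
            out[2 + 2 * i] = s.vaf
            out[3 + 2 * i] = s.dp / H
    return out
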