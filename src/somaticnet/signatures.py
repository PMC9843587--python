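"""Trinucleotide-context mutational signatures and Jensen-Shannon divergence.

A mutation class is the 3-bp reference window centered on an SNV plus the
alternate base. Without strand collapsing there are 64 contexts x 3 alternate
bases = 192 classes; the COSMIC-style option collapses purine-centered
classes onto their reverse complements, giving 96 pyrimidine-centered
classes. A signature is the probability vector over classes, optionally
normalized by how often each context occurs in the reference genome (so that
genome composition does not masquerade as mutational preference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pysam
from scipy.spatial.distance import jensenshannon

from somaticnet.variants import CandidateVariant

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def mutation_classes(collapse: bool = False) -> tuple[tuple[str, str], ...]:
    """Ordered (context, alt) class space: 192 classes, or 96 when collapsed."""
    classes = []
    for l, c, r in product(_BASES, repeat=3):
        if collapse and c not in "CT":
            continue
        for alt in _BASES:
            if alt != c:
                classes.append((l + c + r, alt))
    return tuple(classes)


def collapse_class(context: str, alt: str) -> tuple[str, str]:
    """Map a class to its pyrimidine-centered representative."""
    if context[1] in "CT":
        return context, alt
    return _revcomp(context), alt.translate(_COMPLEMENT)


@dataclass
class MutationalSignature:
    """Probability vector over (trinucleotide context, alt) mutation classes."""

    probs: np.ndarray
    classes: tuple[tuple[str, str], ...]
    collapsed: bool = False

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.classes),):
            raise ValueError("probability vector does not match the class space")
        if np.any(self.probs < 0):
            raise ValueError("signature probabilities must be non-negative")
        total = self.probs.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"signature probabilities sum to {total}, not 1")

    def as_dict(self) -> dict[tuple[str, str], float]:
        return dict(zip(self.classes, self.probs))


def genome_context_counts(fasta: pysam.FastaFile, collapse: bool = False) -> dict[str, int]:
    """Occurrences of every trinucleotide context in the reference.

    In collapsed mode, purine-centered windows are counted toward their
    reverse complement so the counts cover both strands of the 32
    pyrimidine-centered contexts.
    """
    counts: dict[str, int] = {}
    lut = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    for contig in fasta.references:
        seq = fasta.fetch(contig)
        codes = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
        if codes.size < 3:
            continue
        valid = (codes[:-2] >= 0) & (codes[1:-1] >= 0) & (codes[2:] >= 0)
        idx = codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:]
        binc = np.bincount(idx[valid], minlength=64)
        for j in range(64):
            if binc[j]:
                ctx = _BASES[j // 16] + _BASES[(j // 4) % 4] + _BASES[j % 4]
                counts[ctx] = counts.get(ctx, 0) + int(binc[j])
    if collapse:
        collapsed: dict[str, int] = {}
        for ctx, n in counts.items():
            rep = ctx if ctx[1] in "CT" else _revcomp(ctx)
            collapsed[rep] = collapsed.get(rep, 0) + n
        return collapsed
    return counts


def compute_signature(
    snvs: Sequence[CandidateVariant],
    fasta: pysam.FastaFile | str,
    normalize_by_genome: bool = False,
    collapse: bool = False,
) -> MutationalSignature:
    """Empirical mutational signature of a pool of SNVs.

    Raw class frequencies are the fraction of the pool falling in each
    (context, alt) class. With ``normalize_by_genome`` each class frequency
    is divided by its context's genome occurrence count and the vector is
    renormalized to sum 1 (classes whose context never occurs get
    probability 0 with a warning). Variants with unresolvable (non-ACGT)
    context are skipped with a logged count.
    """
    own = isinstance(fasta, str)
    fa = pysam.FastaFile(fasta) if own else fasta
    classes = mutation_classes(collapse)
    index = {cls: i for i, cls in enumerate(classes)}
    counts = np.zeros(len(classes), dtype=float)
    n_skipped = 0
    try:
        for v in snvs:
            if v.variant_type != "SNP":
                raise ValueError(f"compute_signature expects SNVs only, got {v.variant_type}")
            pos0 = v.pos - 1
            ctx = fa.fetch(v.chrom, max(pos0 - 1, 0), pos0 + 2).upper()
            if len(ctx) != 3 or not set(ctx) <= set(_BASES):
                n_skipped += 1
                continue
            if ctx[1] != v.ref:
                raise ValueError(f"reference mismatch at {v.chrom}:{v.pos}: {ctx[1]} vs {v.ref}")
            cls = collapse_class(ctx, v.alt) if collapse else (ctx, v.alt)
            counts[index[cls]] += 1
        if n_skipped:
            logger.info("skipped %d SNVs with ambiguous context", n_skipped)
        if counts.sum() == 0:
            raise ValueError("no SNVs with resolvable context")
        probs = counts / counts.sum()
        if normalize_by_genome:
            ctx_counts = genome_context_counts(fa, collapse)
            denom = np.array([ctx_counts.get(ctx, 0) for ctx, _ in classes], dtype=float)
            zero = (denom == 0) & (probs > 0)
            if zero.any():
                logger.warning("%d classes have zero genome occurrence; set to 0", int(zero.sum()))
            with np.errstate(divide="ignore", invalid="ignore"):
                probs = np.where(denom > 0, probs / denom, 0.0)
            if probs.sum() == 0:
                raise ValueError("genome normalization annihilated the signature")
            probs = probs / probs.sum()
    finally:
        if own:
            fa.close()
    return MutationalSignature(probs=probs, classes=classes, collapsed=collapse)


def js_divergence(p: MutationalSignature, q: MutationalSignature) -> float:
    """Jensen-Shannon divergence (base-2 logarithm) between two signatures.

    Symmetric, bounded in [0, 1], zero iff the signatures coincide. Raises
    when the class spaces differ.
    """
    if p.classes != q.classes:
        raise ValueError("signatures live on different class spaces")
    # scipy returns the JS *distance* (sqrt of the divergence)
    d = jensenshannon(p.probs, q.probs, base=2)
    if np.isnan(d):  # identical distributions can produce 0/0 inside scipy
        return 0.0
    return float(min(d * d, 1.0))


def write_signature_tsv(sig: MutationalSignature, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("context\talt\tprobability\n")
        for (ctx, alt), p in zip(sig.classes, sig.probs):
            fh.write(f"{ctx}\t{alt}\t{p:.8g}\n")
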